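"""Alternative data-generating processes for the power study.

Samplers (and densities, where the fits and self-consistency tests need
them) for the unit-interval laws used as alternatives to the beta model:

* Kumaraswamy ``KW(omega, phi)`` in a median parametrization: shape-1 is the
  precision ``phi`` and shape-2 is chosen so the distribution median is
  exactly ``omega`` (the standard median-dispersion reparametrization of the
  Kumaraswamy-regression literature).
* unit Weibull ``UW(omega, phi)``, the tau = 0.5 quantile parametrization
  with distribution function ``F(y) = 0.5 ** ((log y / log omega) ** phi)``
  on (0, 1), so the median is ``omega``.
* simplex ``S(mu, sigma)`` with mean ``mu`` and dispersion ``sigma``
  (``sigma**2`` occupies the dispersion slot of the density), sampled by
  numerical inversion of a quadrature-tabulated CDF.
* beta with a logit mean regression: ``logit(mu_t) = beta1 + beta2 * x_t``
  with log-normal covariates, precision held constant.
* zero-inflated beta, plus the boundary-replacement rule
  ``[y (n-1) + 0.5] / n`` used before fitting a standard beta model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from betaimt.betadist import DomainError, FractionalSample

__all__ = [
    "DGPSpec",
    "sample_kumaraswamy",
    "sample_unit_weibull",
    "sample_simplex",
    "sample_beta_regression",
    "sample_inflated_beta",
    "replace_inflated",
    "kumaraswamy_shape2",
    "kumaraswamy_logpdf",
    "kumaraswamy_cdf",
    "unit_weibull_logpdf",
    "unit_weibull_cdf",
    "simplex_logpdf",
]


def _check_unit_open(x, name):
    if not (0.0 < x < 1.0):
        raise DomainError(f"{name} must lie in (0, 1), got {x!r}")


def _check_pos(x, name):
    if not (x > 0.0):
        raise DomainError(f"{name} must be positive, got {x!r}")


# ---------------------------------------------------------------------------
# Kumaraswamy, median parametrization
# ---------------------------------------------------------------------------

def kumaraswamy_shape2(omega: float, phi: float) -> float:
    """Second shape parameter fixing the median at ``omega``.

    With F(y) = 1 - (1 - y**phi)**b, F(omega) = 1/2 gives
    b = log(1/2) / log(1 - omega**phi).
    """
    return np.log(0.5) / np.log1p(-(omega ** phi))


def kumaraswamy_cdf(y, omega: float, phi: float):
    b = kumaraswamy_shape2(omega, phi)
    y = np.asarray(y, dtype=float)
    return -np.expm1(b * np.log1p(-(y ** phi)))


def kumaraswamy_logpdf(y, omega: float, phi: float):
    b = kumaraswamy_shape2(omega, phi)
    y = np.asarray(y, dtype=float)
    return (
        np.log(phi) + np.log(b)
        + (phi - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-(y ** phi))
    )


def sample_kumaraswamy(
    omega: float, phi: float, n: int, rng: np.random.Generator
) -> FractionalSample:
    """Inverse-CDF draws from the median-parametrized Kumaraswamy law."""
    _check_unit_open(omega, "omega")
    _check_pos(phi, "phi")
    b = kumaraswamy_shape2(omega, phi)
    u = rng.uniform(size=int(n))
    # Q(u) = (1 - (1-u)**(1/b))**(1/phi)
    y = (-np.expm1(np.log1p(-u) / b)) ** (1.0 / phi)
    return FractionalSample(np.clip(y, np.finfo(float).tiny, 1.0 - 1e-16))


# ---------------------------------------------------------------------------
# unit Weibull, median (tau = 0.5) parametrization
# ---------------------------------------------------------------------------

def unit_weibull_cdf(y, omega: float, phi: float):
    y = np.asarray(y, dtype=float)
    z = np.log(y) / np.log(omega)
    return 0.5 ** (z ** phi)


def unit_weibull_logpdf(y, omega: float, phi: float):
    y = np.asarray(y, dtype=float)
    lw = np.log(omega)
    z = np.log(y) / lw
    # f = F(y) * log(2) * phi * z**(phi-1) / (y * (-log omega))
    return (
        (z ** phi) * np.log(0.5)
        + np.log(np.log(2.0)) + np.log(phi)
        + (phi - 1.0) * np.log(z)
        - np.log(y) - np.log(-lw)
    )


def sample_unit_weibull(
    omega: float, phi: float, n: int, rng: np.random.Generator
) -> FractionalSample:
    """Inverse-CDF draws from the median-parametrized unit Weibull law."""
    _check_unit_open(omega, "omega")
    _check_pos(phi, "phi")
    u = rng.uniform(size=int(n))
    y = np.exp(np.log(omega) * (np.log(u) / np.log(0.5)) ** (1.0 / phi))
    return FractionalSample(np.clip(y, np.finfo(float).tiny, 1.0 - 1e-16))


# ---------------------------------------------------------------------------
# simplex
# ---------------------------------------------------------------------------

def simplex_logpdf(y, mu: float, sigma: float):
    """Log density of the simplex law S(mu, sigma), mean mu.

    f(y) = [2 pi sigma^2 (y(1-y))^3]^{-1/2} exp(-d(y; mu) / (2 sigma^2)),
    d(y; mu) = (y - mu)^2 / (y (1-y) mu^2 (1-mu)^2).
    """
    y = np.asarray(y, dtype=float)
    s2 = sigma * sigma
    dev = (y - mu) ** 2 / (y * (1.0 - y) * mu ** 2 * (1.0 - mu) ** 2)
    return (
        -0.5 * np.log(2.0 * np.pi * s2)
        - 1.5 * np.log(y * (1.0 - y))
        - dev / (2.0 * s2)
    )


def _simplex_cdf_table(mu: float, sigma: float, grid_size: int = 4096):
    """Tabulated CDF of the simplex law on a logit-spaced grid."""
    t = np.linspace(-16.0, 16.0, grid_size)
    y = expit(t)
    # integrate in t: f(y) dy = f(y) y(1-y) dt
    dens = np.exp(simplex_logpdf(y, mu, sigma)) * y * (1.0 - y)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0 * np.diff(t))])
    cdf /= cdf[-1]
    return y, cdf


def sample_simplex(
    mu: float, sigma: float, n: int, rng: np.random.Generator
) -> FractionalSample:
    """Draws from the simplex law by numerical inversion of its CDF."""
    _check_unit_open(mu, "mu")
    _check_pos(sigma, "sigma")
    y_grid, cdf = _simplex_cdf_table(mu, sigma)
    u = rng.uniform(size=int(n))
    y = np.interp(u, cdf, y_grid)
    return FractionalSample(np.clip(y, np.finfo(float).tiny, 1.0 - 1e-16))


# ---------------------------------------------------------------------------
# beta with a logit mean regression; zero-inflated beta
# ---------------------------------------------------------------------------

def sample_beta_regression(
    beta1: float,
    beta2: float,
    phi: float,
    n: int,
    rng: np.random.Generator,
    sdlog: float = 0.5,
) -> FractionalSample:
    """Beta draws with logit(mu_t) = beta1 + beta2 * x_t, constant precision.

    The covariates are drawn from the log-normal law with log-scale mean 0
    and log-scale standard deviation ``sdlog`` (fresh draws per call).
    """
    _check_pos(phi, "phi")
    x = rng.lognormal(mean=0.0, sigma=sdlog, size=int(n))
    mu_t = expit(beta1 + beta2 * x)
    y = rng.beta(mu_t * phi, (1.0 - mu_t) * phi)
    return FractionalSample(np.clip(y, np.finfo(float).tiny, 1.0 - 1e-16))


def sample_inflated_beta(
    mu: float, phi: float, lam: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Zero-inflated beta draws: exact 0 with probability ``lam``, else beta.

    Returns a raw array (it may contain exact zeros, so it is not a
    :class:`FractionalSample`); see :func:`replace_inflated`.
    """
    _check_unit_open(mu, "mu")
    _check_pos(phi, "phi")
    if not (0.0 <= lam < 1.0):
        raise DomainError(f"lam must lie in [0, 1), got {lam!r}")
    y = rng.beta(mu * phi, (1.0 - mu) * phi, size=int(n))
    y = np.clip(y, np.finfo(float).tiny, 1.0 - 1e-16)
    y[rng.uniform(size=int(n)) < lam] = 0.0
    return y


def replace_inflated(values, n: int | None = None) -> FractionalSample:
    """Map boundary values into (0, 1) by y -> [y (n-1) + 0.5] / n.

    Only exact zeros and ones are transformed (0 -> 0.5/n, 1 -> (n-0.5)/n);
    interior values pass through unchanged.
    """
    y = np.asarray(values, dtype=float).copy()
    if n is None:
        n = y.size
    at0 = y == 0.0
    at1 = y == 1.0
    y[at0] = 0.5 / n
    y[at1] = (n - 0.5) / n
    return FractionalSample(y)


# ---------------------------------------------------------------------------
# declarative DGP specification
# ---------------------------------------------------------------------------

_FAMILIES = (
    "beta", "kumaraswamy", "unit_weibull", "simplex",
    "beta_regression", "inflated_beta",
)


@dataclass
class DGPSpec:
    """A data-generating process: family tag plus family-specific parameters.

    Parameter keys by family:
      beta: mu, phi; kumaraswamy / unit_weibull: omega, phi;
      simplex: mu, sigma; beta_regression: beta1, beta2, phi (optional
      sdlog); inflated_beta: mu, phi, lam.
    """

    family: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def label(self) -> str:
        inner = ",".join(f"{k}={v:g}" for k, v in sorted(self.params.items()))
        return f"{self.family}({inner})"

    def sample(self, n: int, rng: np.random.Generator | None = None):
        """Draw a sample of size ``n``; inflated values are replaced so the
        result is always a valid :class:`FractionalSample`."""
        if rng is None:
            rng = np.random.default_rng(self.seed)
        p = self.params
        if self.family == "beta":
            y = rng.beta(p["mu"] * p["phi"], (1.0 - p["mu"]) * p["phi"], size=int(n))
            return FractionalSample(np.clip(y, np.finfo(float).tiny, 1.0 - 1e-16))
        if self.family == "kumaraswamy":
            return sample_kumaraswamy(p["omega"], p["phi"], n, rng)
        if self.family == "unit_weibull":
            return sample_unit_weibull(p["omega"], p["phi"], n, rng)
        if self.family == "simplex":
            return sample_simplex(p["mu"], p["sigma"], n, rng)
        if self.family == "beta_regression":
            return sample_beta_regression(
                p["beta1"], p["beta2"], p["phi"], n, rng, sdlog=p.get("sdlog", 0.5)
            )
        raw = sample_inflated_beta(p["mu"], p["phi"], p["lam"], n, rng)
        return replace_inflated(raw, int(n))

    def to_mapping(self) -> dict:
        return {"family": self.family, "params": dict(self.params), "seed": self.seed}

    @classmethod
    def from_mapping(cls, mapping: dict) -> "DGPSpec":
        return cls(
            family=mapping["family"],
            params=dict(mapping.get("params", {})),
            seed=mapping.get("seed"),
        )
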