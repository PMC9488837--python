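"""The mean-precision beta model.

The beta density is written in terms of its mean ``mu`` and precision
``phi``::

    f(y; mu, phi) = Gamma(phi) / (Gamma(mu*phi) * Gamma((1-mu)*phi))
                    * y**(mu*phi - 1) * (1-y)**((1-mu)*phi - 1),

for ``0 < y < 1``, ``0 < mu < 1`` and ``phi > 0``, so that ``E(Y) = mu`` and
``Var(Y) = mu*(1-mu)/(1+phi)``: at fixed mean, larger precision means less
dispersion.  The individual log-likelihood only involves the data through the
two transforms ``y* = log(y/(1-y))`` and ``y^dag = log(1-y)``, whose
expectations are ``mu* = psi(mu*phi) - psi((1-mu)*phi)`` and
``mu^dag = psi((1-mu)*phi) - psi(phi)`` (``psi`` is the digamma function).

Maximum likelihood estimation is performed by the BFGS quasi-Newton method
with the analytic score, run in unconstrained coordinates
``(logit mu, log phi)`` so no box constraints are needed, and polished by
Fisher scoring until the gradient of the *mean* log-likelihood (per
observation, which keeps the convergence criterion independent of the sample
size) falls below the tolerance.  A vectorised Fisher-scoring fitter,
``_fit_many``, solves large batches of independent fits on their sufficient
statistics; it reaches the same stationary points as :func:`fit_mle` and is
what the bootstrap and Monte Carlo machinery use internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from scipy.special import expit, gammaln, polygamma, psi

__all__ = [
    "ThetaMP",
    "FractionalSample",
    "FitResult",
    "DomainError",
    "DegenerateSampleError",
    "log_density",
    "loglik",
    "score_contrib",
    "expected_info",
    "sample_beta",
    "moment_start",
    "fit_mle",
]

#: floor / ceiling applied to the moment-based precision start
PHI_START_FLOOR = 1e-2
PHI_START_CEIL = 1e6

#: convergence tolerance: sup-norm of the mean-log-likelihood gradient in
#: (logit mu, log phi) coordinates
GRAD_TOL = 1e-8


class DomainError(ValueError):
    """Raised when an observation or parameter lies outside its domain."""


class DegenerateSampleError(ValueError):
    """Raised when a sample has zero variance (moment start undefined)."""


@dataclass(frozen=True)
class ThetaMP:
    """Beta parameter pair (mean ``mu``, precision ``phi``)."""

    mu: float
    phi: float

    def __post_init__(self) -> None:
        mu, phi = float(self.mu), float(self.phi)
        if not (0.0 < mu < 1.0) or not np.isfinite(mu):
            raise DomainError(f"mu must lie in (0, 1), got {self.mu!r}")
        if not (phi > 0.0) or not np.isfinite(phi):
            raise DomainError(f"phi must be positive, got {self.phi!r}")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "phi", phi)

    @property
    def variance(self) -> float:
        """Implied variance mu*(1-mu)/(1+phi)."""
        return self.mu * (1.0 - self.mu) / (1.0 + self.phi)

    def as_array(self) -> np.ndarray:
        return np.array([self.mu, self.phi])


class FractionalSample:
    """An i.i.d. sample of observations strictly inside (0, 1).

    Caches the transforms ``ystar = log(y/(1-y))`` and ``ydag = log(1-y)``
    through which the beta log-likelihood sees the data.
    """

    __slots__ = ("values", "_ystar", "_ydag")

    def __init__(self, values) -> None:
        y = np.asarray(values, dtype=float)
        if y.ndim != 1:
            raise DomainError("sample must be one-dimensional")
        if y.size < 2:
            raise DomainError("sample must contain at least two observations")
        if not np.all((y > 0.0) & (y < 1.0)):
            raise DomainError("all observations must lie strictly in (0, 1)")
        self.values = y
        self._ystar = None
        self._ydag = None

    @property
    def n(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.values.size

    @property
    def ystar(self) -> np.ndarray:
        if self._ystar is None:
            self._ystar = special.logit(self.values)
        return self._ystar

    @property
    def ydag(self) -> np.ndarray:
        if self._ydag is None:
            self._ydag = np.log1p(-self.values)
        return self._ydag


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    theta_hat: ThetaMP
    loglik: float
    converged: bool
    n_iter: int
    start: ThetaMP
    se: np.ndarray | None = None
    se_method: str | None = None
    family: str = "beta"
    grad_norm: float = field(default=np.nan)


# ---------------------------------------------------------------------------
# expectations of the data transforms and the (w, c) information scalars
# ---------------------------------------------------------------------------

def _mustar(mu, phi):
    return psi(mu * phi) - psi((1.0 - mu) * phi)


def _mudag(mu, phi):
    return psi((1.0 - mu) * phi) - psi(phi)


def _w(mu, phi):
    return polygamma(1, mu * phi) + polygamma(1, (1.0 - mu) * phi)


def _c(mu, phi):
    return phi * (mu * _w(mu, phi) - polygamma(1, (1.0 - mu) * phi))


def log_density(y: float, theta: ThetaMP) -> float:
    """Log of the beta density at ``y`` under ``theta``."""
    y = float(y)
    if not (0.0 < y < 1.0):
        raise DomainError(f"y must lie strictly in (0, 1), got {y!r}")
    mu, phi = theta.mu, theta.phi
    ystar = np.log(y) - np.log1p(-y)
    ydag = np.log1p(-y)
    return float(
        gammaln(phi)
        - gammaln(mu * phi)
        - gammaln((1.0 - mu) * phi)
        + (mu * phi - 1.0) * ystar
        + (phi - 2.0) * ydag
    )


def loglik(sample: FractionalSample, theta: ThetaMP) -> float:
    """Total log-likelihood of ``sample`` under ``theta``."""
    mu, phi = theta.mu, theta.phi
    n = sample.n
    return float(
        n * (gammaln(phi) - gammaln(mu * phi) - gammaln((1.0 - mu) * phi))
        + (mu * phi - 1.0) * sample.ystar.sum()
        + (phi - 2.0) * sample.ydag.sum()
    )


def score_contrib(y, theta: ThetaMP) -> np.ndarray:
    """Per-observation score vector(s) (d/dmu, d/dphi) at ``theta``.

    Accepts a scalar or an array of observations; returns shape ``(..., 2)``.
    """
    y = np.asarray(y, dtype=float)
    if not np.all((y > 0.0) & (y < 1.0)):
        raise DomainError("observations must lie strictly in (0, 1)")
    mu, phi = theta.mu, theta.phi
    ystar = special.logit(y)
    ydag = np.log1p(-y)
    a = ystar - _mustar(mu, phi)
    b = ydag - _mudag(mu, phi)
    return np.stack([phi * a, mu * a + b], axis=-1)


def expected_info(theta: ThetaMP) -> np.ndarray:
    """Fisher information matrix B(theta) for a single observation."""
    mu, phi = theta.mu, theta.phi
    w = _w(mu, phi)
    c = _c(mu, phi)
    b_pp = mu * c / phi + (1.0 - mu) * polygamma(1, (1.0 - mu) * phi) - polygamma(1, phi)
    return np.array([[phi * phi * w, c], [c, b_pp]])


def sample_beta(theta: ThetaMP, n: int, rng: np.random.Generator) -> FractionalSample:
    """Draw ``n`` i.i.d. observations from the beta law at ``theta``.

    Variates are generated by the gamma-ratio construction of the underlying
    generator; draws that round to the boundary in floating point (possible
    only for extreme shapes) are nudged into the open interval.
    """
    if n < 1:
        raise DomainError("n must be at least 1")
    y = rng.beta(theta.mu * theta.phi, (1.0 - theta.mu) * theta.phi, size=int(n))
    tiny = np.finfo(float).tiny
    np.clip(y, tiny, 1.0 - 1e-16, out=y)
    return FractionalSample(y)


def moment_start(sample: FractionalSample) -> ThetaMP:
    """Method-of-moments starting values (ybar, ybar(1-ybar)/Var - 1).

    The variance uses the (n-1) denominator.  The precision component is
    clipped into [PHI_START_FLOOR, PHI_START_CEIL] so the start is always a
    valid parameter point.
    """
    y = sample.values
    ybar = float(y.mean())
    v = float(y.var(ddof=1))
    if v <= 0.0:
        raise DegenerateSampleError("sample variance is zero")
    phi0 = ybar * (1.0 - ybar) / v - 1.0
    phi0 = float(np.clip(phi0, PHI_START_FLOOR, PHI_START_CEIL))
    return ThetaMP(ybar, phi0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _mean_loglik_eta(eta1, eta2, mstar, mdag):
    """Mean log-likelihood at (logit mu, log phi) = (eta1, eta2)."""
    mu = expit(eta1)
    phi = np.exp(eta2)
    return (
        gammaln(phi)
        - gammaln(mu * phi)
        - gammaln((1.0 - mu) * phi)
        + (mu * phi - 1.0) * mstar
        + (phi - 2.0) * mdag
    )


def _mean_grad_eta(eta1, eta2, mstar, mdag):
    """Gradient of the mean log-likelihood in (eta1, eta2)."""
    mu = expit(eta1)
    phi = np.exp(eta2)
    a = mstar - _mustar(mu, phi)
    b = mdag - _mudag(mu, phi)
    g_mu = phi * a
    g_phi = mu * a + b
    return g_mu * mu * (1.0 - mu), g_phi * phi


_ETA2_MAX = 18.0  # cap on log(phi) during iteration; phi ~ 6.6e7


def _fit_many(mstar, mdag, mu0, phi0, gtol=GRAD_TOL, max_iter=200):
    """Fisher-scoring MLE for a batch of samples given sufficient statistics.

    Parameters are arrays of per-sample mean ystar, mean ydag and starting
    values.  Returns ``(mu, phi, converged, n_iter)``.  Each step solves the
    2x2 expected-information system in (logit mu, log phi) coordinates and
    backtracks (step halving) on the mean log-likelihood.
    """
    mstar = np.asarray(mstar, dtype=float)
    mdag = np.asarray(mdag, dtype=float)
    eta1 = special.logit(np.asarray(mu0, dtype=float)).copy()
    eta2 = np.log(np.asarray(phi0, dtype=float)).copy()
    m = eta1.shape[0]
    converged = np.zeros(m, dtype=bool)
    n_iter = np.zeros(m, dtype=np.int32)

    f = _mean_loglik_eta(eta1, eta2, mstar, mdag)
    for _ in range(max_iter):
        g1, g2 = _mean_grad_eta(eta1, eta2, mstar, mdag)
        newly = (np.abs(g1) <= gtol) & (np.abs(g2) <= gtol) & ~converged
        converged |= newly
        act = ~converged
        if not act.any():
            break
        mu = expit(eta1[act])
        phi = np.exp(eta2[act])
        w = polygamma(1, mu * phi) + polygamma(1, (1.0 - mu) * phi)
        c = phi * (mu * w - polygamma(1, (1.0 - mu) * phi))
        b_pp = mu * c / phi + (1.0 - mu) * polygamma(1, (1.0 - mu) * phi) - polygamma(1, phi)
        j1 = mu * (1.0 - mu)
        j2 = phi
        i11 = j1 * j1 * (phi * phi * w)
        i12 = j1 * j2 * c
        i22 = j2 * j2 * b_pp
        det = i11 * i22 - i12 * i12
        # guard: fall back to a gradient step when the 2x2 system is bad
        bad = ~np.isfinite(det) | (det <= 0.0)
        ga1 = g1[act]
        ga2 = g2[act]
        s1 = np.where(bad, ga1, (i22 * ga1 - i12 * ga2) / det)
        s2 = np.where(bad, ga2, (i11 * ga2 - i12 * ga1) / det)

        # backtracking on the mean log-likelihood
        step = np.ones(s1.shape[0])
        e1_old = eta1[act]
        e2_old = eta2[act]
        f_old = f[act]
        e1_new = e1_old + s1
        e2_new = np.minimum(e2_old + s2, _ETA2_MAX)
        f_new = _mean_loglik_eta(e1_new, e2_new, mstar[act], mdag[act])
        # accept up to a rounding-level decrease so the polish does not stall
        # when the improvement falls below float precision near the optimum
        slack = 1e-13 * (np.abs(f_old) + 1.0)
        for _half in range(40):
            worse = ~np.isfinite(f_new) | (f_new < f_old - slack)
            if not worse.any():
                break
            step[worse] *= 0.5
            e1_new = np.where(worse, e1_old + step * s1, e1_new)
            e2_new = np.where(worse, np.minimum(e2_old + step * s2, _ETA2_MAX), e2_new)
            f_new = np.where(
                worse, _mean_loglik_eta(e1_new, e2_new, mstar[act], mdag[act]), f_new
            )
        keep = np.isfinite(f_new) & (f_new >= f_old - slack)
        eta1[act] = np.where(keep, e1_new, e1_old)
        eta2[act] = np.where(keep, e2_new, e2_old)
        f[act] = np.where(keep, f_new, f_old)
        n_iter[act] += 1

    # samples stuck at the precision cap are not trusted
    converged &= eta2 < _ETA2_MAX - 1e-9
    return expit(eta1), np.exp(eta2), converged, n_iter


def fit_mle(
    sample: FractionalSample,
    start: ThetaMP | None = None,
    gtol: float = GRAD_TOL,
    max_iter: int = 500,
    se_method: str | None = "expected_info",
) -> FitResult:
    """Maximum-likelihood fit of the mean-precision beta model.

    BFGS with the analytic score, run on the mean log-likelihood in
    (logit mu, log phi) coordinates starting from :func:`moment_start`,
    followed by a Fisher-scoring polish that enforces the gradient
    tolerance.  Standard errors (when requested) come from the inverse of
    ``n * expected_info(theta_hat)``.
    """
    if start is None:
        start = moment_start(sample)
    mstar = float(sample.ystar.mean())
    mdag = float(sample.ydag.mean())

    def neg_f(eta):
        val = _mean_loglik_eta(eta[0], eta[1], mstar, mdag)
        return -val if np.isfinite(val) else np.inf

    def neg_g(eta):
        g1, g2 = _mean_grad_eta(eta[0], eta[1], mstar, mdag)
        return -np.array([g1, g2])

    eta0 = np.array([special.logit(start.mu), np.log(start.phi)])
    res = optimize.minimize(
        neg_f, eta0, jac=neg_g, method="BFGS",
        options={"gtol": gtol, "maxiter": max_iter},
    )
    # Fisher-scoring polish: BFGS can stop on line-search precision loss
    # before the gradient tolerance is met.
    mu_v, phi_v, conv, extra = _fit_many(
        np.array([mstar]), np.array([mdag]),
        np.array([expit(res.x[0])]), np.array([np.exp(res.x[1])]),
        gtol=gtol, max_iter=100,
    )
    mu_hat, phi_hat = float(mu_v[0]), float(phi_v[0])
    g1, g2 = _mean_grad_eta(special.logit(mu_hat), np.log(phi_hat), mstar, mdag)
    gnorm = float(max(abs(g1), abs(g2)))
    converged = bool(conv[0]) and gnorm <= gtol
    theta_hat = ThetaMP(mu_hat, phi_hat)
    ll = loglik(sample, theta_hat)

    se = None
    if se_method == "expected_info":
        info = sample.n * expected_info(theta_hat)
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    return FitResult(
        theta_hat=theta_hat,
        loglik=ll,
        converged=converged,
        n_iter=int(res.nit) + int(extra[0]),
        start=start,
        se=se,
        se_method=se_method if se is not None else None,
        grad_norm=gnorm,
    )
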