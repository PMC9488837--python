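"""Information-matrix misspecification tests for the beta model.

Under correct specification the expected Hessian ``A(theta0)`` of the
individual log-likelihood and the expected score outer product ``B(theta0)``
satisfy ``A + B = 0``.  The tests are built on the half-vectorised sample
counterpart of that sum,

    Dn(theta) = (1/n) sum_t d(theta; Y_t),
    d = vech(Hessian_t + score_t score_t'),

a 3-vector whose components d1, d2, d3 correspond to the (mu,mu), (mu,phi)
and (phi,phi) entries.  Evaluated at the MLE, sqrt(n) Dn is asymptotically
normal with covariance V(theta0), and quadratic forms

    zeta = n * Dn' V^{-1} Dn

are chi-square (q degrees of freedom) when V is estimated by the White
estimator Vn1 or the Chesher-Lancaster estimator Vn2 (no third-order
derivatives), and Hotelling T-squared with (q, B-1) degrees of freedom when V
is the parametric-bootstrap covariance estimator built from B refits.  By
default q = 2 restrictions are tested (d1, d2): the third component is
numerically near-degenerate and renders the 3-restriction covariance
estimates near singular; q = 3 stays available behind the explicit argument.

The chi-square tests are size-distorted in small samples, so their
parametric-bootstrap critical-value versions (zeta1B, zeta2B) are also
provided: each bootstrap resample from the fitted beta law is refitted and
the full statistic, including its covariance estimator, is recomputed at the
resample's own MLE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats
from scipy.special import polygamma, psi

from betaimt.betadist import (
    DomainError,
    FractionalSample,
    ThetaMP,
    _fit_many,
    fit_mle,
    moment_start,
)

__all__ = [
    "AuxQuantities",
    "RestrictionSet",
    "CovEstimate",
    "TestResult",
    "SingularCovarianceError",
    "BootstrapFailureError",
    "aux_quantities",
    "d_contrib",
    "restriction_set",
    "v_n1",
    "v_n2",
    "bootstrap_cov",
    "zeta_statistic",
    "test_asymptotic",
    "test_zeta3",
    "test_bootstrap_critical",
    "hotelling_sf",
]

#: condition number beyond which a covariance estimate is treated as singular
COND_THRESHOLD = 1e12

#: hard cap on redraws of failed bootstrap refits, as a multiple of B
MAX_REDRAW_FACTOR = 10


class SingularCovarianceError(np.linalg.LinAlgError):
    """A covariance estimate is numerically singular (condition > 1e12)."""


class BootstrapFailureError(RuntimeError):
    """Too many bootstrap refits failed to converge."""


@dataclass(frozen=True)
class AuxQuantities:
    """Scalar building blocks of the test machinery at a given theta.

    ``mustar``/``mudag`` are the expectations of the data transforms,
    ``w = psi'(mu phi) + psi'((1-mu) phi)``,
    ``c = phi (mu w - psi'((1-mu) phi))``,
    ``m = psi''(mu phi) - psi''((1-mu) phi)``, together with the partial
    derivatives needed for the analytic Jacobian of Dn.
    """

    mustar: float
    mudag: float
    w: float
    c: float
    m: float
    dmustar_dmu: float
    dmustar_dphi: float
    d2mustar_dphi2: float
    dmudag_dmu: float
    dmudag_dphi: float
    dw_dmu: float
    dw_dphi: float
    dc_dmu: float
    dc_dphi: float


@dataclass
class RestrictionSet:
    """Per-observation d-vectors, their average and analytic Jacobian."""

    contribs: np.ndarray  # (n, 3)
    Dn: np.ndarray        # (3,)
    gradDn: np.ndarray    # (3, 2)
    q: int
    active_index: np.ndarray

    @property
    def Dn_active(self) -> np.ndarray:
        return self.Dn[self.active_index]

    @property
    def gradDn_active(self) -> np.ndarray:
        return self.gradDn[self.active_index]


@dataclass
class CovEstimate:
    """A q x q covariance estimate of sqrt(n) * Dn with provenance."""

    matrix: np.ndarray
    method: str  # "vn1" | "vn2" | "bootstrap"
    B: int | None = None
    condition: float = np.nan
    n_redraws: int = 0

    @property
    def is_singular(self) -> bool:
        return not np.isfinite(self.condition) or self.condition > COND_THRESHOLD


@dataclass
class TestResult:
    """Outcome of a misspecification test."""

    name: str          # zeta1 | zeta1B | zeta2 | zeta2B | zeta3
    statistic: float
    q: int
    reference: str     # chisq_q | hotelling_q_Bminus1 | bootstrap_empirical
    p_value: float
    B: int | None = None
    boot_stats: np.ndarray | None = field(default=None, repr=False)
    seed: int | None = None

    def reject(self, alpha: float) -> bool:
        """Accept/reject decision at level ``alpha``.

        Bootstrap-critical-value tests use the empirical 1-alpha quantile of
        the replicates (the ceil((1-alpha)B)-th order statistic); the others
        compare the p-value with alpha.
        """
        if self.reference == "bootstrap_empirical":
            b = len(self.boot_stats)
            k = int(np.ceil((1.0 - alpha) * b))
            crit = np.sort(self.boot_stats)[k - 1]
            return bool(self.statistic > crit)
        return bool(self.p_value <= alpha)

    def to_record(self) -> dict:
        return {
            "name": self.name,
            "statistic": float(self.statistic),
            "q": int(self.q),
            "reference": self.reference,
            "p_value": float(self.p_value),
            "B": None if self.B is None else int(self.B),
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# scalar machinery
# ---------------------------------------------------------------------------

def aux_quantities(theta: ThetaMP) -> AuxQuantities:
    """All scalar quantities and partial derivatives at ``theta``."""
    mu, phi = theta.mu, theta.phi
    p1m = polygamma(1, (1.0 - mu) * phi)
    p1mu = polygamma(1, mu * phi)
    p2m = polygamma(2, (1.0 - mu) * phi)
    p2mu = polygamma(2, mu * phi)
    w = p1mu + p1m
    c = phi * (mu * w - p1m)
    m = p2mu - p2m
    dmustar_dmu = phi * w
    dmustar_dphi = c / phi
    d2mustar_dphi2 = mu * mu * p2mu - (1.0 - mu) ** 2 * p2m
    dmudag_dmu = -phi * p1m
    dmudag_dphi = (1.0 - mu) * p1m - polygamma(1, phi)
    dw_dmu = phi * m
    dw_dphi = mu * p2mu + (1.0 - mu) * p2m
    dc_dmu = phi * (w + phi * dw_dphi)
    dc_dphi = dmustar_dphi + phi * d2mustar_dphi2
    return AuxQuantities(
        mustar=float(psi(mu * phi) - psi((1.0 - mu) * phi)),
        mudag=float(psi((1.0 - mu) * phi) - psi(phi)),
        w=float(w), c=float(c), m=float(m),
        dmustar_dmu=float(dmustar_dmu), dmustar_dphi=float(dmustar_dphi),
        d2mustar_dphi2=float(d2mustar_dphi2),
        dmudag_dmu=float(dmudag_dmu), dmudag_dphi=float(dmudag_dphi),
        dw_dmu=float(dw_dmu), dw_dphi=float(dw_dphi),
        dc_dmu=float(dc_dmu), dc_dphi=float(dc_dphi),
    )


def d_contrib(y, theta: ThetaMP) -> np.ndarray:
    """Per-observation restriction vector (d1, d2, d3) at ``theta``.

    d1 = phi^2 [(y* - mu*)^2 - w]
    d2 = (y* - mu*) - c + phi (y* - mu*) [mu (y* - mu*) + (ydag - mudag)]
    d3 = -mu c/phi - (1-mu) psi'((1-mu) phi) + psi'(phi)
         + [mu (y* - mu*) + (ydag - mudag)]^2
    """
    y = np.asarray(y, dtype=float)
    if not np.all((y > 0.0) & (y < 1.0)):
        raise DomainError("observations must lie strictly in (0, 1)")
    mu, phi = theta.mu, theta.phi
    aux = aux_quantities(theta)
    a = special.logit(y) - aux.mustar
    s = mu * a + (np.log1p(-y) - aux.mudag)
    d1 = phi * phi * (a * a - aux.w)
    d2 = a - aux.c + phi * a * s
    a_pp = -mu * aux.c / phi - (1.0 - mu) * polygamma(1, (1.0 - mu) * phi) + polygamma(1, phi)
    d3 = a_pp + s * s
    return np.stack([d1, d2, d3], axis=-1)


def _grad_dn(y, mu, phi):
    """Analytic 3x2 Jacobian of Dn, averaged over the observations.

    ``y`` has shape (n,) with scalar parameters, or (m, n) with parameter
    vectors of length m.  Returns shape (3, 2) or (m, 3, 2) accordingly.
    """
    single = np.ndim(y) == 1
    y = np.atleast_2d(np.asarray(y, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))[:, None]
    phi = np.atleast_1d(np.asarray(phi, dtype=float))[:, None]

    p1m = polygamma(1, (1.0 - mu) * phi)
    p2m = polygamma(2, (1.0 - mu) * phi)
    p2mu = polygamma(2, mu * phi)
    w = polygamma(1, mu * phi) + p1m
    c = phi * (mu * w - p1m)
    m_ = p2mu - p2m
    dmustar_dmu = phi * w
    dmustar_dphi = c / phi
    d2mustar_dphi2 = mu * mu * p2mu - (1.0 - mu) ** 2 * p2m
    dmudag_dmu = -phi * p1m
    dmudag_dphi = (1.0 - mu) * p1m - polygamma(1, phi)
    dw_dmu = phi * m_
    dw_dphi = mu * p2mu + (1.0 - mu) * p2m
    dc_dmu = phi * (w + phi * dw_dphi)
    dc_dphi = dmustar_dphi + phi * d2mustar_dphi2

    a = special.logit(y) - (psi(mu * phi) - psi((1.0 - mu) * phi))
    s = mu * a + (np.log1p(-y) - (psi((1.0 - mu) * phi) - psi(phi)))

    d11 = phi * phi * (-dw_dmu - 2.0 * a * dmustar_dmu)
    d12 = 2.0 * phi * (a * a - w) + phi * phi * (-2.0 * a * dmustar_dphi - dw_dphi)
    d21 = (
        -dmustar_dmu - dc_dmu
        - phi * dmustar_dmu * s
        + phi * a * (a - mu * dmustar_dmu - dmudag_dmu)
    )
    d22 = (
        -dmustar_dphi - dc_dphi
        + a * s
        - phi * dmustar_dphi * s
        - phi * a * (mu * dmustar_dphi + dmudag_dphi)
    )
    d31 = (
        -c / phi - mu / phi * dc_dmu
        + p1m + (1.0 - mu) * phi * p2m
        + 2.0 * s * (a - mu * dmustar_dmu - dmudag_dmu)
    )
    d32 = (
        mu * c / (phi * phi) - mu / phi * dc_dphi
        - (1.0 - mu) ** 2 * p2m + polygamma(2, phi)
        - 2.0 * s * (mu * dmustar_dphi + dmudag_dphi)
    )
    rows = [
        np.stack([d11.mean(axis=-1), d12.mean(axis=-1)], axis=-1),
        np.stack([d21.mean(axis=-1), d22.mean(axis=-1)], axis=-1),
        np.stack([d31.mean(axis=-1), d32.mean(axis=-1)], axis=-1),
    ]
    out = np.stack(rows, axis=-2)
    return out[0] if single else out


def restriction_set(sample: FractionalSample, theta: ThetaMP, q: int = 2) -> RestrictionSet:
    """Per-observation restriction vectors, their average Dn and Jacobian.

    ``q = 2`` (default) retains the (d1, d2) components and drops the third
    row of the Jacobian; ``q = 3`` keeps everything; ``q = 1`` keeps only d1.
    """
    if q not in (1, 2, 3):
        raise ValueError(f"q must be 1, 2 or 3, got {q!r}")
    contribs = d_contrib(sample.values, theta)
    dn = contribs.mean(axis=0)
    grad = _grad_dn(sample.values, theta.mu, theta.phi)
    return RestrictionSet(
        contribs=contribs,
        Dn=dn,
        gradDn=grad,
        q=q,
        active_index=np.arange(q),
    )


# ---------------------------------------------------------------------------
# covariance estimators
# ---------------------------------------------------------------------------

def _an_matrix(sample: FractionalSample, theta: ThetaMP) -> np.ndarray:
    """Sample average of the per-observation Hessian, An(theta; Y)."""
    mu, phi = theta.mu, theta.phi
    aux = aux_quantities(theta)
    a_mean = float((sample.ystar - aux.mustar).mean())
    a_pp = -mu * aux.c / phi - (1.0 - mu) * polygamma(1, (1.0 - mu) * phi) + polygamma(1, phi)
    return np.array([
        [-phi * phi * aux.w, a_mean - aux.c],
        [a_mean - aux.c, a_pp],
    ])


def _bn_matrix(sample: FractionalSample, theta: ThetaMP) -> np.ndarray:
    """Sample average of the score outer product, Bn(theta; Y)."""
    mu, phi = theta.mu, theta.phi
    aux = aux_quantities(theta)
    a = sample.ystar - aux.mustar
    s = mu * a + (sample.ydag - aux.mudag)
    return np.array([
        [phi * phi * float((a * a).mean()), phi * float((a * s).mean())],
        [phi * float((a * s).mean()), float((s * s).mean())],
    ])


def _cond2(mat: np.ndarray) -> float:
    return float(np.linalg.cond(mat))


def v_n1(sample: FractionalSample, theta: ThetaMP, rs: RestrictionSet) -> CovEstimate:
    """White's covariance estimator Vn1 on the active restriction components.

    Vn1 = (1/n) sum_t r_t r_t' with
    r_t = d_t - gradDn An^{-1} score_t.
    """
    an = _an_matrix(sample, theta)
    if abs(np.linalg.det(an)) < 1e-300 or _cond2(an) > COND_THRESHOLD:
        raise SingularCovarianceError(
            f"An(theta) is numerically singular (cond={_cond2(an):.3e})"
        )
    mu, phi = theta.mu, theta.phi
    aux = aux_quantities(theta)
    a = sample.ystar - aux.mustar
    s_phi = mu * a + (sample.ydag - aux.mudag)
    scores = np.stack([phi * a, s_phi], axis=-1)         # (n, 2)
    g = rs.gradDn_active                                  # (q, 2)
    proj = scores @ np.linalg.solve(an, g.T)              # (n, q)
    r = rs.contribs[:, rs.active_index] - proj
    mat = r.T @ r / sample.n
    return CovEstimate(matrix=mat, method="vn1", condition=_cond2(mat))


def v_n2(sample: FractionalSample, theta: ThetaMP, rs: RestrictionSet) -> CovEstimate:
    """Chesher-Lancaster covariance estimator Vn2 (no third derivatives).

    Uses Ln = -(1/n) sum_t d_t score_t' in place of the analytic Jacobian:
    r_t = d_t + Ln Bn^{-1} score_t.
    """
    bn = _bn_matrix(sample, theta)
    if abs(np.linalg.det(bn)) < 1e-300 or _cond2(bn) > COND_THRESHOLD:
        raise SingularCovarianceError(
            f"Bn(theta) is numerically singular (cond={_cond2(bn):.3e})"
        )
    mu, phi = theta.mu, theta.phi
    aux = aux_quantities(theta)
    a = sample.ystar - aux.mustar
    s_phi = mu * a + (sample.ydag - aux.mudag)
    scores = np.stack([phi * a, s_phi], axis=-1)
    d_act = rs.contribs[:, rs.active_index]
    ln = -(d_act.T @ scores) / sample.n                   # (q, 2)
    proj = scores @ np.linalg.solve(bn, ln.T)             # (n, q)
    r = d_act + proj
    mat = r.T @ r / sample.n
    return CovEstimate(matrix=mat, method="vn2", condition=_cond2(mat))


def zeta_statistic(rs: RestrictionSet, cov: CovEstimate, n: int) -> float:
    """Quadratic form n * Dn' V^{-1} Dn over the active components."""
    if cov.is_singular:
        raise SingularCovarianceError(
            f"covariance estimate is singular (cond={cov.condition:.3e})"
        )
    dn = rs.Dn_active
    return float(n * dn @ np.linalg.solve(cov.matrix, dn))


def hotelling_sf(t2: float, q: int, m: int) -> float:
    """Upper tail of Hotelling's T-squared with (q, m) degrees of freedom.

    Uses the exact scaled-F representation:
    T2 * (m - q + 1) / (q m) ~ F(q, m - q + 1).
    """
    f_stat = t2 * (m - q + 1) / (q * m)
    return float(stats.f.sf(f_stat, q, m - q + 1))


# ---------------------------------------------------------------------------
# batched internals (used by the bootstrap and the Monte Carlo harness)
# ---------------------------------------------------------------------------

def _dn_batch(y, mu, phi, q=2):
    """Dn over the active components for a batch of samples.

    ``y``: (m, n); ``mu``, ``phi``: (m,).  Returns (m, q).
    """
    mu_ = mu[:, None]
    phi_ = phi[:, None]
    p1m = polygamma(1, (1.0 - mu) * phi)
    w = polygamma(1, mu * phi) + p1m
    c = phi * (mu * w - p1m)
    mustar = psi(mu * phi) - psi((1.0 - mu) * phi)
    mudag = psi((1.0 - mu) * phi) - psi(phi)
    a = special.logit(y) - mustar[:, None]
    s = mu_ * a + (np.log1p(-y) - mudag[:, None])
    d1 = (phi * phi)[:, None] * (a * a - w[:, None])
    d2 = a - c[:, None] + phi_ * a * s
    cols = [d1.mean(axis=1), d2.mean(axis=1)]
    if q >= 3:
        a_pp = -mu * c / phi - (1.0 - mu) * p1m + polygamma(1, phi)
        d3 = a_pp[:, None] + s * s
        cols.append(d3.mean(axis=1))
    return np.stack(cols[:q], axis=-1) if q != 1 else cols[0][:, None]


def _zeta_batch(y, mu, phi, q=2, variant="vn1"):
    """Dn, covariance and zeta statistic for a batch of samples.

    Vectorised transcription of ``v_n1``/``v_n2`` + ``zeta_statistic``.
    Returns ``(zeta, ok)`` where ``ok`` flags a well-conditioned covariance.
    Only q in {1, 2} is supported here (the default restriction choice).
    """
    if q not in (1, 2):
        raise ValueError("batched path supports q in {1, 2}")
    m, n = y.shape
    mu_ = mu[:, None]
    phi_ = phi[:, None]
    p1m = polygamma(1, (1.0 - mu) * phi)
    w = polygamma(1, mu * phi) + p1m
    c = phi * (mu * w - p1m)
    mustar = psi(mu * phi) - psi((1.0 - mu) * phi)
    mudag = psi((1.0 - mu) * phi) - psi(phi)
    a = special.logit(y) - mustar[:, None]
    sph = mu_ * a + (np.log1p(-y) - mudag[:, None])
    a_pp = -mu * c / phi - (1.0 - mu) * p1m + polygamma(1, phi)

    d1 = (phi * phi)[:, None] * (a * a - w[:, None])
    d2 = a - c[:, None] + phi_ * a * sph
    d = np.stack([d1, d2], axis=-1)[..., :q]              # (m, n, q)
    dn = d.mean(axis=1)                                   # (m, q)
    scores = np.stack([phi_ * a, sph], axis=-1)           # (m, n, 2)

    if variant == "vn1":
        grad = _grad_dn(y, mu, phi)[:, :q, :]             # (m, q, 2)
        an = np.empty((m, 2, 2))
        a_mean = a.mean(axis=1)
        an[:, 0, 0] = -phi * phi * w
        an[:, 0, 1] = an[:, 1, 0] = a_mean - c
        an[:, 1, 1] = a_pp
        coef = np.linalg.solve(an, np.swapaxes(grad, 1, 2))   # (m, 2, q)
        r = d - np.einsum("mnj,mjk->mnk", scores, coef)
    elif variant == "vn2":
        bn = np.empty((m, 2, 2))
        bn[:, 0, 0] = (phi * phi) * (a * a).mean(axis=1)
        bn[:, 0, 1] = bn[:, 1, 0] = phi * (a * sph).mean(axis=1)
        bn[:, 1, 1] = (sph * sph).mean(axis=1)
        ln = -np.einsum("mnk,mnj->mkj", d, scores) / n        # (m, q, 2)
        coef = np.linalg.solve(bn, np.swapaxes(ln, 1, 2))     # (m, 2, q)
        r = d + np.einsum("mnj,mjk->mnk", scores, coef)
    else:
        raise ValueError(f"unknown variant {variant!r}")

    v = np.einsum("mnk,mnl->mkl", r, r) / n               # (m, q, q)
    if q == 1:
        vdet = v[:, 0, 0]
        ok = np.isfinite(vdet) & (vdet > 0)
        zeta = np.where(ok, n * dn[:, 0] ** 2 / np.where(ok, vdet, 1.0), np.nan)
        return zeta, ok
    tr = v[:, 0, 0] + v[:, 1, 1]
    det = v[:, 0, 0] * v[:, 1, 1] - v[:, 0, 1] * v[:, 1, 0]
    disc = np.sqrt(np.maximum(tr * tr / 4.0 - det, 0.0))
    lmax = tr / 2.0 + disc
    lmin = tr / 2.0 - disc
    ok = np.isfinite(det) & (lmin > 0) & (lmax < COND_THRESHOLD * lmin)
    safe_det = np.where(det != 0, det, 1.0)
    quad = (
        dn[:, 0] * (v[:, 1, 1] * dn[:, 0] - v[:, 0, 1] * dn[:, 1])
        + dn[:, 1] * (v[:, 0, 0] * dn[:, 1] - v[:, 1, 0] * dn[:, 0])
    ) / safe_det
    zeta = np.where(ok, n * quad, np.nan)
    return zeta, ok


def _fit_batch_samples(y, gtol=1e-8):
    """Batched MLE over rows of ``y`` (m, n); returns mu, phi, converged."""
    ybar = y.mean(axis=1)
    yvar = y.var(axis=1, ddof=1)
    phi0 = np.clip(ybar * (1.0 - ybar) / np.maximum(yvar, 1e-300) - 1.0, 1e-2, 1e6)
    mstar = special.logit(y).mean(axis=1)
    mdag = np.log1p(-y).mean(axis=1)
    mu, phi, conv, _ = _fit_many(mstar, mdag, ybar, phi0, gtol=gtol)
    return mu, phi, conv


def _draw_beta(rng, mu, phi, size):
    y = rng.beta(mu * phi, (1.0 - mu) * phi, size=size)
    tiny = np.finfo(float).tiny
    return np.clip(y, tiny, 1.0 - 1e-16)


def _bootstrap_replicates(theta_hat, n, B, rng, compute, min_keep=None):
    """Run ``compute`` on B parametric-bootstrap refits, redrawing failures.

    ``compute(y, mu, phi)`` maps a batch of samples and their fitted
    parameters to ``(values, ok)``.  A replicate whose refit does not
    converge, or whose ``compute`` flags it, is replaced by a freshly drawn
    resample, up to MAX_REDRAW_FACTOR * B extra draws.  Returns
    ``(values, n_redraws)`` with exactly B rows.
    """
    mu0, phi0 = theta_hat.mu, theta_hat.phi
    y = _draw_beta(rng, mu0, phi0, (B, n))
    mu, phi, conv = _fit_batch_samples(y)
    vals, ok = compute(y, mu, phi)
    ok = ok & conv
    redraws = 0
    budget = MAX_REDRAW_FACTOR * B
    while not ok.all():
        bad = np.flatnonzero(~ok)
        if redraws + bad.size > budget:
            raise BootstrapFailureError(
                f"more than {budget} bootstrap refits failed to converge"
            )
        redraws += bad.size
        y_new = _draw_beta(rng, mu0, phi0, (bad.size, n))
        mu_new, phi_new, conv_new = _fit_batch_samples(y_new)
        vals_new, ok_new = compute(y_new, mu_new, phi_new)
        ok_new = ok_new & conv_new
        vals[bad] = vals_new
        ok[bad] = ok_new
    return vals, redraws


def bootstrap_cov(
    sample: FractionalSample,
    theta_hat: ThetaMP,
    B: int,
    rng: np.random.Generator,
    q: int = 2,
) -> CovEstimate:
    """Parametric-bootstrap estimator of the exact covariance of sqrt(n) Dn.

    Draws B samples of size n from the fitted beta law, refits each, collects
    Dn at each resample's own MLE, and returns n/(B-1) times the centred
    cross-product matrix of the replicates.
    """
    if B < q + 2:
        raise ValueError(f"B must be at least q+2 = {q + 2}")
    n = sample.n

    def compute(y, mu, phi):
        dns = _dn_batch(y, mu, phi, q=q)
        return dns, np.isfinite(dns).all(axis=1)

    dns, redraws = _bootstrap_replicates(theta_hat, n, B, rng, compute)
    dc = dns - dns.mean(axis=0)
    mat = n * (dc.T @ dc) / (B - 1)
    return CovEstimate(
        matrix=mat, method="bootstrap", B=B,
        condition=_cond2(mat), n_redraws=redraws,
    )


# ---------------------------------------------------------------------------
# the five tests
# ---------------------------------------------------------------------------

def _fit_or_raise(sample: FractionalSample):
    fit = fit_mle(sample, se_method=None)
    if not fit.converged:
        raise RuntimeError("maximum-likelihood fit did not converge")
    return fit


def test_asymptotic(sample: FractionalSample, variant: str, q: int = 2) -> TestResult:
    """zeta1 (White covariance) or zeta2 (Chesher-Lancaster) with the
    chi-square(q) reference distribution."""
    if variant not in ("zeta1", "zeta2"):
        raise ValueError(f"variant must be 'zeta1' or 'zeta2', got {variant!r}")
    fit = _fit_or_raise(sample)
    rs = restriction_set(sample, fit.theta_hat, q=q)
    cov = (v_n1 if variant == "zeta1" else v_n2)(sample, fit.theta_hat, rs)
    stat = zeta_statistic(rs, cov, sample.n)
    return TestResult(
        name=variant, statistic=stat, q=q, reference="chisq_q",
        p_value=float(stats.chi2.sf(stat, q)),
    )


def test_zeta3(
    sample: FractionalSample,
    B: int = 500,
    q: int = 2,
    rng: np.random.Generator | None = None,
) -> TestResult:
    """zeta3: quadratic form in the bootstrap covariance estimate, referred
    to Hotelling's T-squared with (q, B-1) degrees of freedom."""
    rng = np.random.default_rng(rng)
    fit = _fit_or_raise(sample)
    rs = restriction_set(sample, fit.theta_hat, q=q)
    cov = bootstrap_cov(sample, fit.theta_hat, B, rng, q=q)
    stat = zeta_statistic(rs, cov, sample.n)
    return TestResult(
        name="zeta3", statistic=stat, q=q, reference="hotelling_q_Bminus1",
        p_value=hotelling_sf(stat, q, B - 1), B=B,
    )


def test_bootstrap_critical(
    sample: FractionalSample,
    variant: str,
    B: int = 500,
    q: int = 2,
    rng: np.random.Generator | None = None,
) -> TestResult:
    """zeta1B / zeta2B: the asymptotic statistic compared against parametric
    bootstrap critical values.

    Each of the B resamples from the fitted law is refitted and the full
    statistic (including its covariance estimator) is recomputed at the
    resample's own MLE.  The reported p-value uses the plus-one convention
    (1 + #{zeta* >= zeta}) / (B + 1); :meth:`TestResult.reject` applies the
    empirical-quantile rule, and the two decisions coincide away from ties.
    """
    if variant not in ("zeta1B", "zeta2B"):
        raise ValueError(f"variant must be 'zeta1B' or 'zeta2B', got {variant!r}")
    if B < 20:
        raise ValueError("B must be at least 20")
    rng = np.random.default_rng(rng)
    which = "vn1" if variant == "zeta1B" else "vn2"
    fit = _fit_or_raise(sample)
    rs = restriction_set(sample, fit.theta_hat, q=q)
    cov = (v_n1 if which == "vn1" else v_n2)(sample, fit.theta_hat, rs)
    stat = zeta_statistic(rs, cov, sample.n)

    def compute(y, mu, phi):
        return _zeta_batch(y, mu, phi, q=q, variant=which)

    boot, _ = _bootstrap_replicates(fit.theta_hat, sample.n, B, rng, compute)
    p_plus = (1.0 + np.count_nonzero(boot >= stat)) / (B + 1.0)
    return TestResult(
        name=variant, statistic=stat, q=q, reference="bootstrap_empirical",
        p_value=float(p_plus), B=B, boot_stats=boot,
    )
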