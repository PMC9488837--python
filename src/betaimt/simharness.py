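"""Monte Carlo engine for the size and power study.

For each sample size the harness draws ``reps`` independent datasets from a
configured data-generating process, fits the beta model to each, runs the
requested misspecification tests and tabulates rejection rates with their
binomial Monte Carlo standard errors.  Per-replication random streams are
spawned from the master seed, so results do not depend on execution order.

Size mode draws from the beta law itself (the null); power mode draws from
an alternative process.  Because the asymptotic zeta1/zeta2 tests are badly
oversized in small samples, their power is evaluated against *empirical*
critical values extracted from a matching null archive ("size-adjusted"
power); the bootstrap-based tests carry their own reference distributions
and run identically in both modes.  When no null archive is supplied, one is
simulated at the pseudo-true beta parameters — the probability limit of the
MLE under the alternative, estimated here by fitting the beta model to one
large sample from the alternative process.

The raw per-replication statistics are archived, which is what the p-value
plots (empirical size against nominal size) and size-power plots (power at
the empirical critical value of each nominal size) are built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from betaimt.altdist import DGPSpec
from betaimt.betadist import ThetaMP
from betaimt.imtest import (
    _dn_batch,
    _fit_batch_samples,
    _zeta_batch,
    hotelling_sf,
)

__all__ = [
    "SimConfig",
    "RejectionTable",
    "CurveData",
    "run_size",
    "run_power",
    "empirical_critical_values",
    "pseudo_true_beta",
    "curve_data",
    "PROFILES",
]

ALL_TESTS = ("zeta1", "zeta1B", "zeta2", "zeta2B", "zeta3")

#: replication profiles: the paper-scale study and a desk-scale variant
PROFILES = {"paper": {"reps": 5000, "boot_B": 500}, "desk": {"reps": 1000, "boot_B": 249}}


@dataclass
class SimConfig:
    """Configuration of one simulation experiment."""

    dgp: DGPSpec
    n_grid: list
    alpha_grid: list
    reps: int = 1000
    boot_B: int = 249
    tests: tuple = ALL_TESTS
    seed: int = 0
    mode: str = "size"
    null_params: ThetaMP | None = None
    q: int = 2

    def __post_init__(self) -> None:
        if self.mode not in ("size", "power"):
            raise ValueError(f"mode must be 'size' or 'power', got {self.mode!r}")
        if self.mode == "size" and self.dgp.family != "beta":
            raise ValueError("size mode requires a beta data-generating process")
        if self.reps < 100:
            raise ValueError("at least 100 replications are required for a reported rate")
        if not all(0.0 < a < 1.0 for a in self.alpha_grid):
            raise ValueError("alpha values must lie in (0, 1)")
        unknown = set(self.tests) - set(ALL_TESTS)
        if unknown:
            raise ValueError(f"unknown tests: {sorted(unknown)}")

    @classmethod
    def from_mapping(cls, m: dict) -> "SimConfig":
        dgp = DGPSpec.from_mapping(m["dgp"])
        null_params = m.get("null_params")
        if null_params is not None:
            null_params = ThetaMP(*null_params)
        return cls(
            dgp=dgp,
            n_grid=list(m["n_grid"]),
            alpha_grid=list(m["alpha_grid"]),
            reps=int(m.get("reps", 1000)),
            boot_B=int(m.get("boot_B", 249)),
            tests=tuple(m.get("tests", ALL_TESTS)),
            seed=int(m.get("seed", 0)),
            mode=m.get("mode", "size"),
            null_params=null_params,
            q=int(m.get("q", 2)),
        )


@dataclass
class RejectionTable:
    """Tidy rejection-rate table plus the raw statistic archive."""

    frame: pd.DataFrame  # test, n, alpha, dgp, rate, mc_se, reps, failures
    archive: dict        # (test, n) -> DataFrame with columns stat, p_value
    boot_archive: dict = field(default_factory=dict)  # (test, n) -> (R, B) stats

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class CurveData:
    """Plot-ready curves: empirical size and size-matched power vs alpha."""

    kind: str            # "pvalue_plot" | "size_power_plot"
    alpha_grid: np.ndarray
    series: dict         # test -> np.ndarray aligned with alpha_grid

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"alpha": self.alpha_grid})
        for test, vals in self.series.items():
            df[test] = vals
        return df


# ---------------------------------------------------------------------------
# the replication engine
# ---------------------------------------------------------------------------

def _mc_cell(config: SimConfig, n: int):
    """Run all replications for one sample size.

    Returns per-test statistic/p-value arrays, per-test bootstrap replicate
    matrices (for the bootstrap-critical-value tests) and the failure count.
    """
    tests = config.tests
    B = config.boot_B
    q = config.q
    need_boot = any(t in tests for t in ("zeta1B", "zeta2B", "zeta3"))
    stats_out = {t: [] for t in tests}
    pvals_out = {t: [] for t in tests}
    boot_out = {t: [] for t in tests if t in ("zeta1B", "zeta2B")}
    failures = 0

    children = np.random.SeedSequence([config.seed, int(n)]).spawn(config.reps)
    for child in children:
        rng = np.random.default_rng(child)
        y = config.dgp.sample(n, rng).values[None, :]
        mu, phi, conv = _fit_batch_samples(y)
        if not conv[0]:
            failures += 1
            continue
        rec_stat = {}
        rec_p = {}
        rec_boot = {}
        ok_rep = True
        for variant, name in (("vn1", "zeta1"), ("vn2", "zeta2")):
            if name in tests or name + "B" in tests:
                z, ok = _zeta_batch(y, mu, phi, q=q, variant=variant)
                if not ok[0]:
                    ok_rep = False
                    break
                if name in tests:
                    rec_stat[name] = z[0]
                    rec_p[name] = stats.chi2.sf(z[0], q)
                if name + "B" in tests:
                    rec_stat[name + "B"] = z[0]
        if not ok_rep:
            failures += 1
            continue

        if need_boot:
            yb = rng.beta(mu[0] * phi[0], (1.0 - mu[0]) * phi[0], size=(B, n))
            np.clip(yb, np.finfo(float).tiny, 1.0 - 1e-16, out=yb)
            mub, phib, convb = _fit_batch_samples(yb)
            for variant, name in (("vn1", "zeta1B"), ("vn2", "zeta2B")):
                if name not in tests:
                    continue
                zb, okb = _zeta_batch(yb, mub, phib, q=q, variant=variant)
                keep = convb & okb
                # failed refits are replaced by fresh resamples
                tries = 0
                while not keep.all() and tries < 10:
                    bad = np.flatnonzero(~keep)
                    y_new = rng.beta(
                        mu[0] * phi[0], (1.0 - mu[0]) * phi[0], size=(bad.size, n)
                    )
                    np.clip(y_new, np.finfo(float).tiny, 1.0 - 1e-16, out=y_new)
                    mu_n, phi_n, conv_n = _fit_batch_samples(y_new)
                    z_n, ok_n = _zeta_batch(y_new, mu_n, phi_n, q=q, variant=variant)
                    zb[bad] = z_n
                    keep[bad] = conv_n & ok_n
                    tries += 1
                if not keep.all():
                    ok_rep = False
                    break
                rec_boot[name] = zb
                rec_p[name] = (1.0 + np.count_nonzero(zb >= rec_stat[name])) / (B + 1.0)
            if ok_rep and "zeta3" in tests:
                keep = convb
                dns = _dn_batch(yb[keep], mub[keep], phib[keep], q=q)
                if dns.shape[0] < q + 2:
                    ok_rep = False
                else:
                    dc = dns - dns.mean(axis=0)
                    v = n * (dc.T @ dc) / (dns.shape[0] - 1)
                    dn = _dn_batch(y, mu, phi, q=q)[0]
                    try:
                        z3 = float(n * dn @ np.linalg.solve(v, dn))
                    except np.linalg.LinAlgError:
                        ok_rep = False
                    else:
                        rec_stat["zeta3"] = z3
                        rec_p["zeta3"] = hotelling_sf(z3, q, B - 1)
        if not ok_rep:
            failures += 1
            continue
        for t in tests:
            stats_out[t].append(rec_stat[t])
            pvals_out[t].append(rec_p.get(t, np.nan))
        for t in rec_boot:
            boot_out[t].append(rec_boot[t])

    stats_out = {t: np.asarray(v) for t, v in stats_out.items()}
    pvals_out = {t: np.asarray(v) for t, v in pvals_out.items()}
    boot_out = {t: np.asarray(v) for t, v in boot_out.items()}
    return stats_out, pvals_out, boot_out, failures


def _boot_reject(stat: np.ndarray, boot: np.ndarray, alpha: float) -> np.ndarray:
    """Quantile-rule decisions, one per replication row of ``boot``."""
    B = boot.shape[1]
    k = int(np.ceil((1.0 - alpha) * B))
    crit = np.sort(boot, axis=1)[:, k - 1]
    return stat > crit


def _tabulate(config, n, stats_out, pvals_out, boot_out, failures,
              critical_values=None):
    rows = []
    label = config.dgp.label
    for t in config.tests:
        st = stats_out[t]
        reps = st.size
        for alpha in config.alpha_grid:
            if t in ("zeta1", "zeta2"):
                if critical_values is not None:
                    cv = critical_values[(t, alpha)]
                else:
                    cv = stats.chi2.ppf(1.0 - alpha, config.q)
                rej = np.mean(st > cv) if reps else np.nan
            elif t in ("zeta1B", "zeta2B"):
                rej = np.mean(_boot_reject(st, boot_out[t], alpha)) if reps else np.nan
            else:  # zeta3
                rej = np.mean(pvals_out[t] <= alpha) if reps else np.nan
            mc_se = np.sqrt(rej * (1.0 - rej) / reps) if reps else np.nan
            rows.append({
                "test": t, "n": n, "alpha": alpha, "dgp": label,
                "rate": rej, "mc_se": mc_se, "reps": reps, "failures": failures,
            })
    return rows


def run_size(config: SimConfig) -> RejectionTable:
    """Null rejection rates: data generated from the beta law itself."""
    rows = []
    archive = {}
    boot_archive = {}
    for n in config.n_grid:
        stats_out, pvals_out, boot_out, failures = _mc_cell(config, n)
        rows.extend(_tabulate(config, n, stats_out, pvals_out, boot_out, failures))
        for t in config.tests:
            archive[(t, n)] = pd.DataFrame(
                {"stat": stats_out[t], "p_value": pvals_out[t]}
            )
        for t in boot_out:
            boot_archive[(t, n)] = boot_out[t]
    return RejectionTable(pd.DataFrame(rows), archive, boot_archive)


def empirical_critical_values(archive: dict, alpha_grid) -> dict:
    """1-alpha empirical quantiles of archived null statistics.

    Keys of the result are (test, alpha); the quantile is the
    ceil((1-alpha)R)-th order statistic of the R archived statistics.
    """
    out = {}
    for (test, _n), df in archive.items():
        st = np.sort(df["stat"].to_numpy())
        r = st.size
        for alpha in alpha_grid:
            k = int(np.ceil((1.0 - alpha) * r))
            if k < 1 or k > r:
                raise ValueError(f"archive too small for alpha={alpha}")
            out[(test, alpha)] = float(st[k - 1])
    return out


def pseudo_true_beta(dgp: DGPSpec, seed: int, n_big: int = 1_000_000) -> ThetaMP:
    """Pseudo-true beta parameters under an alternative process.

    Estimated by fitting the beta model to one large sample from ``dgp`` —
    the Kullback-Leibler projection onto the beta family, i.e. the
    probability limit of the MLE under misspecification.
    """
    rng = np.random.default_rng(seed)
    y = dgp.sample(n_big, rng).values[None, :]
    mu, phi, conv = _fit_batch_samples(y)
    if not conv[0]:
        raise RuntimeError("pseudo-true fit did not converge")
    return ThetaMP(float(mu[0]), float(phi[0]))


def run_power(config: SimConfig, critical_values: dict | None = None) -> RejectionTable:
    """Non-null rejection rates under an alternative data-generating process.

    zeta1/zeta2 are rejected against empirical critical values (supplied, or
    simulated here from the null at the pseudo-true beta parameters);
    zeta1B/zeta2B/zeta3 carry their own bootstrap references.
    """
    if config.mode != "power":
        raise ValueError("run_power requires a config with mode='power'")
    needs_cv = any(t in config.tests for t in ("zeta1", "zeta2"))
    rows = []
    archive = {}
    boot_archive = {}
    for n in config.n_grid:
        cv = critical_values
        if needs_cv and cv is None:
            theta0 = config.null_params or pseudo_true_beta(config.dgp, config.seed + 1)
            null_cfg = SimConfig(
                dgp=DGPSpec("beta", {"mu": theta0.mu, "phi": theta0.phi}),
                n_grid=[n], alpha_grid=config.alpha_grid,
                reps=config.reps, boot_B=config.boot_B,
                tests=tuple(t for t in config.tests if t in ("zeta1", "zeta2")),
                seed=config.seed + 7_654_321, mode="size", q=config.q,
            )
            null_tab = run_size(null_cfg)
            cv = empirical_critical_values(null_tab.archive, config.alpha_grid)
        stats_out, pvals_out, boot_out, failures = _mc_cell(config, n)
        rows.extend(
            _tabulate(config, n, stats_out, pvals_out, boot_out, failures,
                      critical_values=cv)
        )
        for t in config.tests:
            archive[(t, n)] = pd.DataFrame(
                {"stat": stats_out[t], "p_value": pvals_out[t]}
            )
        for t in boot_out:
            boot_archive[(t, n)] = boot_out[t]
    return RejectionTable(pd.DataFrame(rows), archive, boot_archive)


def curve_data(size_archive: dict, power_archive: dict | None = None,
               alpha_grid: np.ndarray | None = None) -> CurveData:
    """p-value-plot or size-power-plot series on a dense alpha grid.

    With only a null archive: empirical size (fraction of null p-values at
    or below alpha) against nominal alpha.  With both archives: power at the
    empirical critical value matched to each nominal size, with the
    endpoints (0, 0) and (1, 1) included.
    """
    if alpha_grid is None:
        alpha_grid = np.linspace(0.01, 0.99, 99)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if power_archive is None:
        series = {}
        for (test, _n), df in size_archive.items():
            p = df["p_value"].to_numpy()
            series[test] = np.array([(p <= a).mean() for a in alpha_grid])
        return CurveData("pvalue_plot", alpha_grid, series)

    keys = sorted(set(size_archive) & set(power_archive))
    if not keys:
        raise ValueError("size and power archives share no (test, n) keys")
    grid = np.concatenate([[0.0], alpha_grid, [1.0]])
    series = {}
    for key in keys:
        test, _n = key
        null_stats = np.sort(size_archive[key]["stat"].to_numpy())
        pow_stats = power_archive[key]["stat"].to_numpy()
        r = null_stats.size
        vals = [0.0]
        for a in alpha_grid:
            k = int(np.ceil((1.0 - a) * r))
            cv = null_stats[k - 1]
            vals.append((pow_stats > cv).mean())
        vals.append(1.0)
        series[test] = np.asarray(vals)
    return CurveData("size_power_plot", grid, series)
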