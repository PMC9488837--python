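"""Unit and oracle tests for the information-matrix test machinery."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import polygamma, psi

from betaimt.betadist import FractionalSample, ThetaMP, fit_mle, sample_beta
from betaimt.imtest import (
    CovEstimate,
    RestrictionSet,
    SingularCovarianceError,
    _fit_batch_samples,
    _zeta_batch,
    aux_quantities,
    bootstrap_cov,
    d_contrib,
    hotelling_sf,
    restriction_set,
    test_asymptotic as zeta_asymptotic,
    test_bootstrap_critical as zeta_bootstrap,
    test_zeta3 as zeta3_run,
    v_n1,
    v_n2,
    zeta_statistic,
)
from betaimt.altdist import sample_kumaraswamy
from betaimt.betadist import log_density, score_contrib
from conftest import random_sample, random_theta


# ---------------------------------------------------------------------------
# naive per-observation transcriptions (the slow oracles)
# ---------------------------------------------------------------------------

def naive_score(y, mu, phi):
    mustar = psi(mu * phi) - psi((1 - mu) * phi)
    mudag = psi((1 - mu) * phi) - psi(phi)
    ys = np.log(y / (1 - y))
    yd = np.log(1 - y)
    return np.array([phi * (ys - mustar), mu * (ys - mustar) + (yd - mudag)])


def naive_an(values, mu, phi):
    w = polygamma(1, mu * phi) + polygamma(1, (1 - mu) * phi)
    c = phi * (mu * w - polygamma(1, (1 - mu) * phi))
    mustar = psi(mu * phi) - psi((1 - mu) * phi)
    total = np.zeros((2, 2))
    for y in values:
        ys = np.log(y / (1 - y))
        a_mm = -phi ** 2 * w
        a_mp = (ys - mustar) - c
        a_pp = (-(mu * c) / phi - (1 - mu) * polygamma(1, (1 - mu) * phi)
                + polygamma(1, phi))
        total += np.array([[a_mm, a_mp], [a_mp, a_pp]])
    return total / len(values)


def naive_bn(values, mu, phi):
    total = np.zeros((2, 2))
    for y in values:
        s = naive_score(y, mu, phi)
        total += np.outer(s, s)
    return total / len(values)


def naive_d(y, mu, phi):
    w = polygamma(1, mu * phi) + polygamma(1, (1 - mu) * phi)
    c = phi * (mu * w - polygamma(1, (1 - mu) * phi))
    mustar = psi(mu * phi) - psi((1 - mu) * phi)
    mudag = psi((1 - mu) * phi) - psi(phi)
    ys = np.log(y / (1 - y))
    yd = np.log(1 - y)
    d1 = phi ** 2 * ((ys - mustar) ** 2 - w)
    d2 = (ys - mustar) - c + phi * (ys - mustar) * (
        mu * (ys - mustar) + (yd - mudag)
    )
    d3 = (-(mu * c) / phi - (1 - mu) * polygamma(1, (1 - mu) * phi)
          + polygamma(1, phi)
          + (mu * (ys - mustar) + (yd - mudag)) ** 2)
    return np.array([d1, d2, d3])


def naive_ln(values, mu, phi, q):
    total = np.zeros((q, 2))
    for y in values:
        total += np.outer(naive_d(y, mu, phi)[:q], naive_score(y, mu, phi))
    return -total / len(values)


def naive_vn1(values, mu, phi, grad_active, q):
    an = naive_an(values, mu, phi)
    an_inv = np.linalg.inv(an)
    total = np.zeros((q, q))
    for y in values:
        r = naive_d(y, mu, phi)[:q] - grad_active @ an_inv @ naive_score(y, mu, phi)
        total += np.outer(r, r)
    return total / len(values)


def naive_vn2(values, mu, phi, q):
    bn = naive_bn(values, mu, phi)
    bn_inv = np.linalg.inv(bn)
    ln = naive_ln(values, mu, phi, q)
    total = np.zeros((q, q))
    for y in values:
        r = naive_d(y, mu, phi)[:q] + ln @ bn_inv @ naive_score(y, mu, phi)
        total += np.outer(r, r)
    return total / len(values)


# ---------------------------------------------------------------------------
# auxiliary scalars
# ---------------------------------------------------------------------------

class TestAuxQuantities:
    def test_m_vanishes_at_symmetric_mean(self):
        for phi in (2.0, 20.0, 120.0):
            assert aux_quantities(ThetaMP(0.5, phi)).m == 0.0

    def test_printed_identities(self, rng):
        for _ in range(10):
            th = random_theta(rng)
            aux = aux_quantities(th)
            assert aux.dmustar_dmu == pytest.approx(th.phi * aux.w, rel=1e-12)
            assert aux.dmustar_dphi * th.phi == pytest.approx(aux.c, rel=1e-12)
            assert aux.w > 0

    @pytest.mark.parametrize("name,base,wrt", [
        ("dmustar_dmu", "mustar", "mu"), ("dmustar_dphi", "mustar", "phi"),
        ("dmudag_dmu", "mudag", "mu"), ("dmudag_dphi", "mudag", "phi"),
        ("dw_dmu", "w", "mu"), ("dw_dphi", "w", "phi"),
        ("dc_dmu", "c", "mu"), ("dc_dphi", "c", "phi"),
    ])
    def test_partials_match_finite_differences(self, rng, name, base, wrt):
        eps = 1e-6
        for _ in range(5):
            th = random_theta(rng)
            if wrt == "mu":
                hi = aux_quantities(ThetaMP(th.mu + eps, th.phi))
                lo = aux_quantities(ThetaMP(th.mu - eps, th.phi))
            else:
                hi = aux_quantities(ThetaMP(th.mu, th.phi + eps))
                lo = aux_quantities(ThetaMP(th.mu, th.phi - eps))
            fd = (getattr(hi, base) - getattr(lo, base)) / (2 * eps)
            got = getattr(aux_quantities(th), name)
            assert got == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_second_derivative_of_mustar(self, rng):
        eps = 1e-4
        th = random_theta(rng)
        fd = (
            aux_quantities(ThetaMP(th.mu, th.phi + eps)).mustar
            - 2 * aux_quantities(th).mustar
            + aux_quantities(ThetaMP(th.mu, th.phi - eps)).mustar
        ) / eps ** 2
        # second-difference oracle carries O(eps^2) truncation + roundoff
        assert aux_quantities(th).d2mustar_dphi2 == pytest.approx(fd, rel=5e-3)


# ---------------------------------------------------------------------------
# restriction vector and Jacobian
# ---------------------------------------------------------------------------

class TestDContrib:
    def test_matches_hessian_plus_outer_product(self, rng):
        eps = 1e-4
        for _ in range(8):
            th = random_theta(rng)
            y = float(rng.uniform(0.05, 0.95))

            def ld(dm, dp):
                return log_density(y, ThetaMP(th.mu + dm, th.phi + dp))

            h = np.empty((2, 2))
            steps = [(eps, 0.0), (0.0, eps)]
            for i in range(2):
                for j in range(2):
                    si, sj = steps[i], steps[j]
                    h[i, j] = (
                        ld(si[0] + sj[0], si[1] + sj[1])
                        - ld(si[0] - sj[0], si[1] - sj[1])
                        - ld(-si[0] + sj[0], -si[1] + sj[1])
                        + ld(-si[0] - sj[0], -si[1] - sj[1])
                    ) / (4 * eps * eps)
            s = score_contrib(y, th)
            m = h + np.outer(s, s)
            expected = np.array([m[0, 0], m[0, 1], m[1, 1]])
            scale = np.abs(expected).max()
            np.testing.assert_allclose(d_contrib(y, th), expected,
                                       rtol=1e-4, atol=1e-6 * scale)

    def test_centred_observation_gives_minus_info_entry(self, rng):
        from scipy.special import expit
        th = random_theta(rng)
        aux = aux_quantities(th)
        y_centred = float(expit(aux.mustar))  # y* = mu* exactly
        d = d_contrib(y_centred, th)
        assert d[0] == pytest.approx(-th.phi ** 2 * aux.w, rel=1e-10)

    def test_zero_mean_under_model_by_quadrature(self, rng):
        from scipy import integrate
        th = random_theta(rng)
        for i in range(3):
            val, _ = integrate.quad(
                lambda y: d_contrib(y, th)[i] * np.exp(log_density(y, th)),
                0.0, 1.0, limit=400,
            )
            assert val == pytest.approx(0.0, abs=1e-6)

    def test_matches_naive_transcription(self, rng):
        th = random_theta(rng)
        y = rng.uniform(0.05, 0.95, size=20)
        got = d_contrib(y, th)
        want = np.stack([naive_d(v, th.mu, th.phi) for v in y])
        np.testing.assert_allclose(got, want, rtol=1e-12)


class TestRestrictionSet:
    def test_invalid_q(self, beta_sample):
        with pytest.raises(ValueError):
            restriction_set(beta_sample, ThetaMP(0.3, 25.0), q=4)

    def test_dn_is_column_mean(self, beta_sample):
        rs = restriction_set(beta_sample, ThetaMP(0.3, 25.0))
        np.testing.assert_allclose(rs.Dn, rs.contribs.mean(axis=0))
        assert rs.Dn_active.shape == (2,)
        assert rs.gradDn_active.shape == (2, 2)

    def test_jacobian_matches_numerical(self, rng):
        eps = 1e-6
        for _ in range(6):
            th = random_theta(rng)
            s = random_sample(rng, th, 50)
            rs = restriction_set(s, th, q=3)

            def dn_at(mu, phi):
                return d_contrib(s.values, ThetaMP(mu, phi)).mean(axis=0)

            num = np.stack([
                (dn_at(th.mu + eps, th.phi) - dn_at(th.mu - eps, th.phi)) / (2 * eps),
                (dn_at(th.mu, th.phi + eps) - dn_at(th.mu, th.phi - eps)) / (2 * eps),
            ], axis=-1)
            scale = np.abs(num).max()
            np.testing.assert_allclose(rs.gradDn, num, rtol=1e-5,
                                       atol=1e-5 * scale)

    def test_permutation_invariance(self, rng, beta_sample):
        th = ThetaMP(0.3, 25.0)
        rs = restriction_set(beta_sample, th)
        perm = FractionalSample(rng.permutation(beta_sample.values))
        rs_p = restriction_set(perm, th)
        np.testing.assert_allclose(rs.Dn, rs_p.Dn)
        np.testing.assert_allclose(rs.gradDn, rs_p.gradDn)

    def test_dn_small_at_mle_of_large_correct_sample(self):
        rng = np.random.default_rng(77)
        s = sample_beta(ThetaMP(0.3, 25.0), 50_000, rng)
        fit = fit_mle(s)
        rs = restriction_set(s, fit.theta_hat)
        cov = v_n1(s, fit.theta_hat, rs)
        se = np.sqrt(np.diag(cov.matrix) / s.n)
        assert np.all(np.abs(rs.Dn_active) < 3 * se)


# ---------------------------------------------------------------------------
# covariance estimators
# ---------------------------------------------------------------------------

class TestCovarianceEstimators:
    @pytest.mark.parametrize("which", ["vn1", "vn2"])
    def test_symmetric_psd(self, rng, which):
        th = random_theta(rng)
        s = random_sample(rng, th, 80)
        rs = restriction_set(s, th)
        cov = (v_n1 if which == "vn1" else v_n2)(s, th, rs)
        np.testing.assert_allclose(cov.matrix, cov.matrix.T, atol=1e-10)
        assert (np.linalg.eigvalsh(cov.matrix) > -1e-10).all()
        assert cov.method == which

    def test_naive_loop_oracle_equality(self, rng):
        # exact (up to summation roundoff) agreement with a literal
        # per-observation transcription of the printed formulas
        for _ in range(10):
            th = random_theta(rng)
            s = random_sample(rng, th, 40)
            rs = restriction_set(s, th)
            got1 = v_n1(s, th, rs).matrix
            want1 = naive_vn1(s.values, th.mu, th.phi, rs.gradDn_active, 2)
            np.testing.assert_allclose(got1, want1, rtol=1e-9)
            got2 = v_n2(s, th, rs).matrix
            want2 = naive_vn2(s.values, th.mu, th.phi, 2)
            np.testing.assert_allclose(got2, want2, rtol=1e-9)

    def test_vn1_vn2_agree_in_large_samples(self):
        rng = np.random.default_rng(13)
        s = sample_beta(ThetaMP(0.4, 30.0), 100_000, rng)
        fit = fit_mle(s)
        rs = restriction_set(s, fit.theta_hat)
        m1 = v_n1(s, fit.theta_hat, rs).matrix
        m2 = v_n2(s, fit.theta_hat, rs).matrix
        np.testing.assert_allclose(m1, m2, rtol=0.15)

    def test_batched_path_matches_public_functions(self, rng):
        th = random_theta(rng)
        s = random_sample(rng, th, 60)
        rs = restriction_set(s, th)
        for which, fn in (("vn1", v_n1), ("vn2", v_n2)):
            z, ok = _zeta_batch(s.values[None, :], np.array([th.mu]),
                                np.array([th.phi]), variant=which)
            assert ok[0]
            want = zeta_statistic(rs, fn(s, th, rs), s.n)
            assert z[0] == pytest.approx(want, rel=1e-9)


class TestBootstrapCov:
    def test_symmetric_psd_and_deterministic(self, rng):
        s = sample_beta(ThetaMP(0.5, 20.0), 100, rng)
        fit = fit_mle(s)
        c1 = bootstrap_cov(s, fit.theta_hat, 200, np.random.default_rng(42))
        c2 = bootstrap_cov(s, fit.theta_hat, 200, np.random.default_rng(42))
        np.testing.assert_array_equal(c1.matrix, c2.matrix)
        np.testing.assert_allclose(c1.matrix, c1.matrix.T)
        assert (np.linalg.eigvalsh(c1.matrix) > 0).all()
        assert c1.method == "bootstrap" and c1.B == 200

    def test_stabilises_as_B_grows(self):
        rng = np.random.default_rng(17)
        s = sample_beta(ThetaMP(0.5, 20.0), 100, rng)
        fit = fit_mle(s)
        t2 = np.trace(bootstrap_cov(s, fit.theta_hat, 2000,
                                    np.random.default_rng(1)).matrix)
        t4 = np.trace(bootstrap_cov(s, fit.theta_hat, 4000,
                                    np.random.default_rng(2)).matrix)
        assert abs(t4 - t2) / t2 < 0.10

    def test_minimum_B(self, beta_sample):
        with pytest.raises(ValueError):
            bootstrap_cov(beta_sample, ThetaMP(0.3, 25.0), 3,
                          np.random.default_rng(0))


# ---------------------------------------------------------------------------
# the statistics and tests
# ---------------------------------------------------------------------------

def _manual_rs(dn):
    dn3 = np.concatenate([dn, [0.0]])
    return RestrictionSet(
        contribs=np.tile(dn3, (4, 1)), Dn=dn3,
        gradDn=np.zeros((3, 2)), q=2, active_index=np.arange(2),
    )


class TestZetaStatistic:
    def test_hand_case(self):
        rs = _manual_rs(np.array([0.1, 0.0]))
        cov = CovEstimate(np.eye(2), "vn1", condition=1.0)
        assert zeta_statistic(rs, cov, 100) == pytest.approx(1.0)

    def test_zero_dn(self):
        rs = _manual_rs(np.zeros(2))
        cov = CovEstimate(np.eye(2), "vn1", condition=1.0)
        assert zeta_statistic(rs, cov, 50) == 0.0

    def test_nonnegative_for_pd_cov(self, rng):
        for _ in range(10):
            a = rng.normal(size=(2, 2))
            cov = CovEstimate(a @ a.T + 0.1 * np.eye(2), "vn1", condition=1.0)
            rs = _manual_rs(rng.normal(size=2))
            assert zeta_statistic(rs, cov, 30) >= 0.0

    def test_singular_covariance_raises(self):
        rs = _manual_rs(np.array([0.1, 0.2]))
        cov = CovEstimate(np.array([[1.0, 1.0], [1.0, 1.0 + 1e-15]]), "vn1",
                          condition=1e15)
        with pytest.raises(SingularCovarianceError):
            zeta_statistic(rs, cov, 100)


class TestHotelling:
    def test_scaled_f_identity(self):
        for t2, q, b in [(3.7, 2, 250), (10.0, 2, 500), (1.2, 3, 100)]:
            m = b - 1
            f_stat = t2 * (m - q + 1) / (q * m)
            assert hotelling_sf(t2, q, m) == pytest.approx(
                stats.f.sf(f_stat, q, m - q + 1), rel=1e-12
            )

    def test_zeta3_f_representation_through_api(self):
        rng = np.random.default_rng(3)
        s = sample_beta(ThetaMP(0.5, 20.0), 150, rng)
        res = zeta3_run(s, B=99, rng=np.random.default_rng(4))
        z, q, b = res.statistic, res.q, res.B
        f_p = stats.f.sf(z * (b - q) / (q * (b - 1)), q, b - q)
        assert res.p_value == pytest.approx(f_p, rel=1e-12)


class TestPublicTests:
    def test_asymptotic_pvalue_and_order_invariance(self, rng):
        s = sample_beta(ThetaMP(0.4, 30.0), 300, rng)
        res = zeta_asymptotic(s, "zeta1")
        assert 0.0 <= res.p_value <= 1.0
        assert res.p_value == pytest.approx(
            stats.chi2.sf(res.statistic, res.q)
        )
        perm = FractionalSample(np.random.default_rng(9).permutation(s.values))
        res_p = zeta_asymptotic(perm, "zeta1")
        # summation order perturbs the refit at roundoff level only
        assert res_p.statistic == pytest.approx(res.statistic, rel=1e-6)

    def test_zeta3_seed_reproducible(self, rng):
        s = sample_beta(ThetaMP(0.5, 20.0), 120, rng)
        r1 = zeta3_run(s, B=99, rng=np.random.default_rng(5))
        r2 = zeta3_run(s, B=99, rng=np.random.default_rng(5))
        assert r1.p_value == r2.p_value
        assert r1.statistic == r2.statistic

    def test_bootstrap_critical_reproducible_and_dual(self, rng):
        s = sample_beta(ThetaMP(0.5, 20.0), 80, rng)
        r1 = zeta_bootstrap(s, "zeta1B", B=99,
                                     rng=np.random.default_rng(6))
        r2 = zeta_bootstrap(s, "zeta1B", B=99,
                                     rng=np.random.default_rng(6))
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.boot_stats, r2.boot_stats)
        # quantile rule and raw empirical p-value give identical decisions
        p_raw = np.count_nonzero(r1.boot_stats >= r1.statistic) / r1.B
        for alpha in (0.01, 0.05, 0.1, 0.25, 0.5, 0.9):
            assert r1.reject(alpha) == (p_raw < alpha)

    def test_bad_variant_rejected(self, beta_sample):
        with pytest.raises(ValueError):
            zeta_asymptotic(beta_sample, "zeta3")
        with pytest.raises(ValueError):
            zeta_bootstrap(beta_sample, "zeta1", B=99)

    def test_statistics_grow_under_misspecification(self):
        # Kumaraswamy data: the statistic should diverge with n
        meds = {}
        for n in (100, 1000):
            stats_n = []
            for i in range(30):
                rng = np.random.default_rng(1000 + i)
                y = sample_kumaraswamy(0.5, 15.0, n, rng).values[None, :]
                mu, phi, conv = _fit_batch_samples(y)
                assert conv[0]
                z, ok = _zeta_batch(y, mu, phi, variant="vn1")
                if ok[0]:
                    stats_n.append(z[0])
            meds[n] = np.median(stats_n)
        assert meds[1000] > meds[100]
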