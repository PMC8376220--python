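"""Slope estimators against closed-form, enumeration and grid oracles."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import collidermr as cmr
from collidermr.errors import ConfigError, NumericalError
from collidermr.estimators import exact_q_objective


def _make_summary(beta_xg, alpha_star, se_alpha, se_xg=None, beta_star=1.0):
    beta_xg = np.asarray(beta_xg, dtype=float)
    k = len(beta_xg)
    return cmr.ColliderSummary(
        snp_ids=[f"g{j+1}" for j in range(k)],
        beta_xg=beta_xg,
        se_xg=np.full(k, 1e-10) if se_xg is None else np.asarray(se_xg, dtype=float),
        alpha_star=np.asarray(alpha_star, dtype=float),
        se_alpha_star=np.asarray(se_alpha, dtype=float),
        beta_star=beta_star,
        se_beta_star=0.05,
        n=10_000,
        k=k,
    )


class TestIVW:
    def test_perfect_proportionality(self):
        s = _make_summary([0.1, 0.2, 0.4], [0.03, 0.06, 0.12], [0.01, 0.02, 0.01])
        est = cmr.ivw_slope(s)
        assert est.slope == pytest.approx(0.3, rel=1e-12)
        assert est.phi == 1.0
        assert est.extras["phi_raw"] == pytest.approx(0.0, abs=1e-18)

    def test_three_snp_closed_form(self, tiny_summary):
        # hand-expanded weighted LS through the origin, w = 1/se^2 = 1e4 each
        x = np.array([0.1, 0.2, 0.3])
        y = np.array([0.05, 0.08, 0.16])
        expected = np.sum(x * y) / np.sum(x * x)  # equal weights cancel
        est = cmr.ivw_slope(tiny_summary)
        assert est.slope == pytest.approx(expected, rel=1e-12)
        # fixed-effects variance 1/(sum w x^2)
        assert est.extras["phi_raw"] > 0

    def test_random_vs_fixed_effects_se(self, tiny_summary):
        re = cmr.ivw_slope(tiny_summary, random_effects=True)
        fe = cmr.ivw_slope(tiny_summary, random_effects=False)
        assert re.se_slope >= fe.se_slope
        assert fe.se_slope == pytest.approx(
            np.sqrt(1.0 / np.sum((1 / 0.01**2) * tiny_summary.beta_xg**2))
        )

    @given(scale=st.floats(0.1, 10.0))
    def test_slope_invariant_to_common_se_rescale(self, scale):
        s = _make_summary([0.1, 0.25, 0.3], [0.02, 0.09, 0.07], [0.01, 0.03, 0.02])
        s2 = dataclasses.replace(s, se_alpha_star=s.se_alpha_star * scale)
        a, b = cmr.ivw_slope(s), cmr.ivw_slope(s2)
        assert a.slope == pytest.approx(b.slope, rel=1e-9)
        if abs(scale - 1) > 1e-3:
            assert a.extras["phi_raw"] != pytest.approx(b.extras["phi_raw"], rel=1e-3)

    def test_ivw_not_shift_invariant_but_egger_is(self):
        s = _make_summary([0.1, 0.2, 0.3, 0.5], [0.02, 0.05, 0.05, 0.11],
                          [0.01, 0.02, 0.01, 0.03])
        shifted = dataclasses.replace(s, alpha_star=s.alpha_star + 0.05)
        assert cmr.ivw_slope(shifted).slope != pytest.approx(
            cmr.ivw_slope(s).slope, rel=1e-6
        )
        e0, e1 = cmr.egger_slope(s), cmr.egger_slope(shifted)
        assert e1.slope == pytest.approx(e0.slope, rel=1e-9)
        assert e1.intercept == pytest.approx(e0.intercept + 0.05, rel=1e-9)

    def test_too_few_snps_raise(self):
        with pytest.raises(ConfigError):
            cmr.ivw_slope(
                _make_summary([0.1, 0.2], [0.0, 0.0], [0.1, 0.1]).__class__(
                    snp_ids=["g1"], beta_xg=np.array([0.1]), se_xg=np.array([0.01]),
                    alpha_star=np.array([0.0]), se_alpha_star=np.array([0.1]),
                    beta_star=1.0, se_beta_star=0.1, n=100, k=1,
                )
            )


class TestEgger:
    def test_exact_affine_data(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        s = _make_summary(x, 0.07 + 1.3 * x, [0.01, 0.02, 0.015, 0.01])
        est = cmr.egger_slope(s)
        assert est.intercept == pytest.approx(0.07, rel=1e-9)
        assert est.slope == pytest.approx(1.3, rel=1e-9)
        assert est.phi == 1.0

    def test_normal_equations_oracle(self):
        x = np.array([0.12, 0.21, 0.33, 0.48])
        y = np.array([0.03, 0.11, 0.05, 0.21])
        se = np.array([0.01, 0.03, 0.02, 0.04])
        w = 1 / se**2
        # brute-force 2x2 weighted normal equations
        a_mat = np.array([[np.sum(w), np.sum(w * x)], [np.sum(w * x), np.sum(w * x * x)]])
        rhs = np.array([np.sum(w * y), np.sum(w * x * y)])
        icept, slope = np.linalg.solve(a_mat, rhs)
        est = cmr.egger_slope(_make_summary(x, y, se))
        assert est.slope == pytest.approx(slope, rel=1e-10)
        assert est.intercept == pytest.approx(icept, rel=1e-10)

    def test_constant_beta_xg_raises(self):
        s = _make_summary([0.2, 0.2, 0.2], [0.01, 0.02, 0.03], [0.01, 0.01, 0.01])
        with pytest.raises(NumericalError):
            cmr.egger_slope(s)


class TestLAD:
    def test_collinear_through_origin_exact(self):
        x = np.array([0.1, -0.2, 0.3, 0.15, 0.25])
        s = _make_summary(x, -0.7 * x, np.full(5, 0.02))
        est = cmr.lad_slope(s, n_boot=0)
        assert est.slope == pytest.approx(-0.7, rel=1e-12)

    @given(seed=st.integers(0, 500))
    def test_ratio_enumeration_oracle(self, seed):
        """The weighted L1 line through the origin passes through one of the
        data ratios; enumerate them all and compare minimized losses."""
        rng = np.random.default_rng(seed)
        k = 7
        x = rng.normal(0.2, 0.1, k)
        x[np.abs(x) < 1e-3] = 0.05
        y = 0.4 * x + rng.normal(0, 0.05, k)
        se = rng.uniform(0.01, 0.05, k)
        est = cmr.lad_slope(_make_summary(x, y, se), n_boot=0)

        def loss(s):
            return np.sum(np.abs(y - s * x) / se)

        candidates = y / x
        best = min(loss(c) for c in candidates)
        assert loss(est.slope) == pytest.approx(best, rel=1e-9)

    def test_bootstrap_se_seeded(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.2, 0.05, 20)
        y = 0.5 * x + rng.normal(0, 0.03, 20)
        s = _make_summary(x, y, np.full(20, 0.03))
        a = cmr.lad_slope(s, n_boot=200, seed=11)
        b = cmr.lad_slope(s, n_boot=200, seed=11)
        assert a.se_slope == b.se_slope > 0
        assert np.isnan(cmr.lad_slope(s, n_boot=0).se_slope)


class TestLimlRaps:
    def test_liml_equals_ivw_under_nome(self):
        # with (near-)zero first-stage SE the exact-weighting objective
        # reduces to the IVW weighted least squares
        rng = np.random.default_rng(5)
        x = rng.normal(0.2, 0.05, 10)
        y = -0.6 * x + rng.normal(0, 0.01, 10)
        s = _make_summary(x, y, np.full(10, 0.01))
        liml = cmr.liml_raps_slope(s, z=0)
        ivw = cmr.ivw_slope(s)
        assert liml.slope == pytest.approx(ivw.slope, abs=1e-6)

    def test_liml_grid_search_oracle(self):
        x = np.array([0.15, 0.22, 0.31])
        y = np.array([0.04, 0.13, 0.08])
        se_x = np.array([0.05, 0.04, 0.06])
        se_y = np.array([0.02, 0.03, 0.02])
        s = _make_summary(x, y, se_y, se_xg=se_x)
        est = cmr.liml_raps_slope(s, z=0)
        grid = np.arange(-5.0, 5.0, 1e-5)
        vals = np.array(
            [
                np.sum((y - g * x) ** 2 / (g * g * se_x**2 + se_y**2))
                for g in grid[:: 1000]
            ]
        )
        coarse = grid[::1000][np.argmin(vals)]
        fine = grid[np.abs(grid - coarse) < 0.02]
        q_fine = [exact_q_objective(g, x, y, se_x**2, se_y**2) for g in fine]
        oracle = fine[int(np.argmin(q_fine))]
        assert est.slope == pytest.approx(oracle, abs=1e-4)
        assert est.extras["q_min"] == pytest.approx(min(q_fine), rel=1e-6)

    def test_raps_close_to_liml_without_pleiotropy(self):
        rng = np.random.default_rng(8)
        k = 30
        x = rng.normal(0.2, 0.05, k)
        se_x = np.full(k, 0.02)
        se_y = np.full(k, 0.02)
        y = -0.6 * x + rng.normal(0, se_y)
        s = _make_summary(x, y, se_y, se_xg=se_x)
        raps = cmr.liml_raps_slope(s, z=1)
        liml = cmr.liml_raps_slope(s, z=0)
        assert raps.converged
        assert raps.slope == pytest.approx(liml.slope, abs=0.05)
        assert raps.extras["tau2"] >= 0

    def test_invalid_z_raises(self, tiny_summary):
        with pytest.raises(ConfigError):
            cmr.liml_raps_slope(tiny_summary, z=2)


class TestTSLS:
    def test_single_snp_wald_ratio(self):
        cfg = cmr.SimulationConfig(n=500, k=2, seed=2)
        d = cmr.simulate_dataset(cfg)
        one = cmr.IndividualData(
            genotypes=d.genotypes[:, [0]], exposure=d.exposure, outcome=d.outcome
        )
        est = cmr.tsls(one)
        g = d.genotypes[:, 0]
        wald = np.cov(d.outcome, g)[0, 1] / np.cov(d.exposure, g)[0, 1]
        assert est.beta_hat == pytest.approx(wald, rel=1e-8)

    def test_consistency_with_valid_instruments(self):
        cfg = cmr.SimulationConfig(n=150_000, k=20, pleiotropy_sd=0.0, h2x=0.02)
        d = cmr.simulate_dataset(cfg, seed=6)
        assert cmr.tsls(d).beta_hat == pytest.approx(0.5, abs=0.05)


class TestCausalEstimate:
    def test_additive_identity_and_zero_slope(self, tiny_summary):
        est = cmr.SlopeEstimate(method="ivw", slope=0.0, se_slope=0.02)
        ce = cmr.causal_estimate(est, tiny_summary)
        assert ce.beta_hat == tiny_summary.beta_star
        est2 = cmr.ivw_slope(tiny_summary)
        ce2 = cmr.causal_estimate(est2, tiny_summary)
        assert ce2.beta_hat == ce2.components["beta_star"] + ce2.components["slope"]

    def test_se_dominates_components(self, tiny_summary):
        est = cmr.ivw_slope(tiny_summary)
        ce = cmr.causal_estimate(est, tiny_summary)
        assert ce.se >= tiny_summary.se_beta_star
        assert ce.se >= est.se_slope
        assert 0 <= ce.p_value <= 1

    def test_standard_arm_guard(self, tiny_summary):
        std = cmr.SlopeEstimate(
            method="standard-ivw", slope=0.5, se_slope=0.1, extras={"estimand": "beta"}
        )
        with pytest.raises(ConfigError):
            cmr.causal_estimate(std, tiny_summary)
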