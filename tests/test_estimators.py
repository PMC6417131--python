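import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrpipe import (
    EstimatorError,
    HarmonizedInstrument,
    HarmonizedInstrumentSet,
    LDMatrix,
    RunConfig,
    WaldEstimate,
    cochran_q,
    estimate_all,
    ivw,
    mr_egger,
    pca_ivw,
    wald_ratio,
    weighted_median,
)
from mrpipe.estimators import _weighted_median


def hinst(snp_id="rs1", bx=0.5, sx=0.01, by=0.02, sy=0.01, **kw):
    return HarmonizedInstrument(snp_id=snp_id, effect_allele="A", other_allele="G",
                                beta_exposure=bx, se_exposure=sx,
                                beta_outcome=by, se_outcome=sy, **kw)


TWO_SNP = [WaldEstimate("a", 0.4, 0.1), WaldEstimate("b", 0.6, 0.2)]
HET_SNP = [WaldEstimate("a", 0.1, 0.1), WaldEstimate("b", 0.9, 0.1)]


class TestWald:
    def test_ratio_and_first_order_se(self):
        w = wald_ratio(hinst(bx=0.5, by=0.02, sy=0.01))
        assert w.ratio == pytest.approx(0.04)
        assert w.se == pytest.approx(0.02)

    def test_zero_outcome_keeps_se(self):
        w = wald_ratio(hinst(bx=0.5, by=0.0, sy=0.01))
        assert w.ratio == 0.0 and w.se == pytest.approx(0.02)

    def test_zero_exposure_is_error(self):
        with pytest.raises(EstimatorError, match="zero_instrument"):
            wald_ratio(hinst(bx=0.0))

    def test_negative_exposure_se_positive(self):
        w = wald_ratio(hinst(bx=-0.5, by=0.02, sy=0.01))
        assert w.ratio == pytest.approx(-0.04) and w.se == pytest.approx(0.02)


class TestCochranQ:
    def test_two_snp_fixture(self):
        q, df, p = cochran_q(TWO_SNP)
        # oracle: weighted mean 0.44; Q = 100*0.0016 + 25*0.0256 = 0.8
        assert q == pytest.approx(0.8, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(0.371, abs=5e-4)

    def test_identical_ratios_no_heterogeneity(self):
        q, _, p = cochran_q([WaldEstimate("a", 0.3, 0.1), WaldEstimate("b", 0.3, 0.2)])
        assert q == pytest.approx(0.0, abs=1e-14) and p == pytest.approx(1.0)

    def test_heterogeneous_fixture(self):
        q, _, p = cochran_q(HET_SNP)
        assert q == pytest.approx(32.0, abs=1e-10)
        assert p == pytest.approx(1.6e-8, rel=0.05)

    def test_single_estimate_is_error(self):
        with pytest.raises(EstimatorError):
            cochran_q(TWO_SNP[:1])


class TestIVW:
    def test_fixed_effects_fixture(self):
        e = ivw(TWO_SNP, 0.05)
        assert e.beta == pytest.approx(0.44)
        assert e.se == pytest.approx(125 ** -0.5, abs=1e-10)  # 0.08944
        assert e.model_variant == "ivw_fixed"
        assert e.q_pvalue > 0.05

    def test_random_effects_inflation(self):
        e = ivw(HET_SNP, 0.05)
        assert e.beta == pytest.approx(0.5)
        assert e.model_variant == "ivw_random"
        assert e.se == pytest.approx(0.4, abs=1e-10)  # 0.0707 * sqrt(32)

    def test_point_estimate_same_across_variants(self):
        fixed = ivw(HET_SNP, heterogeneity_alpha=1e-12)  # force fixed
        random_ = ivw(HET_SNP, heterogeneity_alpha=0.5)
        assert fixed.beta == random_.beta
        assert random_.se >= fixed.se

    def test_single_wald_identity(self):
        e = ivw(TWO_SNP[:1], 0.05)
        assert e.beta == pytest.approx(0.4) and e.se == pytest.approx(0.1)
        assert e.model_variant == "ivw_fixed"

    def test_ci_uses_normal_quantile(self):
        e = ivw(TWO_SNP, 0.05)
        assert e.ci_low == pytest.approx(e.beta - 1.959964 * e.se)
        assert e.ci_high == pytest.approx(e.beta + 1.959964 * e.se)


class TestWeightedMedian:
    def test_equal_weights_symmetric(self):
        walds = [WaldEstimate(f"s{i}", r, 0.1) for i, r in enumerate([0.1, 0.2, 0.3])]
        e = weighted_median(walds, bootstrap_reps=100, seed=0)
        assert e.beta == pytest.approx(0.2)

    def test_unequal_weight_interpolation(self):
        # standardized weights {0.25, 0.25, 0.5}: se ratio 1 : 1 : 1/sqrt(2)
        walds = [WaldEstimate("a", 0.1, 0.2), WaldEstimate("b", 0.2, 0.2),
                 WaldEstimate("c", 0.4, 0.2 / np.sqrt(2))]
        e = weighted_median(walds, bootstrap_reps=100, seed=0)
        # oracle: interpolate 0.5 between p2 = 0.375 and p3 = 0.75
        assert e.beta == pytest.approx(0.2667, abs=2e-4)

    def test_degenerate_identical_ratios_small_se(self):
        walds = [WaldEstimate(f"s{i}", 0.25, 1e-6) for i in range(5)]
        e = weighted_median(walds, bootstrap_reps=200, seed=1)
        assert e.beta == pytest.approx(0.25)
        assert e.se < 1e-5

    def test_too_few_instruments(self):
        with pytest.raises(EstimatorError, match="too_few_instruments"):
            weighted_median(TWO_SNP, 100, 0)

    def test_bootstrap_seed_reproducible(self):
        walds = [WaldEstimate(f"s{i}", r, 0.1) for i, r in enumerate([0.1, 0.25, 0.3, 0.5])]
        a = weighted_median(walds, 300, seed=42)
        b = weighted_median(walds, 300, seed=42)
        assert a.se == b.se

    @given(st.lists(st.tuples(st.floats(-2, 2), st.floats(0.01, 1)), min_size=3, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_within_ratio_range(self, pairs):
        walds = [WaldEstimate(f"s{i}", r, se) for i, (r, se) in enumerate(pairs)]
        e = weighted_median(walds, bootstrap_reps=10, seed=0)
        ratios = [w.ratio for w in walds]
        assert min(ratios) - 1e-12 <= e.beta <= max(ratios) + 1e-12

    @given(st.lists(st.floats(-1, 1), min_size=3, max_size=11).filter(lambda l: len(l) % 2 == 1))
    @settings(max_examples=60, deadline=None)
    def test_equal_weights_odd_j_is_sample_median(self, ratios):
        walds = [WaldEstimate(f"s{i}", r, 0.1) for i, r in enumerate(ratios)]
        e = weighted_median(walds, bootstrap_reps=10, seed=0)
        assert e.beta == pytest.approx(float(np.median(ratios)), abs=1e-12)


class TestMREgger:
    def _line(self, intercept=0.01, slope=0.3, gammas=(0.2, 0.4, 0.6), sy=0.05):
        return [hinst(snp_id=f"s{i}", bx=g, by=intercept + slope * g, sy=sy)
                for i, g in enumerate(gammas)]

    def test_noiseless_line_recovered_exactly(self):
        e = mr_egger(self._line())
        assert e.beta == pytest.approx(0.3, abs=1e-12)
        assert e.egger_intercept == pytest.approx(0.01, abs=1e-12)

    def test_orientation_invariance(self):
        inst = self._line()
        neg = list(inst)
        i = inst[1]
        neg[1] = hinst(snp_id=i.snp_id, bx=-i.beta_exposure, by=-i.beta_outcome,
                       sy=i.se_outcome)
        a, b = mr_egger(inst), mr_egger(neg)
        assert a.beta == pytest.approx(b.beta, abs=1e-14)
        assert a.egger_intercept == pytest.approx(b.egger_intercept, abs=1e-14)

    def test_matches_statsmodels_wls_oracle(self):
        """Dual route: closed-form WLS vs the statsmodels fit on a noisy fixture."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        bx = np.array([0.2, 0.35, 0.5, 0.8])
        sy = np.array([0.02, 0.03, 0.025, 0.04])
        by = 0.012 + 0.27 * bx + rng.normal(0, 0.03, 4)
        inst = [hinst(snp_id=f"s{i}", bx=bx[i], by=by[i], sy=sy[i]) for i in range(4)]
        e = mr_egger(inst)
        fit = sm.WLS(by, sm.add_constant(bx), weights=sy ** -2).fit()
        assert e.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert e.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
        # statsmodels bse scales by the residual dispersion; ours floors it at 1
        sigma = np.sqrt(fit.scale)
        expected_se = fit.bse[1] / sigma * max(1.0, sigma)
        assert e.se == pytest.approx(expected_se, rel=1e-8)

    def test_collinear_design_is_error(self):
        inst = [hinst(snp_id=f"s{i}", bx=0.3, by=0.1) for i in range(3)]
        with pytest.raises(EstimatorError, match="collinear"):
            mr_egger(inst)

    def test_too_few_instruments(self):
        with pytest.raises(EstimatorError):
            mr_egger(self._line()[:2])


def _iset(instruments, ld=None):
    return HarmonizedInstrumentSet(instruments=instruments, ld=ld)


class TestPcaIvw:
    def test_identity_ld_equals_fixed_ivw(self):
        inst = [hinst(snp_id=f"s{i}", bx=bx, by=by, sy=sy)
                for i, (bx, by, sy) in enumerate(
                    [(0.5, 0.02, 0.01), (0.3, 0.015, 0.012), (0.4, 0.01, 0.02)])]
        ld = LDMatrix([i.snp_id for i in inst], np.eye(3))
        e = pca_ivw(_iset(inst, ld), variance_kept=1.0)
        ref = ivw([wald_ratio(i) for i in inst], 1e-12)
        assert e.beta == pytest.approx(ref.beta, abs=1e-10)
        assert e.se == pytest.approx(ref.se, abs=1e-10)
        assert e.n_components == 3

    def test_duplicated_snp_collapses_to_single_wald(self):
        a = hinst(snp_id="s1", bx=0.5, by=0.02, sy=0.01)
        b = hinst(snp_id="s2", bx=0.5, by=0.02, sy=0.01)
        ld = LDMatrix(["s1", "s2"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        e = pca_ivw(_iset([a, b], ld), variance_kept=0.99)
        w = wald_ratio(a)
        assert e.n_components == 1
        assert e.beta == pytest.approx(w.ratio, abs=1e-10)
        assert e.se == pytest.approx(w.se, abs=1e-10)

    def test_two_uncorrelated_equal_ratios(self):
        inst = [hinst(snp_id="s1", bx=0.5, by=0.05, sy=0.01),
                hinst(snp_id="s2", bx=0.2, by=0.02, sy=0.01)]
        ld = LDMatrix(["s1", "s2"], np.eye(2))
        e = pca_ivw(_iset(inst, ld), variance_kept=1.0)
        assert e.beta == pytest.approx(0.1, abs=1e-10)

    def test_full_rank_agrees_with_direct_gls(self):
        rng = np.random.default_rng(11)
        J = 6
        bx = rng.uniform(0.2, 0.8, J)
        sy = rng.uniform(0.01, 0.05, J)
        by = 0.25 * bx + rng.normal(0, 0.01, J)
        rho = 0.4 ** np.abs(np.subtract.outer(np.arange(J), np.arange(J))).astype(float)
        inst = [hinst(snp_id=f"s{i}", bx=bx[i], by=by[i], sy=sy[i]) for i in range(J)]
        ld = LDMatrix([f"s{i}" for i in range(J)], rho)
        e = pca_ivw(_iset(inst, ld), variance_kept=1.0)
        # oracle: GLS on the untransformed system
        sigma = np.outer(sy, sy) * rho
        sinv_g = np.linalg.solve(sigma, bx)
        beta_gls = (bx @ np.linalg.solve(sigma, by)) / (bx @ sinv_g)
        se_gls = (bx @ sinv_g) ** -0.5
        assert e.beta == pytest.approx(beta_gls, abs=1e-8)
        assert e.se == pytest.approx(se_gls, abs=1e-8)

    def test_requires_ld(self):
        with pytest.raises(EstimatorError):
            pca_ivw(_iset([hinst()]), 0.99)


class TestEstimateAll:
    def test_three_uncorrelated_without_ld(self, config):
        inst = [hinst(snp_id=f"s{i}", bx=0.3 + 0.1 * i, by=0.01 * (i + 1)) for i in range(3)]
        cfg = RunConfig(wm_bootstrap_reps=50)
        ests, skipped = estimate_all(_iset(inst), cfg)
        methods = {e.method for e in ests}
        assert {"weighted_median", "mr_egger"} <= methods
        assert any(m.startswith("ivw") for m in methods)
        assert ("pca_ivw", "no_ld_matrix") in skipped

    def test_correlated_with_ld_includes_pca(self):
        J = 5
        inst = [hinst(snp_id=f"s{i}", bx=0.3 + 0.05 * i, by=0.01) for i in range(J)]
        rho = 0.5 ** np.abs(np.subtract.outer(np.arange(J), np.arange(J))).astype(float)
        ld = LDMatrix([f"s{i}" for i in range(J)], rho)
        ests, skipped = estimate_all(_iset(inst, ld), RunConfig(wm_bootstrap_reps=50))
        assert "pca_ivw" in {e.method for e in ests}

    def test_single_instrument_reports_skips(self, config):
        ests, skipped = estimate_all(_iset([hinst()]), config)
        assert len(ests) == 1 and ests[0].method == "ivw_fixed"
        assert {m for m, _ in skipped} == {"weighted_median", "mr_egger", "pca_ivw"}
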