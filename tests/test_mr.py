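"""Two-sample MR estimators: closed forms, diagnostics, robustness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cihmet import mr, synthio


def _inst(bx, by, sex=None, sey=None):
    k = len(bx)
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(k)],
            "beta_exposure": bx,
            "se_exposure": sex if sex is not None else [0.01] * k,
            "beta_outcome": by,
            "se_outcome": sey if sey is not None else [0.05] * k,
        }
    )


class TestWaldRatio:
    def test_direct_division_and_delta_se(self):
        est = mr.wald_ratio(bx=0.1, by=0.2, sey=0.05)
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.5)

    def test_zero_outcome_effect(self):
        assert mr.wald_ratio(bx=0.1, by=0.0, sey=0.05).beta == 0.0

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError, match="exposure"):
            mr.wald_ratio(bx=0.0, by=0.1, sey=0.05)

    def test_delta_se_matches_monte_carlo(self, rng):
        bx, by, sey = 0.2, 0.1, 0.03
        draws = (by + rng.normal(0, sey, 10**6)) / bx
        assert mr.wald_ratio(bx, by, sey).se == pytest.approx(draws.std(ddof=1), rel=0.02)


class TestIVW:
    def test_single_instrument_collapses_to_wald(self):
        inst = _inst([0.1], [0.25], sey=[0.04])
        est = mr.ivw(inst, effects="fixed")
        wald = mr.wald_ratio(0.1, 0.25, 0.04)
        assert est.beta == pytest.approx(wald.beta, abs=1e-14)
        assert est.se == pytest.approx(wald.se, abs=1e-14)

    def test_perfectly_consistent_instruments(self):
        bx = np.array([0.1, 0.2, 0.3])
        inst = _inst(bx, 2.0 * bx, sey=[0.05] * 3)
        est = mr.ivw(inst, effects="random")
        assert est.beta == pytest.approx(2.0, abs=1e-12)
        assert est.q_stat == pytest.approx(0.0, abs=1e-20)
        assert est.se == pytest.approx(mr.ivw(inst, effects="fixed").se)

    def test_fixed_beta_is_weighted_mean_of_ratios(self, rng):
        inst = synthio.generate_mr_dataset(30, 0.4, 0.2, seed=8)
        est = mr.ivw(inst, effects="fixed")
        w = (inst["beta_exposure"] / inst["se_outcome"]) ** 2
        ratios = inst["beta_outcome"] / inst["beta_exposure"]
        assert est.beta == pytest.approx(float((w * ratios).sum() / w.sum()), abs=1e-12)

    def test_coverage_of_true_slope(self):
        covered = 0
        for seed in range(100):
            inst = synthio.generate_mr_dataset(50, 0.3, 0.0, seed=seed)
            est = mr.ivw(inst, effects="random")
            covered += est.ci_low <= 0.3 <= est.ci_high
        assert covered >= 93

    def test_random_effects_se_never_below_fixed(self, rng):
        for seed in range(20):
            inst = synthio.generate_mr_dataset(25, 0.2, 0.3, pleiotropy_scale=0.2, seed=seed)
            assert mr.ivw(inst, "random").se >= mr.ivw(inst, "fixed").se - 1e-15

    def test_exposure_scale_equivariance(self):
        inst = synthio.generate_mr_dataset(20, 0.3, 0.0, seed=3)
        scaled = inst.copy()
        scaled["beta_exposure"] *= 4.0
        scaled["se_exposure"] *= 4.0
        for effects in ("fixed", "random"):
            assert mr.ivw(scaled, effects).beta == pytest.approx(mr.ivw(inst, effects).beta / 4.0, rel=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            mr.ivw(_inst([], []))


class TestMREgger:
    def test_zero_intercept_constraint_reproduces_ivw(self):
        import statsmodels.api as sm

        inst = synthio.generate_mr_dataset(40, 0.3, 0.2, seed=4)
        bx = np.abs(inst["beta_exposure"].to_numpy())
        by = inst["beta_outcome"].to_numpy() * np.sign(inst["beta_exposure"].to_numpy())
        res = sm.WLS(by, bx[:, None], weights=1 / inst["se_outcome"] ** 2).fit()
        assert res.params[0] == pytest.approx(mr.ivw(inst, "fixed").beta, abs=1e-12)

    def test_null_intercept_p_is_uniform(self):
        ps = []
        for seed in range(400):
            inst = synthio.generate_mr_dataset(30, 0.3, 0.0, seed=seed)
            ps.append(mr.mr_egger(inst).intercept_p)
        stat, _ = stats.kstest(ps, "uniform")
        assert stat < 0.08  # KS 1% critical value for n=400 is ~0.081

    def test_constant_pleiotropy_lands_in_intercept(self):
        betas, icpts = [], []
        for seed in range(50):
            inst = synthio.generate_mr_dataset(50, 0.3, 0.0, seed=seed)
            inst["beta_outcome"] += 0.05
            est = mr.mr_egger(inst)
            betas.append(est.beta)
            icpts.append(est.intercept)
        assert np.mean(icpts) == pytest.approx(0.05, abs=0.01)
        assert np.mean(betas) == pytest.approx(0.3, abs=0.05)

    def test_under_identified_and_degenerate_designs_rejected(self):
        with pytest.raises(ValueError, match="under-identified"):
            mr.mr_egger(_inst([0.1, 0.2], [0.0, 0.1]))
        with pytest.raises(ValueError, match="degenerate"):
            mr.mr_egger(_inst([0.1, 0.1, 0.1], [0.0, 0.1, 0.2]))


class TestWeightedMedian:
    def test_equal_weight_odd_count_median(self):
        inst = _inst([1.0, 1.0, 1.0], [1.0, 2.0, 9.0], sey=[1.0] * 3)
        assert mr.weighted_median(inst, n_boot=10, seed=0).beta == pytest.approx(2.0)

    def test_robust_to_forty_percent_invalid_instruments(self):
        # precise instruments (large-GWAS outcome SEs) with directional
        # offsets ~17x the per-SNP signal; the valid majority-of-weight
        # keeps the weighted median near the true slope
        ok = 0
        for seed in range(100):
            inst = synthio.generate_mr_dataset(
                50, 0.3, 0.4, pleiotropy_scale=0.5, seed=seed, se_outcome_range=(0.004, 0.01)
            )
            ok += abs(mr.weighted_median(inst, n_boot=200, seed=seed).beta - 0.3) <= 0.1
        assert ok >= 90

    def test_bootstrap_se_stable_across_seeds(self):
        inst = synthio.generate_mr_dataset(40, 0.3, 0.1, seed=6)
        se1 = mr.weighted_median(inst, n_boot=5000, seed=1).se
        se2 = mr.weighted_median(inst, n_boot=5000, seed=2).se
        assert abs(se1 - se2) / se1 < 0.05

    def test_single_instrument_rejected(self):
        with pytest.raises(ValueError):
            mr.weighted_median(_inst([0.1], [0.1]))


class TestCochranQAndLeaveOneOut:
    def test_consistent_ratios_give_zero_q(self):
        bx = np.array([0.1, 0.2, 0.4])
        q, df, p = mr.cochran_q(_inst(bx, 1.5 * bx))
        assert q == pytest.approx(0.0, abs=1e-18)
        assert df == 2 and p == pytest.approx(1.0)

    def test_null_q_mean_matches_chi_square_df(self):
        k = 20
        qs = []
        for seed in range(1000):
            inst = synthio.generate_mr_dataset(k, 0.3, 0.0, seed=seed)
            qs.append(mr.cochran_q(inst)[0])
        se = np.sqrt(2 * (k - 1) / len(qs))
        assert np.mean(qs) == pytest.approx(k - 1, abs=5 * se + 0.5)

    def test_outlier_dominates_q_by_hand(self):
        bx = np.full(7, 0.1)
        by = np.array([0.03] * 6 + [0.5])
        inst = _inst(bx, by, sey=[0.05] * 7)
        beta_ref = mr.ivw(inst, "fixed").beta
        q, _, _ = mr.cochran_q(inst, beta_ref)
        w = (bx / 0.05) ** 2
        terms = w * (by / bx - beta_ref) ** 2
        assert q == pytest.approx(float(terms.sum()), rel=1e-12)
        assert terms[6] / q > 0.8

    def test_leave_one_out_k2_collapses_to_other_wald(self):
        inst = _inst([0.1, 0.2], [0.2, 0.5], sey=[0.05, 0.04])
        loo = mr.leave_one_out(inst)
        assert loo.loc[loo["snp_dropped"] == "rs0", "beta"].iloc[0] == pytest.approx(0.5 / 0.2)
        assert loo.loc[loo["snp_dropped"] == "rs1", "beta"].iloc[0] == pytest.approx(0.2 / 0.1)

    def test_homogeneous_set_has_no_flags(self):
        inst = synthio.generate_mr_dataset(30, 0.3, 0.0, seed=11)
        assert not mr.leave_one_out(inst)["outside_full_ci"].any()

    def test_planted_outlier_is_flagged(self):
        # a tight inlier cluster (identical precise ratios) plus one gross
        # outlier: only the outlier's removal moves the pooled estimate
        # outside the full-set confidence interval
        bx = [0.1] * 12
        by = [0.03] * 11 + [0.13]
        inst = _inst(bx, by, sey=[0.005] * 12)
        loo = mr.leave_one_out(inst, effects="fixed")
        flagged = loo.loc[loo["outside_full_ci"], "snp_dropped"].tolist()
        assert flagged == ["rs11"]


def test_mr_suite_reports_all_methods():
    inst = synthio.generate_mr_dataset(20, 0.3, 0.0, seed=1)
    suite = mr.mr_suite(inst, seed=0)
    assert set(suite["method"]) == {"ivw_fixed", "ivw_random", "mr_egger", "weighted_median"}
    assert suite["se"].gt(0).all()
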