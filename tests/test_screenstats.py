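import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phenoscreen.profclass import CVSpec
from phenoscreen.screenstats import (
    bootstrap_median_ci,
    call_hits,
    compare_groups,
    loocv_attribution,
    replicate_power,
    z_factor,
)

from conftest import planted_feature_table


class TestZFactor:
    def test_closed_form_point_four(self):
        rng = np.random.default_rng(0)
        # construct samples with exact means/SDs 1/0 and 0.1/0.1
        def exact(mu, sd, n=50):
            x = rng.normal(0, 1, n)
            return mu + sd * (x - x.mean()) / x.std(ddof=1)

        res = z_factor(exact(1.0, 0.1), exact(0.0, 0.1))
        assert res.z == pytest.approx(0.4, abs=1e-12)

    def test_zero_spread_gives_one(self):
        res = z_factor([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        assert res.z == 1.0

    def test_equal_means_flagged_undefined(self):
        res = z_factor([1.0, 3.0], [3.0, 1.0])
        assert not res.defined
        assert res.z == -np.inf

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            z_factor([1.0], [0.0, 0.1])

    @given(
        gap=st.floats(min_value=0.5, max_value=10),
        extra=st.floats(min_value=0.1, max_value=5),
    )
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_separation_and_spread(self, gap, extra):
        rng = np.random.default_rng(1)
        base_p = rng.normal(0, 0.2, 40)
        base_n = rng.normal(0, 0.2, 40)
        z1 = z_factor(base_p + gap, base_n).z
        z2 = z_factor(base_p + gap + extra, base_n).z
        assert z2 > z1  # larger separation, same SDs
        z3 = z_factor((base_p - base_p.mean()) * (1 + extra) + base_p.mean() + gap, base_n).z
        assert z3 < z1  # inflated sigma_p


class TestCallHits:
    def test_all_at_median_no_hits(self):
        ref = np.array([0.0, 1.0, -1.0, 0.5, -0.5, 0.2, -0.2, 0.0])
        res = call_hits(np.full(5, np.median(ref)), ref)
        assert not res.wells["hit"].any()

    def test_single_well_beyond_4sd_flagged(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(0, 1, 100)
        m, s = np.median(ref), ref.std(ddof=1)
        scores = np.concatenate([[m + 4 * s], ref[:20]])
        res = call_hits(scores, ref, k=3)
        # only wells genuinely beyond 3 SDs flagged; the planted one must be
        assert res.wells["hit"].iloc[0]
        assert res.wells["hit"].sum() == 1 + (np.abs((ref[:20] - m) / s) > 3).sum()

    def test_null_rate_matches_two_sided_normal_tail(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(0, 1, 10_000)
        scores = rng.normal(0, 1, 10_000)
        res = call_hits(scores, ref, k=3)
        p = 2 * stats.norm.cdf(-3)  # 0.0027
        se = np.sqrt(p * (1 - p) / 10_000)
        frac = res.wells["hit"].mean()
        assert frac < 0.01
        assert abs(frac - p) <= 3 * se

    def test_degenerate_reference_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = call_hits([1.0, 2.0], np.ones(10))
        assert res.degenerate
        assert not res.wells["hit"].any()

    def test_fractions_by_condition(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(0, 1, 200)
        scores = np.concatenate([rng.normal(0, 1, 50), rng.normal(8, 1, 50)])
        conds = ["null"] * 50 + ["shifted"] * 50
        res = call_hits(scores, ref, conditions=conds)
        assert res.hit_fraction_by_condition["shifted"] > 0.95
        assert res.hit_fraction_by_condition["null"] < 0.05


class TestReplicatePower:
    def test_minimal_n_is_11_at_d2_k3(self):
        res = replicate_power("normal", d=2, k=3, power_target=0.85,
                              n_max=50, method="analytic")
        assert res.minimal_n == 11

    def test_minimal_n_is_1_at_d6(self):
        res = replicate_power("normal", d=6, k=3, power_target=0.85,
                              n_max=10, method="analytic")
        assert res.minimal_n == 1

    def test_d0_two_sided_minimal_n_702(self):
        res = replicate_power("normal", d=0, k=3, power_target=0.85,
                              n_max=1000, directional=False, method="analytic")
        assert res.minimal_n == 702

    def test_mc_matches_closed_form_within_3_se(self):
        n_sim = 4000
        res = replicate_power("normal", d=2, k=3, n_max=30, n_sim=n_sim,
                              method="mc", seed=5)
        p = stats.norm.cdf(2 - 3)
        for n in (1, 5, 11, 20, 30):
            exact = 1 - (1 - p) ** n
            se = np.sqrt(exact * (1 - exact) / n_sim)
            assert abs(res.power_by_n.loc[n] - exact) <= 3 * se, n

    def test_power_curve_non_decreasing(self):
        res = replicate_power("normal", d=1.5, k=3, n_max=100, n_sim=500, seed=6)
        assert (res.power_by_n.diff().dropna() >= 0).all()

    def test_empirical_null_accepted(self):
        rng = np.random.default_rng(7)
        res = replicate_power(rng.normal(0, 1, 500), d=3, k=3, n_max=40,
                              n_sim=500, seed=7)
        assert res.minimal_n is not None

    def test_unreached_target_reported_not_error(self):
        res = replicate_power("normal", d=0.5, k=3, power_target=0.99,
                              n_max=5, n_sim=200, seed=8)
        assert res.minimal_n is None

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            replicate_power("normal", d=-1)
        with pytest.raises(ValueError):
            replicate_power("normal", power_target=1.5)


class TestCompareGroups:
    def test_identical_samples_p_near_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        stat, p, used = compare_groups(x, x.copy(), test="mannwhitney")
        assert p >= 0.99

    def test_mannwhitney_exact_oracle(self):
        # independent oracle: enumerate all C(6,3) rank splits
        combined = [1, 2, 3, 4, 5, 6]
        u_obs = 0  # no y < x pairs for x={1,2,3}, y={4,5,6}
        count_extreme = 0
        us = []
        for xs in itertools.combinations(combined, 3):
            ys = [v for v in combined if v not in xs]
            u = sum(1 for a in xs for b in ys if a > b)
            us.append(u)
        u_min = min(u_obs, 9 - u_obs)
        count_extreme = sum(1 for u in us if min(u, 9 - u) <= u_min)
        p_exact = count_extreme / len(us)
        assert p_exact == pytest.approx(0.1)
        stat, p, used = compare_groups([1, 2, 3], [4, 5, 6], test="mannwhitney")
        assert stat == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_strong_shift_significant(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 50)
        y = rng.normal(3, 1, 50)
        for test in ("mannwhitney", "welch", "auto"):
            _, p, _ = compare_groups(x, y, test=test)
            assert p < 0.001

    def test_all_tied_warns_p_one(self):
        with pytest.warns(UserWarning, match="tied"):
            _, p, used = compare_groups([1.0] * 5, [1.0] * 5)
        assert p == 1.0 and used == "degenerate"

    def test_auto_selects_welch_for_normal_data(self):
        rng = np.random.default_rng(10)
        _, _, used = compare_groups(rng.normal(0, 1, 80), rng.normal(0.5, 1, 80), test="auto")
        assert used == "welch"

    def test_min_group_size(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2], [3, 4, 5])


class TestBootstrapCI:
    def test_constant_vector_zero_width(self):
        lo, hi = bootstrap_median_ci(np.full(20, 3.5), seed=0)
        assert lo == hi == 3.5

    def test_coverage_of_true_median(self):
        rng = np.random.default_rng(11)
        hits = 0
        for seed in range(40):
            x = rng.normal(0, 1, 1000)
            lo, hi = bootstrap_median_ci(x, n_boot=1000, seed=seed)
            hits += lo <= 0 <= hi
        assert hits >= 36  # >= 90% of repetitions cover the true median

    def test_single_resample_degenerate(self):
        x = np.arange(10.0)
        lo, hi = bootstrap_median_ci(x, n_boot=1, seed=1)
        assert lo == hi

    def test_deterministic_given_seed(self):
        x = np.random.default_rng(12).normal(size=50)
        assert bootstrap_median_ci(x, seed=3) == bootstrap_median_ci(x, seed=3)

    def test_min_size(self):
        with pytest.raises(ValueError):
            bootstrap_median_ci([1.0, 2.0, 3.0])


class TestLOOCV:
    CV = CVSpec(n_repeats=5, seed=0)
    GRID = {"clf__C": [1.0]}

    def test_planted_feature_ranks_first(self):
        t = planted_feature_table(n_per_class=60, n_noise=10, effect=1.4, seed=1)
        res = loocv_attribution(t, "neg", "pos", "SVM", self.CV, grid=self.GRID)
        assert len(res.table) == 11
        assert res.ranked_features()[0] == "informative"
        top, runner = res.table["delta_z"].iloc[0], res.table["delta_z"].iloc[1]
        assert top - runner >= 0.1

    def test_duplicate_informative_features_share_credit(self):
        t = planted_feature_table(n_per_class=60, n_noise=5, effect=1.4, seed=2)
        t["informative_copy"] = t["informative"]
        res = loocv_attribution(t, "neg", "pos", "SVM", self.CV, grid=self.GRID)
        for f in ("informative", "informative_copy"):
            dz = res.table.loc[res.table["feature"] == f, "delta_z"].iloc[0]
            assert abs(dz) < 0.05, f

    def test_all_noise_attributions_small_and_sign_mixed(self):
        # without signal Z_full is strongly negative (tiny mean separation in
        # the denominator), so |delta_z| is judged relative to |Z_full|
        t = planted_feature_table(n_per_class=60, n_noise=8, effect=1.0, seed=3)
        res = loocv_attribution(t, "neg", "pos", "SVM", self.CV, grid=self.GRID)
        assert res.z_full < 0
        assert (res.table["z_without"] < 0).all()  # no feature rescues the assay
        assert (res.table["delta_z"].abs() <= 0.5 * abs(res.z_full)).all()
        signs = np.sign(res.table["delta_z"])
        assert (signs > 0).any() and (signs < 0).any()

    def test_single_feature_rejected(self):
        t = planted_feature_table(n_per_class=20, n_noise=0)
        with pytest.raises(ValueError, match="leave one out"):
            loocv_attribution(t, "neg", "pos", "SVM", self.CV, grid=self.GRID)
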