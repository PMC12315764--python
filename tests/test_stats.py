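import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from hybridqmt.atlas import LobeMap
from hybridqmt.stats import (bonferroni_threshold, effect_category, hedges_g,
                             lobar_aggregate, mann_whitney_u, pearson,
                             run_correlation_analysis, run_group_analysis)
from hybridqmt.synthetic import CohortSpec, generate_cohort


def make_measurements(rows):
    return pd.DataFrame(rows, columns=["subject", "group", "hemisphere", "roi",
                                       "measure", "mean", "sample_variance",
                                       "n_samples"])


class TestLobarAggregate:
    LOBEMAP = LobeMap(lobes={"L": ("a", "b")}, exclusions=())

    def _table(self, entries):
        rows = [("s1", "Abeta_neg", "left", roi, "m", m, v, n)
                for roi, m, v, n in entries]
        return make_measurements(rows)

    def test_equal_weights_give_arithmetic_mean(self):
        out = lobar_aggregate(self._table([("a", 1.0, 2.0, 10), ("b", 3.0, 2.0, 10)]),
                              self.LOBEMAP)
        assert out["value"].iloc[0] == pytest.approx(2.0, rel=1e-12)

    def test_single_roi_lobe(self):
        lm = LobeMap(lobes={"L": ("a",)}, exclusions=())
        out = lobar_aggregate(self._table([("a", 4.2, 1.0, 5)]), lm)
        assert out["value"].iloc[0] == pytest.approx(4.2, rel=1e-12)

    def test_hand_computed_weighted_mean(self):
        # weights n/s^2: 10/1 = 10 and 10/4 = 2.5 -> (10*1 + 2.5*3)/12.5 = 1.4
        out = lobar_aggregate(self._table([("a", 1.0, 1.0, 10), ("b", 3.0, 4.0, 10)]),
                              self.LOBEMAP)
        assert out["value"].iloc[0] == pytest.approx(1.4, rel=1e-12)

    def test_sample_variance_weighting_mode(self):
        # weights 1/s^2 ignore n: 1 and 0.25 -> (1 + 0.75)/1.25 = 1.4 as well
        # with distinct n the two modes differ
        tab = self._table([("a", 1.0, 1.0, 100), ("b", 3.0, 4.0, 10)])
        w_mean = lobar_aggregate(tab, self.LOBEMAP, weighting="mean_variance")
        w_samp = lobar_aggregate(tab, self.LOBEMAP, weighting="sample_variance")
        assert w_mean["value"].iloc[0] != w_samp["value"].iloc[0]
        assert w_samp["value"].iloc[0] == pytest.approx((1 + 0.25 * 3) / 1.25, rel=1e-12)

    def test_excluded_roi_dropped(self):
        lm = LobeMap(lobes={"L": ("a", "b")}, exclusions=("b",))
        out = lobar_aggregate(self._table([("a", 1.0, 1.0, 10), ("b", 9.0, 1.0, 10)]),
                              lm)
        assert out["value"].iloc[0] == pytest.approx(1.0, rel=1e-12)

    def test_zero_variance_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capped"):
            out = lobar_aggregate(self._table([("a", 2.0, 0.0, 10),
                                               ("b", 4.0, 1.0, 10)]), self.LOBEMAP)
        assert out["value"].iloc[0] == pytest.approx(2.0, abs=1e-9)


class TestMannWhitney:
    def test_identical_groups(self):
        u, p = mann_whitney_u([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], mode="exact")
        assert u == 4.5  # n1*n2/2 with all ties
        assert p == 1.0

    def test_complete_separation_3v3(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert u in (0.0, 9.0)
        assert p == pytest.approx(0.1, abs=1e-12)  # 2 extreme / C(6,3)=20

    def test_exact_matches_scipy_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for n1, n2 in [(2, 2), (3, 3), (4, 4), (5, 5), (3, 5), (4, 6)]:
            a, b = rng.standard_normal(n1), rng.standard_normal(n2)
            u, p = mann_whitney_u(a, b, mode="exact")
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert u == float(ref.statistic)
            assert p == pytest.approx(float(ref.pvalue), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_exact_vs_normal_mode_close(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal(6), rng.standard_normal(6)
        _, p_exact = mann_whitney_u(a, b, mode="exact")
        _, p_norm = mann_whitney_u(a, b, mode="normal")
        assert abs(p_exact - p_norm) < 0.05

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([1.0], [2.0, 3.0])


class TestHedgesG:
    def test_equal_means_small(self):
        g, cat = hedges_g([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
        assert g == pytest.approx(0.0, abs=1e-12)
        assert cat == "small"

    def test_hand_example(self):
        # d = 2, J = 1 - 3/15 = 0.8 -> g = 1.6, very large
        g, cat = hedges_g([3, 4, 5], [1, 2, 3])
        assert g == pytest.approx(1.6, abs=1e-12)
        assert cat == "very_large"

    def test_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(23)
        a, b = rng.standard_normal(8), 0.5 + rng.standard_normal(9)
        g1, _ = hedges_g(a, b)
        g2, _ = hedges_g(b, a)
        assert g1 == pytest.approx(-g2, rel=1e-12)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            hedges_g([1.0, 1.0], [1.0, 1.0])

    def test_category_cutoffs(self):
        assert effect_category(0.49) == "small"
        assert effect_category(-0.5) == "medium"
        assert effect_category(0.8) == "large"
        assert effect_category(-1.2) == "very_large"


class TestBonferroni:
    def test_five_lobar_comparisons(self):
        assert bonferroni_threshold(0.05, 5) == pytest.approx(0.01, abs=1e-15)

    def test_subcortical_family_reported_3dp(self):
        assert bonferroni_threshold(0.05, 7, decimals=3) == 0.007

    def test_single_comparison(self):
        assert bonferroni_threshold(0.037, 1) == 0.037


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(29)
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        res = pearson(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_direct = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert res.pearson_r == pytest.approx(r_direct, abs=1e-12)
        t = r_direct * np.sqrt(10 / (1 - r_direct**2))
        p_direct = 2 * sps.t.sf(abs(t), 10)
        assert res.p_value == pytest.approx(p_direct, rel=1e-9)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(31)
        ps = [pearson(rng.standard_normal(30), rng.standard_normal(30)).p_value
              for _ in range(1000)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def lobar():
    tab, _ = generate_cohort(CohortSpec(seed=5))
    return lobar_aggregate(tab)


class TestGroupAnalysis:
    def test_deterministic(self, lobar):
        r1 = run_group_analysis(lobar, family_size=5)
        r2 = run_group_analysis(lobar, family_size=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_row_per_measure_lobe(self, lobar):
        res = run_group_analysis(lobar, family_size=5)
        assert len(res) == lobar["measure"].nunique() * lobar["lobe"].nunique()
        assert set(res["n_pos"]) == {18} and set(res["n_neg"]) == {12}

    def test_bonferroni_marker_implies_nominal_marker(self, lobar):
        res = run_group_analysis(lobar, family_size=5)
        starred = res[res["significant_bonferroni"] == "**"]
        assert (starred["significant"] == "*").all()

    def test_programmed_negative_effect_recovered_in_sign(self):
        spec = CohortSpec(seed=11, effects={("Rx", "temporal"): -1.5})
        tab, _ = generate_cohort(spec)
        res = run_group_analysis(lobar_aggregate(tab)).set_index(["measure", "lobe"])
        assert res.loc[("Rx", "temporal"), "hedges_g"] < 0

    def test_hemisphere_averaged_mode(self, lobar):
        res = run_group_analysis(lobar, hemisphere_mode="averaged")
        assert set(res["n_pos"]) == {9} and set(res["n_neg"]) == {6}


class TestCorrelationAnalysis:
    def test_coupled_suvr_correlates(self):
        spec = CohortSpec(seed=13, n_neg=30, n_pos=30,
                          suvr_coupling={"Rx": -0.8})
        tab, _ = generate_cohort(spec)
        res = run_correlation_analysis(lobar_aggregate(tab))
        rx = res[res["measure"] == "Rx"].set_index("lobe")
        assert rx.loc["temporal", "pearson_r"] < 0
        assert rx.loc["temporal", "significant"] == "*"

    def test_missing_suvr_rejected(self):
        tab, _ = generate_cohort(CohortSpec(seed=1, control={"m0s": (0.1, 0.01)}))
        with pytest.raises(ValueError):
            run_correlation_analysis(lobar_aggregate(tab))


def test_exact_mann_whitney_full_enumeration_property():
    """Exact p equals the fraction of labelings at least as extreme, for all
    group splits with n1 + n2 <= 10 on a fixed tied dataset."""
    pooled = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0, 6.0, 7.0, 7.0])
    for n1 in range(2, 9):
        n2_max = min(10 - n1, 5)
        for n2 in range(2, n2_max + 1):
            data = pooled[:n1 + n2]
            a, b = data[:n1], data[n1:]
            u_obs, p = mann_whitney_u(a, b, mode="exact")
            # brute-force oracle: independent enumeration via rank sums
            mid = n1 * n2 / 2
            count = total = 0
            for comb in itertools.combinations(range(n1 + n2), n1):
                mask = np.zeros(n1 + n2, bool)
                mask[list(comb)] = True
                x, y = data[mask], data[~mask]
                u = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
                count += abs(u - mid) >= abs(u_obs - mid) - 1e-12
                total += 1
            assert p == pytest.approx(count / total, abs=1e-12)
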