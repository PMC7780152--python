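"""Scalar quantifications, ordinal binning and group statistics.

The statistics oracle here is hand-coded closed form (pooled-variance
t, sums-of-squares ANOVA F, studentized-range Tukey p) — independent of
the scipy/statsmodels routines the implementation calls.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from gland3d import (ComponentSet, area_fraction, bin_expression,
                     compare_groups, correlate, count_per_volume,
                     expression_heatmap, follicle_density, positive_fraction)

from conftest import SPACING, make_ball_mask


# ---------------------------------------------------------------------------
# closed-form oracles
# ---------------------------------------------------------------------------

def pooled_t_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), na + nb - 2)
    return t, p


def anova_f_oracle(groups):
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    return f, sps.f.sf(f, df_b, df_w)


def tukey_p_oracle(groups):
    """Pairwise Tukey HSD p-values from the studentized-range distribution."""
    k = len(groups)
    df_w = sum(len(g) for g in groups) - k
    mse = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups) / df_w
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = len(groups[i]), len(groups[j])
            se = np.sqrt(mse / 2 * (1 / ni + 1 / nj))
            q = abs(np.mean(groups[i]) - np.mean(groups[j])) / se
            out.append(float(sps.studentized_range.sf(q, k, df_w)))
    return out


class TestAreaFraction:
    def test_full_and_empty(self):
        region = np.ones((6, 6, 6), bool)
        assert area_fraction(region, region) == 100.0
        assert area_fraction(np.zeros_like(region), region) == 0.0

    def test_planted_40pct_recovered(self):
        rng = np.random.default_rng(0)
        region = np.ones((20, 20, 20), bool)
        marker = rng.random(region.shape) < 0.40
        assert area_fraction(marker, region) == pytest.approx(40.0, abs=2.0)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            area_fraction(np.ones((4, 4, 4), bool), np.zeros((4, 4, 4), bool))

    def test_invariant_to_padding(self):
        region = np.zeros((10, 10, 10), bool)
        region[2:8, 2:8, 2:8] = True
        marker = np.zeros_like(region)
        marker[2:5, 2:8, 2:8] = True
        f1 = area_fraction(marker, region)
        f2 = area_fraction(np.pad(marker, 5), np.pad(region, 5))
        assert f1 == f2


class TestPositiveFraction:
    def _cells(self):
        return pd.DataFrame({
            "type": ["beta"] * 10 + ["mac"] * 5,
            "ki67_pos": [True] * 4 + [False] * 6 + [False] * 5,
            "beta_pos": [True] * 10 + [False] * 5,
        })

    def test_all_positive_gives_100(self):
        cells = pd.DataFrame({"type": ["beta"] * 5, "ki67_pos": [True] * 5})
        assert positive_fraction(cells, {"ki67_pos": True}, "beta") == 100.0

    def test_subset_fraction(self):
        assert positive_fraction(self._cells(), {"ki67_pos": True},
                                 {"beta_pos": True}) == pytest.approx(40.0)

    def test_zero_denominator_flagged_nan(self):
        cells = pd.DataFrame({"type": ["mac"], "ki67_pos": [True]})
        assert np.isnan(positive_fraction(cells, {"ki67_pos": True}, "beta"))

    def test_unknown_column_raises(self):
        with pytest.raises(KeyError):
            positive_fraction(self._cells(), {"nope": True}, "beta")


class TestCountsAndDensities:
    def test_count_per_volume_arithmetic(self):
        # 10 cells in 0.001 mm³ (=10⁶ μm³) → 10,000 per mm³
        cells = pd.DataFrame({"type": ["mac"] * 10})
        tissue = np.ones((100, 100, 100), bool)
        assert count_per_volume(cells, "mac", tissue, (1, 1, 1)) == pytest.approx(10000.0)

    def test_zero_cells(self):
        tissue = np.ones((10, 10, 10), bool)
        assert count_per_volume(pd.DataFrame({"type": []}), "mac", tissue, (1, 1, 1)) == 0.0

    def test_follicle_density_per_area_and_volume(self):
        mask = make_ball_mask((20, 30, 30), (1, 1, 1), (10, 10, 10), 3.0)
        mask |= make_ball_mask((20, 30, 30), (1, 1, 1), (10, 20, 20), 3.0)
        follicles = ComponentSet.from_mask(mask, (1, 1, 1))
        gland = np.ones((20, 30, 30), bool)
        per_mm3 = follicle_density(follicles, gland, (1, 1, 1), mode="volume")
        assert per_mm3 == pytest.approx(2 / (18000 / 1e9))
        per_mm2 = follicle_density(follicles, gland, (1, 1, 1), mode="area")
        assert per_mm2 == pytest.approx(2 / (18000 / 1e6))

    def test_empty_gland_rejected(self):
        follicles = ComponentSet.from_mask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        with pytest.raises(ValueError):
            follicle_density(follicles, np.zeros((4, 4, 4), bool), (1, 1, 1))


class TestExpressionBinning:
    EDGES = [10.0, 20.0, 30.0, 40.0]

    def test_zero_is_none(self):
        assert bin_expression(0.0, self.EDGES) == "none"

    def test_boundary_at_e3_is_high(self):
        assert bin_expression(30.0, self.EDGES) == "high"

    def test_above_e4_is_very_high(self):
        assert bin_expression(40.0, self.EDGES) == "very_high"
        assert bin_expression(1e6, self.EDGES) == "very_high"

    def test_non_ascending_edges_rejected(self):
        with pytest.raises(ValueError):
            bin_expression(5.0, [10, 10, 30, 40])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.floats(0, 100), st.floats(0, 100))
    def test_monotone_intensities_map_to_monotone_levels(self, a, b):
        from gland3d.stats import EXPRESSION_LEVELS

        lo, hi = sorted([a, b])
        levels = [EXPRESSION_LEVELS.index(bin_expression(v, self.EDGES)) for v in (lo, hi)]
        assert levels[0] <= levels[1]

    def test_heatmap_levels_ordered_with_intensity(self):
        df = pd.DataFrame({"cortex": [0.0, 50.0], "medulla": [25.0, 100.0]},
                          index=["VCAM1", "CD102"])
        levels = expression_heatmap(df, edges={"VCAM1": self.EDGES, "CD102": self.EDGES})
        assert levels.loc["VCAM1", "cortex"] == "none"
        assert levels.loc["CD102", "medulla"] == "very_high"


class TestCorrelation:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = correlate(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_null_simulation_keeps_r_small(self):
        rng = np.random.default_rng(123)
        hits = 0
        reps = 200
        for _ in range(reps):
            x, y = rng.normal(size=(2, 100))
            r, _ = correlate(x, y)
            hits += abs(r) < 0.25
        assert hits / reps >= 0.95

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 2], [3, 4])

    def test_zero_variance_flagged(self):
        r, p = correlate([1, 1, 1], [1, 2, 3])
        assert np.isnan(r) and np.isnan(p)


class TestGroupComparison:
    def test_identical_groups_give_t0_p1(self):
        gc = compare_groups({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert gc.test == "t-test"
        assert gc.statistic == 0.0
        assert gc.p_value == 1.0
        assert not gc.significant

    def test_t_matches_hand_computed_pooled_variance(self):
        a, b = [1, 2, 3, 4], [11, 12, 13, 14]
        gc = compare_groups({"a": a, "b": b})
        t_ref, p_ref = pooled_t_oracle(a, b)
        assert gc.statistic == pytest.approx(t_ref, abs=1e-10)
        assert gc.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_anova_and_tukey_match_closed_form(self):
        groups = {"g1": [5.1, 4.9, 5.3, 5.0], "g2": [5.2, 5.4, 5.1, 5.3],
                  "g3": [7.9, 8.1, 8.0, 8.3]}
        gc = compare_groups(groups)
        f_ref, p_ref = anova_f_oracle(list(groups.values()))
        assert gc.statistic == pytest.approx(f_ref, abs=1e-10)
        assert gc.p_value == pytest.approx(p_ref, abs=1e-10)
        p_tukey_ref = tukey_p_oracle(list(groups.values()))
        np.testing.assert_allclose(gc.tukey["p_adj"].to_numpy(), p_tukey_ref, atol=1e-8)

    def test_one_shifted_group_detected_only_in_its_pairs(self):
        rng = np.random.default_rng(7)
        groups = {"a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10),
                  "c": rng.normal(3, 1, 10)}   # shifted by 3 s.d.
        gc = compare_groups(groups)
        assert gc.p_value < 0.05
        tk = gc.tukey.set_index(["group1", "group2"])
        assert tk.loc[("a", "c"), "p_adj"] < 0.05
        assert tk.loc[("b", "c"), "p_adj"] < 0.05
        assert tk.loc[("a", "b"), "p_adj"] > 0.05

    def test_f_equals_t_squared_for_two_groups(self):
        a, b = [1.0, 2.5, 3.1, 4.0], [2.0, 3.6, 4.1, 5.5]
        gc = compare_groups({"a": a, "b": b})
        f_ref, p_ref = anova_f_oracle([a, b])
        assert gc.statistic**2 == pytest.approx(f_ref, abs=1e-10)
        assert gc.p_value == pytest.approx(p_ref, abs=1e-10)

    def test_group_with_single_value_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1], "b": [1, 2]})

    def test_means_and_sds_reported(self):
        gc = compare_groups({"a": [1.0, 3.0], "b": [2.0, 6.0]})
        assert gc.means["a"] == 2.0
        assert gc.sds["b"] == pytest.approx(np.std([2, 6], ddof=1))
        assert len(gc.summary()) == 2
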