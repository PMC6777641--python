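import io
import itertools
import math
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import amquant as aq
from oracles import group_compositions, kw_statistic

TABLE_GROUPS = {
    "Low": [88, 95, 87, 74, 95, 93, 80],
    "Medium": [79, 72, 52, 80, 53, 63, 62],
    "High": [21, 7, 5, 18, 7, 17, 2],
}


def pairs_frame(rows):
    return pd.DataFrame(rows, columns=["sample_1", "sample_2", "p_adj"])


class TestRankMidties:
    def test_distinct(self):
        assert aq.rank_midties([10, 20, 30]).tolist() == [1, 2, 3]

    def test_midranks(self):
        assert aq.rank_midties([5, 5, 9]).tolist() == [1.5, 1.5, 3]

    @given(st.lists(st.integers(0, 5), min_size=1, max_size=50))
    def test_rank_sum_identity(self, values):
        n = len(values)
        assert aq.rank_midties(values).sum() == pytest.approx(n * (n + 1) / 2)

    def test_rejects_empty_and_nonfinite(self):
        with pytest.raises(aq.InferenceError):
            aq.rank_midties([])
        with pytest.raises(aq.InferenceError):
            aq.rank_midties([1.0, float("nan")])


class TestKruskalWallis:
    def test_identical_distributions(self):
        result = aq.kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert result.H == pytest.approx(0.0, abs=1e-12)
        assert result.p == pytest.approx(1.0)

    def test_all_values_identical(self):
        result = aq.kruskal_wallis([[5, 5], [5, 5, 5]])
        assert result.H == 0.0 and result.p == 1.0

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(aq.InferenceError):
            aq.kruskal_wallis([[1, 2, 3]])

    def test_example_total_column(self):
        result = aq.kruskal_wallis(list(TABLE_GROUPS.values()))
        assert result.H == pytest.approx(
            kw_statistic(list(TABLE_GROUPS.values())), abs=1e-12)
        assert result.H > 15
        assert result.p < 0.001
        assert result.df == 2

    def test_matches_scipy(self):
        groups = list(TABLE_GROUPS.values())
        result = aq.kruskal_wallis(groups)
        scipy_result = sps.kruskal(*groups)
        assert result.H == pytest.approx(scipy_result.statistic, abs=1e-10)
        assert result.p == pytest.approx(scipy_result.pvalue, abs=1e-12)

    def test_oracle_equivalence_all_small_configs(self):
        """Brute-force oracle parity on every composition with N <= 8."""
        rng = random.Random(202)
        for total in range(3, 9):
            for sizes in group_compositions(total):
                # small value range forces frequent ties
                values = [rng.randint(0, 3) for _ in range(total)]
                groups, start = [], 0
                for n_i in sizes:
                    groups.append(values[start:start + n_i])
                    start += n_i
                result = aq.kruskal_wallis(groups)
                assert result.H == pytest.approx(kw_statistic(groups),
                                                abs=1e-12)

    def test_two_group_chi2_vs_exact_permutation_logged(self):
        """Chi-square approximation is compared with (not tightly asserted
        against) the exact permutation distribution for two groups of 3."""
        values = [1, 2, 3, 4, 5, 6]
        observed = aq.kruskal_wallis([values[:3], values[3:]])
        h_values = []
        for combo in itertools.combinations(range(6), 3):
            g1 = [values[i] for i in combo]
            g2 = [values[i] for i in range(6) if i not in combo]
            h_values.append(kw_statistic([g1, g2]))
        exact_p = sum(1 for h in h_values if h >= observed.H - 1e-12) \
            / len(h_values)
        assert len(h_values) == 20
        assert 0.0 < exact_p <= 1.0
        # documented tolerance of the chi-square approximation at tiny n
        assert abs(observed.p - exact_p) < 0.1

    @given(st.lists(st.lists(st.integers(0, 20), min_size=2, max_size=6),
                    min_size=2, max_size=4))
    def test_invariance_under_monotone_transform(self, groups):
        result = aq.kruskal_wallis(groups)
        transformed = [[math.exp(v / 5.0) + 3.0 for v in g] for g in groups]
        result2 = aq.kruskal_wallis(transformed)
        assert result2.H == pytest.approx(result.H, abs=1e-9)


class TestPairwiseLSD:
    def test_symmetry_and_two_group_consistency(self):
        a, b = [1, 4, 6], [2, 8, 9]
        lsd_ab = aq.pairwise_lsd_on_ranks([a, b], ["A", "B"])
        lsd_ba = aq.pairwise_lsd_on_ranks([b, a], ["B", "A"])
        assert lsd_ab.loc[0, "p"] == pytest.approx(lsd_ba.loc[0, "p"])

    def test_example_low_vs_high(self):
        lsd = aq.pairwise_lsd_on_ranks(list(TABLE_GROUPS.values()),
                                       list(TABLE_GROUPS))
        row = lsd[(lsd["sample_1"] == "Low") & (lsd["sample_2"] == "High")]
        assert float(row["p"].iloc[0]) < 0.01
        # pair ordering follows group order
        assert lsd[["sample_1", "sample_2"]].values.tolist() == [
            ["Low", "Medium"], ["Low", "High"], ["Medium", "High"]]

    def test_oracle_formula(self):
        """Recompute the LSD t statistic from scratch for one pair."""
        groups = list(TABLE_GROUPS.values())
        N, k = 21, 3
        pooled = [v for g in groups for v in g]
        ranks = sps.rankdata(pooled)
        mean_low = ranks[:7].mean()
        mean_high = ranks[14:].mean()
        H = sps.kruskal(*groups).statistic
        S2 = ranks.var(ddof=1)
        se = math.sqrt(S2 * (N - 1 - H) / (N - k) * (2 / 7))
        expected = 2 * sps.t.sf(abs(mean_low - mean_high) / se, N - k)
        lsd = aq.pairwise_lsd_on_ranks(groups, list(TABLE_GROUPS))
        row = lsd[(lsd["sample_1"] == "Low") & (lsd["sample_2"] == "High")]
        assert float(row["p"].iloc[0]) == pytest.approx(expected, abs=1e-12)

    def test_identical_values_give_p_one(self):
        lsd = aq.pairwise_lsd_on_ranks([[5, 5], [5, 5], [5, 5]])
        assert (lsd["p"] == 1.0).all()

    def test_no_residual_df_rejected(self):
        with pytest.raises(aq.InferenceError):
            aq.pairwise_lsd_on_ranks([[1], [2], [3]])


class TestAdjustPvalues:
    def test_bonferroni(self):
        out = aq.adjust_pvalues([0.01, 0.02, 0.03], "bonferroni")
        assert out.tolist() == pytest.approx([0.03, 0.06, 0.09])

    def test_bonferroni_clips_at_one(self):
        assert aq.adjust_pvalues([0.5, 0.6], "bonferroni").max() == 1.0

    def test_bh_step_up(self):
        out = aq.adjust_pvalues([0.01, 0.02, 0.03], "BH")
        assert out.tolist() == pytest.approx([0.03, 0.03, 0.03])

    def test_none_identity(self):
        p = [0.2, 0.01, 0.7]
        assert aq.adjust_pvalues(p, "none").tolist() == p

    def test_fdr_is_bh_alias(self):
        p = np.linspace(0.001, 0.9, 11)
        assert np.allclose(aq.adjust_pvalues(p, "fdr"),
                           aq.adjust_pvalues(p, "BH"))

    def test_unknown_method_lists_valid_names(self):
        with pytest.raises(aq.InferenceError, match="holm"):
            aq.adjust_pvalues([0.5], "banana")

    def test_out_of_range_p_rejected(self):
        with pytest.raises(aq.InferenceError):
            aq.adjust_pvalues([1.5], "holm")

    def test_order_preserved(self):
        p = [0.04, 0.001, 0.2]
        out = aq.adjust_pvalues(p, "holm")
        assert out[1] < out[0] < out[2]

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1,
                    max_size=12))
    def test_dominance_properties(self, p):
        raw = np.asarray(p)
        holm = aq.adjust_pvalues(raw, "holm")
        bonf = aq.adjust_pvalues(raw, "bonferroni")
        hoch = aq.adjust_pvalues(raw, "hochberg")
        assert np.all(holm >= raw - 1e-12)
        assert np.all(bonf >= holm - 1e-12)
        assert np.all(holm >= hoch - 1e-12)
        for method in aq.ADJUST_METHODS:
            if method == "none":
                continue
            adj = aq.adjust_pvalues(raw, method)
            assert np.all(adj >= raw - 1e-12)
            assert np.all((adj >= 0) & (adj <= 1))


class TestPairwiseTests:
    def test_example_shape(self, grid_ds):
        cmp = aq.pairwise_tests(grid_ds)
        wide = cmp.wide()
        assert len(wide) == 3
        assert list(wide.columns) == ["sample_1", "sample_2",
                                      *aq.GRID_VARIABLES]

    def test_adjusted_dominates_raw(self, grid_ds):
        cmp = aq.pairwise_tests(grid_ds, "fdr")
        assert (cmp.data["p_adj"] >= cmp.data["p_raw"] - 1e-12).all()

    def test_trouvelot_six_pairs(self, trouvelot_ds):
        cmp = aq.pairwise_tests(trouvelot_ds, "fdr")
        assert len(cmp.wide()) == 6  # C(4, 2)
        assert cmp.variables == list(aq.TROUVELOT_VARIABLES)

    def test_single_sample_rejected(self):
        ds = aq.read_colonization_table(
            io.StringIO("Samples,Replicates,Total\nX,1,50\nX,2,60\n"), "grid")
        with pytest.raises(aq.InferenceError):
            aq.pairwise_tests(ds)

    def test_per_variable_independence(self, grid_csv_text):
        """Permuting the Vesicle column never changes Total's p-values."""
        lines = grid_csv_text.strip().split("\n")
        rows = [line.split(",") for line in lines[1:]]
        vesicle = [r[-1] for r in rows]
        random.Random(5).shuffle(vesicle)
        for r, v in zip(rows, vesicle):
            r[-1] = v
        permuted = "\n".join([lines[0]] + [",".join(r) for r in rows]) + "\n"
        ds1 = aq.read_colonization_table(io.StringIO(grid_csv_text), "grid")
        ds2 = aq.read_colonization_table(io.StringIO(permuted), "grid")
        t1 = aq.pairwise_tests(ds1, "BH").variable_rows("Total")
        t2 = aq.pairwise_tests(ds2, "BH").variable_rows("Total")
        assert t1["p_adj"].tolist() == t2["p_adj"].tolist()


class TestCompactLetterDisplay:
    def test_forced_three_groups(self):
        rows = pairs_frame([("A", "B", 0.001), ("A", "C", 0.001),
                            ("B", "C", 0.8)])
        letters = aq.compact_letter_display(rows, 0.05, ["A", "B", "C"])
        assert letters == {"A": "a", "B": "b", "C": "b"}

    def test_all_similar_single_letter(self):
        rows = pairs_frame([("A", "B", 1.0), ("A", "C", 1.0), ("B", "C", 1.0)])
        letters = aq.compact_letter_display(rows, 0.05, ["A", "B", "C"])
        assert letters == {"A": "a", "B": "a", "C": "a"}

    def test_all_different_distinct_letters(self):
        rows = pairs_frame([("A", "B", 0.0), ("A", "C", 0.0), ("B", "C", 0.0)])
        letters = aq.compact_letter_display(rows, 0.05, ["A", "B", "C"])
        assert letters == {"A": "a", "B": "b", "C": "c"}

    def test_incomplete_coverage_rejected(self):
        rows = pairs_frame([("A", "B", 0.5)])
        with pytest.raises(aq.InferenceError):
            aq.compact_letter_display(rows, 0.05, ["A", "B", "C"])

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_exhaustive_soundness_and_completeness(self, k):
        samples = [f"S{i}" for i in range(k)]
        pairs = list(itertools.combinations(samples, 2))
        for pattern in itertools.product([True, False], repeat=len(pairs)):
            rows = pairs_frame([
                (a, b, 0.001 if sig else 0.8)
                for (a, b), sig in zip(pairs, pattern)])
            letters = aq.compact_letter_display(rows, 0.05, samples)
            assert all(letters[s] for s in samples)
            for (a, b), sig in zip(pairs, pattern):
                shared = set(letters[a]) & set(letters[b])
                assert bool(shared) == (not sig), (pattern, letters)


class TestAsterisks:
    def test_between_alpha_tiers_unmarked(self):
        rows = pairs_frame([("ctrl", "X", 0.03)])
        assert aq.asterisks_vs_control(rows, "ctrl", alpha=0.01)["X"] == ""

    def test_below_alpha_marked(self):
        rows = pairs_frame([("ctrl", "X", 0.005)])
        assert aq.asterisks_vs_control(rows, "ctrl", alpha=0.01)["X"] == "*"

    def test_control_never_marked(self):
        rows = pairs_frame([("ctrl", "X", 0.0001), ("ctrl", "Y", 0.9),
                            ("X", "Y", 0.0001)])
        marks = aq.asterisks_vs_control(rows, "ctrl")
        assert marks["ctrl"] == ""
        assert marks == {"ctrl": "", "X": "*", "Y": ""}

    def test_missing_control_rejected(self):
        rows = pairs_frame([("A", "B", 0.5)])
        with pytest.raises(aq.InferenceError):
            aq.asterisks_vs_control(rows, "ctrl")

    def test_default_alpha(self):
        rows = pairs_frame([("ctrl", "X", 0.04)])
        assert aq.asterisks_vs_control(rows, "ctrl")["X"] == "*"


class TestOneWay:
    def test_omnibus_attached_and_significant(self, grid_ds):
        result = aq.oneway_tests(grid_ds)
        assert result.omnibus["Total"].p < 0.001

    def test_identical_values_p_one(self):
        ds = aq.read_colonization_table(io.StringIO(
            "Samples,Replicates,Total\nX,1,50\nX,2,50\nY,1,50\nY,2,50\n"),
            "grid")
        result = aq.oneway_tests(ds)
        assert result.omnibus["Total"].p == 1.0
        assert (result.data["p_adj"] == 1.0).all()

    def test_alias_of_pairwise_tests(self, grid_ds):
        a = aq.oneway_tests(grid_ds, "BH")
        b = aq.pairwise_tests(grid_ds, "BH")
        pd.testing.assert_frame_equal(a.data, b.data)


class TestTwoWayAnova:
    @staticmethod
    def _balanced(noise_fn=lambda s, t, r: 0.0):
        rows = ["Samples,Replicates,Total,trt"]
        for s, s_eff in (("S1", -5.0), ("S2", 5.0)):
            for t, t_eff in (("sand", -2.0), ("clay", 2.0)):
                for r in (1, 2):
                    value = 50.0 + s_eff + t_eff + noise_fn(s, t, r)
                    rows.append(f"{s},R{r},{value},{t}")
        return aq.read_colonization_table(io.StringIO("\n".join(rows) + "\n"),
                                          "grid")

    def test_known_additive_effects_sum_of_squares(self):
        table = aq.twoway_anova(self._balanced())["Total"].table
        # 8 observations, effects +-5 and +-2, no interaction, no noise
        assert table.loc["Samples", "sum_sq"] == pytest.approx(200.0, abs=1e-8)
        assert table.loc["trt", "sum_sq"] == pytest.approx(32.0, abs=1e-8)
        assert table.loc["Samples:trt", "sum_sq"] == pytest.approx(0, abs=1e-8)
        assert table.loc["Residual", "sum_sq"] == pytest.approx(0.0, abs=1e-8)

    def test_df_sum_is_n_minus_one(self):
        ds = self._balanced(lambda s, t, r: {1: 0.5, 2: -0.5}[r])
        table = aq.twoway_anova(ds)["Total"].table
        assert table["df"].sum() == pytest.approx(8 - 1)
        assert table.loc["Residual", "sum_sq"] >= 0

    def test_identical_cells_zero_residual(self):
        result = aq.twoway_anova(self._balanced())["Total"]
        assert result.table.loc["Residual", "sum_sq"] == \
            pytest.approx(0.0, abs=1e-8)

    def test_qq_diagnostics_contract(self):
        ds = self._balanced(lambda s, t, r: {1: 0.5, 2: -0.5}[r])
        result = aq.twoway_anova(ds)["Total"]
        assert len(result.qq_sample) == 8
        assert len(result.fitted) == len(result.residuals) == 8
        assert np.all(np.diff(result.qq_sample) >= 0)

    def test_missing_trt_is_schema_error(self, grid_ds):
        with pytest.raises(aq.SchemaError, match="trt"):
            aq.twoway_anova(grid_ds)

    def test_single_level_factor_rejected(self):
        ds = aq.read_colonization_table(io.StringIO(
            "Samples,Replicates,Total,trt\nX,1,50,a\nX,2,60,a\n"
            "Y,1,40,a\nY,2,30,a\n"), "grid")
        with pytest.raises(aq.InferenceError):
            aq.twoway_anova(ds)
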