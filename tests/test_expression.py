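"""Normalization, log2 fold changes, the derepression statistic, profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dcquant
from dcquant.expression import (
    chromosome_profile,
    derepression,
    fold_change_equivalent,
    log2_fold_changes,
    round_sig,
    size_factors,
    validate_dge,
    wilcoxon_rank_sum,
)


def make_table(x_vals, a_vals):
    n = len(x_vals) + len(a_vals)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "chrom": ["X"] * len(x_vals) + ["I"] * len(a_vals),
            "log2fc": list(x_vals) + list(a_vals),
        }
    )


class TestSizeFactors:
    def test_doubled_library_detected(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 1000, size=200)
        counts = pd.DataFrame({"s1": base, "s2": 2 * base})
        f = size_factors(counts)
        assert f["s2"] / f["s1"] == pytest.approx(2.0)

    def test_identical_samples_get_equal_factors(self):
        counts = pd.DataFrame({"a": [5, 10, 20], "b": [5, 10, 20], "c": [5, 10, 20]})
        f = size_factors(counts)
        assert np.allclose(f, f.iloc[0])

    def test_matches_hand_computed_median_of_ratios(self):
        counts = pd.DataFrame({"s1": [10, 20, 40, 0, 100], "s2": [20, 10, 80, 5, 100]})
        # rows with a zero are dropped; ratios per remaining gene g:
        # geo-means: sqrt(10*20), sqrt(20*10), sqrt(40*80), sqrt(100*100)
        geo = np.sqrt(np.array([200, 200, 3200, 10000]))
        expected1 = np.median(np.array([10, 20, 40, 100]) / geo)
        expected2 = np.median(np.array([20, 10, 80, 100]) / geo)
        f = size_factors(counts)
        assert f["s1"] == pytest.approx(expected1)
        assert f["s2"] == pytest.approx(expected2)

    def test_all_zero_rows_rejected(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [3, 0]})
        with pytest.raises(ValueError, match="positive"):
            size_factors(counts)


class TestLog2FoldChanges:
    def test_identical_groups_give_zero(self):
        rng = np.random.default_rng(1)
        base = rng.integers(5, 500, size=50)
        counts = pd.DataFrame({f"ctrl_{i}": base for i in (1, 2)} | {f"trt_{i}": base for i in (1, 2)})
        groups = {c: ("control" if c.startswith("ctrl") else "treatment") for c in counts.columns}
        tab = log2_fold_changes(counts, groups)
        assert np.allclose(tab["log2fc"], 0.0)

    def test_fourfold_gene_near_two(self):
        counts = pd.DataFrame(
            {
                "ctrl_1": [1000, 500, 800],
                "ctrl_2": [1000, 500, 800],
                "trt_1": [4000, 500, 800],
                "trt_2": [4000, 500, 800],
            }
        )
        groups = {"ctrl_1": "control", "ctrl_2": "control", "trt_1": "treatment", "trt_2": "treatment"}
        tab = log2_fold_changes(counts, groups, factors=pd.Series(1.0, index=counts.columns))
        assert tab["log2fc"].iloc[0] == pytest.approx(2.0, abs=0.01)  # pseudocount-limited
        assert tab["log2fc"].iloc[1] == pytest.approx(0.0, abs=1e-12)

    def test_recovers_simulated_shift(self):
        params = dcquant.CountSimParams(d_true=0.78, seed=12)
        counts, genes, truth = dcquant.generate_count_matrix(params)
        tab = log2_fold_changes(counts, truth["groups"], gene_info=genes)
        res = derepression(tab)
        assert res.d == pytest.approx(0.78, abs=0.05)

    def test_group_label_mismatch_rejected(self):
        counts = pd.DataFrame({"a": [1], "b": [2]})
        with pytest.raises(ValueError, match="groups"):
            log2_fold_changes(counts, {"a": "control", "zz": "treatment"})


class TestWilcoxon:
    def test_separated_samples_exact_p(self):
        # all 3 x-ranks below all 3 y-ranks: 2 of the C(6,3)=20 assignments
        # are at least as extreme two-sided
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        w, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_normal_approximation_tracks_exact_enumeration(self, seed):
        # independent oracle: exhaustive rank-assignment enumeration at 5 vs 5
        from itertools import combinations

        rng = np.random.default_rng(seed)
        x = rng.normal(0.6, 1, 5)
        y = rng.normal(0, 1, 5)
        pooled = np.concatenate([x, y])
        ranks = pooled.argsort().argsort() + 1
        w_obs = ranks[:5].sum()
        n = 10
        ws = [sum(c) for c in combinations(range(1, n + 1), 5)]
        mean_w = 5 * (n + 1) / 2
        tail = sum(1 for w in ws if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9)
        p_exact = tail / len(ws)
        _, p_approx = wilcoxon_rank_sum(x, y, method="asymptotic")
        assert p_approx == pytest.approx(p_exact, abs=0.02)


class TestDerepression:
    def test_uniform_shift_recovered(self):
        res = derepression(make_table([0.5, 0.5, 0.5], [0.0, 0.0, 0.0]))
        assert res.d == pytest.approx(0.5)
        assert res.fold == pytest.approx(2**0.5, rel=1e-12)
        assert (res.n_x, res.n_a) == (3, 3)
        assert res.d == pytest.approx(res.median_x - res.median_a, abs=1e-12)

    def test_identical_distributions_null(self):
        vals = [0.1, -0.2, 0.3, 0.0]
        res = derepression(make_table(vals, vals))
        assert res.d == 0.0
        assert res.fold == 1.0
        assert res.p_value == pytest.approx(1.0)

    def test_additive_shift_invariance_of_d(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.4, 0.3, 41)
        a = rng.normal(0.0, 0.3, 100)
        base = derepression(make_table(x, a))
        shifted = derepression(make_table(x + 1.7, a + 1.7))
        assert shifted.d == pytest.approx(base.d, abs=1e-12)

    def test_unplaced_chromosomes_dropped_not_fatal(self):
        tab = make_table([0.5], [0.0, 0.1])
        tab.loc[len(tab)] = ["gmt", "MtDNA", 9.9]
        res = derepression(tab)
        assert res.n_x + res.n_a == 3

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError, match="X-linked"):
            derepression(make_table([], [0.1]))


class TestFoldEquivalents:
    @pytest.mark.parametrize(
        "d,printed,digits",
        [(0.503, 1.4, 1), (0.435, 1.35, 2), (0.78, 1.72, 2), (0.612, 1.53, 2), (0.721, 1.65, 2)],
    )
    def test_reported_fold_conversions(self, d, printed, digits):
        assert round(fold_change_equivalent(d), digits) == printed

    def test_identity_points(self):
        assert fold_change_equivalent(0.0) == 1.0
        assert fold_change_equivalent(1.0) == 2.0

    @given(st.floats(min_value=1e-6, max_value=1e6, allow_nan=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_with_log2(self, v):
        assert fold_change_equivalent(np.log2(v)) == pytest.approx(v, rel=1e-12)

    def test_three_significant_figure_reporting(self):
        assert round_sig(fold_change_equivalent(0.435), 3) == 1.35
        assert round_sig(1.7169, 3) == 1.72


class TestChromosomeProfile:
    def lengths(self):
        return {"I": 2_000_000, "X": 1_000_000}

    def test_all_filtered_leaves_empty_bins(self):
        tab = make_table([0.5], [0.1])
        tab["start"] = [10, 20]
        tab["pvalue"] = [0.9, 0.8]
        prof = chromosome_profile(tab, lengths=self.lengths(), bin_size=1_000_000)
        assert prof["n_genes"].sum() == 0
        assert prof["mean_log2fc"].isna().all()

    def test_single_gene_owns_its_bin(self):
        tab = make_table([], [0.7])
        tab["start"] = [1]
        prof = chromosome_profile(tab, lengths=self.lengths(), bin_size=1_000_000, p_max=None)
        row = prof[(prof.chrom == "I") & (prof.bin_start == 1)].iloc[0]
        assert row.mean_log2fc == pytest.approx(0.7)
        assert row.n_genes == 1

    def test_bins_tile_chromosomes(self):
        tab = make_table([0.2], [0.1])
        tab["start"] = [5, 5]
        prof = chromosome_profile(tab, lengths=self.lengths(), bin_size=300_000, p_max=None)
        for chrom, length in self.lengths().items():
            sub = prof[prof.chrom == chrom]
            assert sub["bin_start"].iloc[0] == 1
            assert sub["bin_end"].iloc[-1] == length
            assert (sub["bin_start"].iloc[1:].to_numpy() == sub["bin_end"].iloc[:-1].to_numpy() + 1).all()

    def test_uniform_x_shift_shows_in_x_bins_only(self):
        params = dcquant.CountSimParams(d_true=0.5, seed=21)
        counts, genes, truth = dcquant.generate_count_matrix(params)
        tab = log2_fold_changes(counts, truth["groups"], gene_info=genes)
        prof = chromosome_profile(tab, bin_size=2_000_000, p_max=None)
        filled = prof[prof.n_genes >= 30]
        x_bins = filled[filled.chrom == "X"]["mean_log2fc"]
        a_bins = filled[filled.chrom != "X"]["mean_log2fc"]
        assert np.all(np.abs(x_bins - 0.5) < 0.1)
        assert np.all(np.abs(a_bins) < 0.1)

    def test_gene_beyond_length_rejected(self):
        tab = make_table([], [0.1])
        tab["start"] = [3_000_000]
        with pytest.raises(ValueError, match="beyond"):
            chromosome_profile(tab, lengths=self.lengths(), p_max=None)


def test_validate_dge_rejects_bad_tables():
    tab = make_table([0.1], [0.2])
    dup = pd.concat([tab, tab.iloc[[0]]])
    with pytest.raises(ValueError, match="unique"):
        validate_dge(dup)
    bad = make_table([np.inf], [0.2])
    with pytest.raises(ValueError, match="finite"):
        validate_dge(bad)
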