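"""Permutation framework, expression bins, evaluators, metaplots."""

import numpy as np
import pandas as pd
import pytest

from rddmscan.permutation import (
    MethylationIndex,
    assign_expression_bins,
    flank_methylation_profile,
    mean_distance_evaluator,
    mean_methylation_evaluator,
    permutation_test,
)
from rddmscan.tecontext import filter_te_annotation, nearest_te_distance

from conftest import make_gene, make_te


def de_table(log2fc, fdr=None, start=0):
    n = len(log2fc)
    return pd.DataFrame(
        {
            "gene_id": [f"g{start + i}" for i in range(n)],
            "log2fc": log2fc,
            "fdr": fdr if fdr is not None else [0.01] * n,
        }
    )


class TestExpressionBins:
    def test_quartile_binning_of_worked_sequence(self):
        # magnitudes 1..8 (after the |log2FC|>1 filter would keep >1; use
        # values 1.1..8.1 shifted to keep all eight)
        values = [v + 0.1 for v in range(1, 9)]
        # quartiles of {1.1 .. 8.1}: Q1 = 2.85, Q3 = 6.35 (linear interp.)
        table = de_table(values)
        bins = {a.gene_id: a.bin for a in assign_expression_bins(table)}
        mags = np.array(values)
        q1, q3 = np.quantile(mags, [0.25, 0.75])
        assert q1 == pytest.approx(2.85) and q3 == pytest.approx(6.35)
        assert bins["g7"] == 3  # 8.1 > Q3
        assert bins["g0"] == 1  # 1.1 < Q1
        assert bins["g3"] == 2  # 4.1 inside IQR

    def test_de_filter_excludes_weak_fold_changes(self):
        table = de_table([0.5, 2.0, 3.0, 4.0, 5.0])
        bins = assign_expression_bins(table)
        assert "g0" not in {a.gene_id for a in bins}

    def test_fdr_filter(self):
        table = de_table([2.0, 3.0, 4.0, 5.0, 6.0], fdr=[0.5, 0.01, 0.01, 0.01, 0.01])
        bins = assign_expression_bins(table)
        assert "g0" not in {a.gene_id for a in bins}

    def test_degenerate_equal_values_all_bin_two(self):
        table = de_table([2.0, 2.0, 2.0, 2.0])
        assert {a.bin for a in assign_expression_bins(table)} == {2}

    def test_down_direction_negative_bins(self):
        table = de_table([-1.5, -2.5, -3.5, -4.5, -5.5, -6.5, -7.5, -8.5])
        bins = {a.gene_id: a.bin for a in assign_expression_bins(table)}
        assert bins["g7"] == -3  # strongest down-regulation
        assert bins["g0"] == -1

    def test_too_few_genes_errors(self):
        with pytest.raises(ValueError, match="quartiles undefined"):
            assign_expression_bins(de_table([2.0, 3.0, 4.0]))


class TestPermutationTest:
    def test_regions_equal_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        values = {g: float(i) for i, g in enumerate(universe)}
        ev = lambda ids: float(np.mean([values[g] for g in ids]))
        res = permutation_test(universe, universe, ev, n_perm=30, seed=0)
        assert res.p == 1.0
        assert set(res.null_values) == {res.observed}

    def test_constant_evaluator_degenerate_null(self):
        universe = [f"g{i}" for i in range(10)]
        res = permutation_test(universe[:3], universe, lambda ids: 1.0,
                               n_perm=20, seed=0)
        assert res.z is None and res.p == 1.0

    def test_alternative_follows_deviation_direction(self):
        universe = [f"g{i}" for i in range(100)]
        values = {g: float(i) for i, g in enumerate(universe)}
        ev = lambda ids: float(np.mean([values[g] for g in ids]))
        res_low = permutation_test(universe[:10], universe, ev, n_perm=99, seed=1)
        assert res_low.alternative == "less"
        assert res_low.p == pytest.approx(1 / 100)

    def test_regions_not_subset_errors(self):
        with pytest.raises(ValueError):
            permutation_test(["x"], ["a", "b"], lambda ids: 0.0)

    def test_add_one_correction_floor(self):
        universe = [f"g{i}" for i in range(50)]
        values = {g: float(i) for i, g in enumerate(universe)}
        ev = lambda ids: float(np.mean([values[g] for g in ids]))
        res = permutation_test(universe[:5], universe, ev, n_perm=200, seed=2)
        assert res.p >= 1 / 201

    def test_p_uniform_under_null(self):
        # query sets drawn from the null generator: p <= 0.05 near 5%
        rng = np.random.default_rng(77)
        universe = [f"g{i}" for i in range(200)]
        values = {g: float(v) for g, v in zip(universe, rng.normal(size=200))}
        ev = lambda ids: float(np.mean([values[g] for g in ids]))
        low = 0
        n_rep = 300
        for i in range(n_rep):
            regions = list(rng.choice(universe, size=30, replace=False))
            res = permutation_test(regions, universe, ev, n_perm=99,
                                   seed=10_000 + i, alternative="greater")
            if res.p <= 0.05:
                low += 1
        from scipy import stats
        lo, hi = stats.binom.interval(0.99, n_rep, 0.05)
        assert lo <= low <= hi

    def test_auto_direction_inflates_null_rate(self):
        # choosing the alternative from the data roughly doubles the
        # one-sided false-positive rate; the explicit-direction mode is
        # the calibrated one
        rng = np.random.default_rng(88)
        universe = [f"g{i}" for i in range(200)]
        values = {g: float(v) for g, v in zip(universe, rng.normal(size=200))}
        ev = lambda ids: float(np.mean([values[g] for g in ids]))
        low = 0
        n_rep = 200
        for i in range(n_rep):
            regions = list(rng.choice(universe, size=30, replace=False))
            res = permutation_test(regions, universe, ev, n_perm=99,
                                   seed=40_000 + i)
            if res.p <= 0.05:
                low += 1
        assert 0.04 < low / n_rep < 0.18

    def test_te_adjacent_genes_detected_closer(self, small_dataset):
        # genes flagged as TSS-proximal to TEs should sit closer to TEs
        # than random same-size gene sets
        ds = small_dataset
        tes = filter_te_annotation(ds.tes)
        ev = mean_distance_evaluator(ds.genes, tes)
        universe = [g.gene_id for g in ds.genes]
        flagged = ds.truth["te_tss500_genes"]
        res = permutation_test(flagged, universe, ev, n_perm=200, seed=9)
        assert res.alternative == "less"
        assert res.p <= 0.005


class TestEvaluators:
    def test_mean_distance_simple(self):
        genes = [
            make_gene("a", "chr1", 0, 100, "+"),
            make_gene("b", "chr1", 1_000, 1_100, "+"),
        ]
        tes = [make_te("chr1", 200, 300, superfamily="RLG")]
        # te shorter than 1 kb would be filtered; evaluate unfiltered here
        ev = mean_distance_evaluator(genes, tes)
        # distances: a: 100, b: 700
        assert ev(["a", "b"]) == pytest.approx(400.0)

    def test_mean_distance_excludes_unmeasurable(self):
        genes = [
            make_gene("a", "chr1", 0, 100, "+"),
            make_gene("b", "chr2", 0, 100, "+"),
        ]
        tes = [make_te("chr1", 200, 300)]
        ev = mean_distance_evaluator(genes, tes)
        assert ev(["a", "b"]) == pytest.approx(100.0)
        with pytest.raises(ValueError):
            ev(["b"])

    def test_mean_distance_matches_brute_force(self, rng):
        genes = [
            make_gene(f"g{i}", "chr1", int(s), int(s) + 100, "+")
            for i, s in enumerate(rng.integers(0, 50_000, size=50))
        ]
        tes = [
            make_te("chr1", int(s), int(s) + 200)
            for s in rng.integers(0, 50_000, size=40)
        ]
        ev = mean_distance_evaluator(genes, tes)
        d = nearest_te_distance(genes, tes)
        ids = [g.gene_id for g in genes]
        assert ev(ids) == pytest.approx(np.mean([d[g] for g in ids]))

    def test_constant_track_mean(self):
        genes = [make_gene("a", "chr1", 5_000, 6_000, "+")]
        track = pd.DataFrame(
            {"chrom": ["chr1"] * 100, "pos": np.arange(3_000, 8_000, 50),
             "level": [0.8] * 100}
        )
        ev = mean_methylation_evaluator(genes, track, flank=1_000, side="both")
        assert ev(["a"]) == pytest.approx(0.8)

    def test_uncovered_gene_excluded(self):
        genes = [
            make_gene("a", "chr1", 5_000, 6_000, "+"),
            make_gene("b", "chr2", 5_000, 6_000, "+"),
        ]
        track = pd.DataFrame(
            {"chrom": ["chr1"] * 10, "pos": np.arange(4_000, 5_000, 100),
             "level": [0.5] * 10}
        )
        ev = mean_methylation_evaluator(genes, track, flank=1_000)
        assert ev(["a", "b"]) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            ev(["b"])

    def test_mean_methylation_matches_brute_force(self, rng):
        genes = [
            make_gene(f"g{i}", "chr1", int(s), int(s) + 500,
                      "+" if i % 2 else "-")
            for i, s in enumerate(rng.integers(3_000, 40_000, size=20))
        ]
        pos = np.sort(rng.choice(50_000, size=2_000, replace=False))
        levels = rng.random(2_000)
        track = pd.DataFrame({"chrom": "chr1", "pos": pos, "level": levels})
        ev = mean_methylation_evaluator(genes, track, flank=1_000, side="upstream")
        per_gene = []
        for g in genes:
            if g.strand == "+":
                lo, hi = g.interval.start - 1_000, g.interval.start
            else:
                lo, hi = g.interval.end, g.interval.end + 1_000
            sel = (pos >= lo) & (pos < hi)
            if sel.any():
                per_gene.append(levels[sel].mean())
        ids = [g.gene_id for g in genes]
        assert ev(ids) == pytest.approx(np.mean(per_gene))


class TestFlankProfile:
    def test_constant_track_flat_curve(self):
        genes = [make_gene("a", "chr1", 10_000, 12_000, "+")]
        track = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(7_000, 15_000, 10),
             "level": 0.5}
        )
        prof = flank_methylation_profile(genes, track, flank=2_000, window=100)
        assert np.allclose(prof.mean_level, 0.5)

    def test_island_localized_to_expected_windows(self, small_dataset):
        ds = small_dataset
        island_genes = [
            g for g in ds.genes if g.gene_id in set(ds.truth["chh_island_genes"])
        ]
        prof = flank_methylation_profile(
            island_genes, ds.methylation["CHH"], flank=1_000, window=100
        )
        prof = prof.set_index("window")
        # island injected at TSS offsets -600..-400: windows -6 and -5
        peak = prof.loc[[-6, -5], "mean_level"].mean()
        background = prof.loc[[-10, -9, 3, 4], "mean_level"].mean()
        assert peak > 0.25
        assert background < 0.12

    def test_strand_reflection_leaves_curve_unchanged(self, rng):
        L = 60_000
        genes = [
            make_gene(f"g{i}", "chr1", int(s), int(s) + 1_000,
                      "+" if i % 2 else "-")
            for i, s in enumerate(rng.integers(5_000, 50_000, size=10))
        ]
        pos = np.sort(rng.choice(L, size=3_000, replace=False))
        levels = rng.random(3_000)
        track = pd.DataFrame({"chrom": "chr1", "pos": pos, "level": levels})
        flip = {"+": "-", "-": "+"}
        genes_m = [
            make_gene(g.gene_id, "chr1", L - g.interval.end, L - g.interval.start,
                      flip[g.strand])
            for g in genes
        ]
        track_m = pd.DataFrame(
            {"chrom": "chr1", "pos": L - 1 - pos, "level": levels}
        )
        a = flank_methylation_profile(genes, track, flank=1_000, window=100)
        b = flank_methylation_profile(genes_m, track_m, flank=1_000, window=100)
        assert np.allclose(a.mean_level, b.mean_level, equal_nan=True)

    def test_flank_not_divisible_errors(self):
        with pytest.raises(ValueError):
            flank_methylation_profile([], pd.DataFrame(columns=["chrom", "pos", "level"]),
                                      flank=1_050, window=100)


def test_methylation_index_range_query(rng):
    pos = np.sort(rng.choice(10_000, size=500, replace=False))
    levels = rng.random(500)
    idx = MethylationIndex(pd.DataFrame({"chrom": "chr1", "pos": pos, "level": levels}))
    lo, hi = 2_000, 4_000
    expected = levels[(pos >= lo) & (pos < hi)]
    assert np.allclose(np.sort(idx.range_levels("chr1", lo, hi)), np.sort(expected))
    assert idx.range_levels("chrX", 0, 100).size == 0
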