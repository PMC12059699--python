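"""Promoter-target genomics: RPKM, fold changes, intervals, KS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neurotoxiscore.genomics import (
    ExpressionTable,
    GeneAnnotation,
    KSResult,
    PeakSet,
    compute_rpkm,
    ecdf,
    expressed_universe,
    gene_panel_overlap,
    genes_with_peak,
    group_fold_changes,
    ks_null_calibration,
    ks_two_sample,
    shuffled_background,
    target_vs_background_analysis,
    upstream_windows,
)
from neurotoxiscore.synthetic import (
    ExpressionSimSpec,
    PeakSimSpec,
    make_expression_dataset,
    make_peaks,
)


def small_table():
    genes = ["g1", "g2", "g3"]
    counts = pd.DataFrame(
        {"A_DMSO": [10, 0, 100], "A_rx": [20, 5, 100],
         "B_DMSO": [10, 2, 50], "B_rx": [30, 2, 50]},
        index=pd.Index(genes, name="gene_id"))
    meta = pd.DataFrame({
        "sample_id": ["A_DMSO", "A_rx", "B_DMSO", "B_rx"],
        "individual": ["A", "A", "B", "B"],
        "group": ["Ctrl", "Ctrl", "Ctrl", "Ctrl"],
        "treatment": ["DMSO", "rx", "DMSO", "rx"],
    })
    lengths = pd.Series([1000.0, 2000.0, 500.0], index=genes)
    return ExpressionTable(counts, meta, lengths)


class TestRpkm:
    def test_unit_case(self):
        genes = ["g1"]
        counts = pd.DataFrame({"s1": [10]}, index=pd.Index(genes, name="gene_id"))
        # library size must be 1e6 for the unit case: pad with a second gene
        counts.loc["g2"] = [10 ** 6 - 10]
        meta = pd.DataFrame({"sample_id": ["s1", "s2"],
                             "individual": ["A", "A"],
                             "group": ["Ctrl", "Ctrl"],
                             "treatment": ["DMSO", "rx"]})
        counts["s2"] = [1, 10 ** 6 - 1]
        lengths = pd.Series([1000.0, 1000.0], index=["g1", "g2"])
        table = ExpressionTable(counts, meta, lengths)
        assert compute_rpkm(table).loc["g1", "s1"] == pytest.approx(10.0)

    def test_zero_count_gives_zero(self):
        table = small_table()
        assert compute_rpkm(table).loc["g2", "A_DMSO"] == 0.0

    def test_matches_scalar_loop_oracle(self):
        table = small_table()
        rpkm = compute_rpkm(table)
        lib = table.counts.sum(axis=0)
        for g in table.counts.index:
            for s in table.counts.columns:
                expected = (table.counts.loc[g, s]
                            / (table.lengths[g] / 1e3) / (lib[s] / 1e6))
                assert rpkm.loc[g, s] == pytest.approx(expected)

    def test_pairing_validation(self):
        table = small_table()
        bad_meta = table.meta.copy()
        bad_meta.loc[1, "treatment"] = "DMSO"  # A now has two DMSO arms
        with pytest.raises(ValueError, match="A"):
            ExpressionTable(table.counts, bad_meta, table.lengths)


class TestExpressedUniverse:
    def test_strictly_above_cutoff(self):
        genes = ["hi", "border", "zero"]
        counts = pd.DataFrame({"s1": [100, 1, 0], "s2": [100, 1, 0]},
                              index=pd.Index(genes, name="gene_id"))
        meta = pd.DataFrame({"sample_id": ["s1", "s2"],
                             "individual": ["A", "A"],
                             "group": ["Ctrl", "Ctrl"],
                             "treatment": ["DMSO", "rx"]})
        lengths = pd.Series([1000.0, 1000.0, 1000.0], index=genes)
        table = ExpressionTable(counts, meta, lengths)
        rpkm = compute_rpkm(table)
        cutoff = float(rpkm.loc["border"].mean())  # exact boundary
        uni = expressed_universe(table, cutoff=cutoff)
        assert "hi" in uni and "border" not in uni and "zero" not in uni


class TestFoldChanges:
    def test_single_individual(self):
        genes = ["g1", "pad"]
        counts = pd.DataFrame({"A_DMSO": [4, 96], "A_rx": [8, 92]},
                              index=pd.Index(genes, name="gene_id"))
        meta = pd.DataFrame({"sample_id": ["A_DMSO", "A_rx"],
                             "individual": ["A", "A"],
                             "group": ["Ctrl", "Ctrl"],
                             "treatment": ["DMSO", "rx"]})
        lengths = pd.Series([1000.0, 1000.0], index=genes)
        table = ExpressionTable(counts, meta, lengths)
        fc = group_fold_changes(table, "Ctrl", pseudocount=0.0)
        # equal library sizes and lengths: FC = 8/4 = 2
        assert fc["g1"] == pytest.approx(2.0)
        assert np.log2(fc["g1"]) == pytest.approx(1.0)

    def test_mean_of_ratios_not_ratio_of_means(self):
        # individual A: 1 -> 1 (FC 1); individual B: 1 -> 3 (FC 3)
        # mean of ratios = 2; ratio of means = (1+3)/(1+1) = 2 ... construct
        # an asymmetric case where they differ: A: 4 -> 4 (FC 1), B: 1 -> 3
        genes = ["g", "pad"]
        counts = pd.DataFrame(
            {"A_DMSO": [40, 60], "A_rx": [40, 60],
             "B_DMSO": [10, 90], "B_rx": [30, 70]},
            index=pd.Index(genes, name="gene_id"))
        meta = pd.DataFrame({
            "sample_id": ["A_DMSO", "A_rx", "B_DMSO", "B_rx"],
            "individual": ["A", "A", "B", "B"],
            "group": ["Ctrl"] * 4, "treatment": ["DMSO", "rx"] * 2})
        lengths = pd.Series([1000.0, 1000.0], index=genes)
        table = ExpressionTable(counts, meta, lengths)
        fc = group_fold_changes(table, "Ctrl", pseudocount=0.0)
        mean_of_ratios = (40 / 40 + 30 / 10) / 2  # = 2.0
        ratio_of_means = (40 + 30) / (40 + 10)    # = 1.4
        assert fc["g"] == pytest.approx(mean_of_ratios)
        assert fc["g"] != pytest.approx(ratio_of_means)

    def test_row_and_column_order_invariance(self):
        sim = make_expression_dataset(ExpressionSimSpec(
            seed=1, n_genes=50, target_set_size=10, delta_log2fc=0.3))
        fc1 = group_fold_changes(sim.table, "Ctrl")
        shuffled = ExpressionTable(
            sim.table.counts.iloc[::-1, ::-1],
            sim.table.meta.iloc[::-1].reset_index(drop=True),
            sim.table.lengths.iloc[::-1])
        fc2 = group_fold_changes(shuffled, "Ctrl")
        pd.testing.assert_series_equal(fc1.sort_index(), fc2.sort_index())


class TestUpstreamWindows:
    def _ann(self, rows):
        return GeneAnnotation(pd.DataFrame(
            rows, columns=["gene_id", "chrom", "start", "end", "strand",
                           "length_bp"]))

    def test_plus_strand(self):
        ann = self._ann([("g", "chr1", 10000, 20000, "+", 1000.0)])
        win = upstream_windows(ann, 5000)
        assert (win.loc[0, "start"], win.loc[0, "end"]) == (5000, 10000)

    def test_minus_strand(self):
        ann = self._ann([("g", "chr1", 10000, 20000, "-", 1000.0)])
        win = upstream_windows(ann, 5000)
        assert (win.loc[0, "start"], win.loc[0, "end"]) == (20000, 25000)

    def test_clipped_at_origin(self):
        ann = self._ann([("g", "chr1", 3000, 9000, "+", 1000.0)])
        win = upstream_windows(ann, 5000)
        assert (win.loc[0, "start"], win.loc[0, "end"]) == (0, 3000)

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError):
            self._ann([("g", "chr1", 0, 10, ".", 1.0)])


def brute_force_hits(windows: pd.DataFrame, peaks: PeakSet) -> set:
    """O(n*m) all-pairs half-open overlap oracle."""
    hits = set()
    for row in windows.itertuples():
        for chrom, ps, pe in peaks.intervals:
            if chrom == row.chrom and row.start < pe and ps < row.end:
                hits.add(row.gene_id)
    return hits


class TestGenesWithPeak:
    def _windows(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])

    def test_one_bp_overlap_counts(self):
        win = self._windows([("g", "chr1", 5000, 10000)])
        peaks = PeakSet((("chr1", 9999, 10100),))
        assert genes_with_peak(win, peaks) == {"g"}

    def test_touching_intervals_do_not_overlap(self):
        win = self._windows([("g", "chr1", 5000, 10000)])
        peaks = PeakSet((("chr1", 10000, 10100),))
        assert genes_with_peak(win, peaks) == set()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_toy_genomes(self, seed):
        rng = np.random.default_rng(seed)
        windows = self._windows([
            (f"g{i}", f"chr{rng.integers(1, 4)}",
             s := int(rng.integers(0, 100000)), s + int(rng.integers(1, 5000)))
            for i in range(200)])
        peaks = PeakSet(tuple(
            (f"chr{rng.integers(1, 4)}",
             s := int(rng.integers(0, 100000)), s + int(rng.integers(1, 1000)))
            for _ in range(100)))
        result = genes_with_peak(windows, peaks)
        assert result == brute_force_hits(windows, peaks)

    def test_chromosome_mismatch_warns(self):
        win = self._windows([("g", "chrX", 0, 100)])
        peaks = PeakSet((("chr1", 0, 100),))
        with pytest.warns(UserWarning, match="chr"):
            assert genes_with_peak(win, peaks) == set()


class TestShuffledBackground:
    def test_full_draw_returns_universe(self):
        uni = {"a", "b", "c"}
        assert shuffled_background(uni, 3, 0) == uni

    def test_deterministic_under_seed(self):
        uni = [f"g{i}" for i in range(100)]
        assert shuffled_background(uni, 10, 7) == shuffled_background(uni, 10, 7)

    def test_oversized_draw_rejected(self):
        with pytest.raises(ValueError):
            shuffled_background({"a"}, 2, 0)

    def test_membership_frequency_is_uniform(self):
        uni = [f"g{i}" for i in range(20)]
        rng = np.random.default_rng(0)
        hits = sum("g0" in shuffled_background(uni, 10, rng)
                   for _ in range(4000))
        # binomial(4000, 0.5): 4 sigma ~ 0.032
        assert hits / 4000 == pytest.approx(0.5, abs=0.04)


def brute_force_ks_d(a, b) -> float:
    """Oracle: evaluate the ECDF gap at every pooled breakpoint."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = (a <= x).mean()
        fb = (b <= x).mean()
        best = max(best, abs(fa - fb))
    return best


def kolmogorov_series(x: float, terms: int = 100) -> float:
    """Oracle: Kolmogorov survival function by direct series summation."""
    if x <= 0:
        return 1.0
    return float(2 * sum((-1) ** (k - 1) * np.exp(-2 * k ** 2 * x ** 2)
                         for k in range(1, terms + 1)))


class TestKS:
    def test_identical_samples(self):
        r = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_disjoint_supports(self):
        r = ks_two_sample([1, 2, 3], [10, 20, 30])
        assert r.statistic == 1.0

    def test_d_and_p_match_oracles(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, int(rng.integers(5, 15)))
            b = rng.normal(0.5, 1.2, int(rng.integers(5, 15)))
            r = ks_two_sample(a, b)
            assert r.statistic == pytest.approx(brute_force_ks_d(a, b),
                                                abs=1e-12)
            n_eff = r.n_target * r.n_background / (r.n_target + r.n_background)
            expected_p = min(kolmogorov_series(np.sqrt(n_eff) * r.statistic), 1.0)
            assert r.p_value == pytest.approx(expected_p, abs=1e-6)

    def test_d_matches_scipy(self, rng):
        a, b = rng.normal(size=40), rng.normal(0.3, 1, size=35)
        mine = ks_two_sample(a, b)
        ref = stats.ks_2samp(a, b)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-12)

    def test_p_converges_to_scipy_asymp_at_large_n(self, rng):
        a, b = rng.normal(size=800), rng.normal(0.08, 1, size=800)
        mine = ks_two_sample(a, b)
        ref = stats.ks_2samp(a, b, method="asymp")
        assert mine.p_value == pytest.approx(ref.pvalue, rel=0.15)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestTargetAnalysis:
    def test_injected_shift_detected(self):
        sim = make_expression_dataset(ExpressionSimSpec(
            seed=2, delta_log2fc=0.5))
        peaks, _ = make_peaks(PeakSimSpec(seed=2), sim.annotation,
                              sim.target_genes)
        res = target_vs_background_analysis(
            sim.table, sim.annotation, peaks, seed=3)
        for group in ("Ctrl", "HD"):
            r = res[group]
            assert r.ks.p_value < 0.01
            # target ECDF right-shifted: target median above background median
            assert r.target_log2fc.median() > r.background_log2fc.median()

    def test_background_equal_to_target_gives_zero_d(self):
        sim = make_expression_dataset(ExpressionSimSpec(
            seed=4, n_genes=300, target_set_size=60, delta_log2fc=1.0))
        fc = group_fold_changes(sim.table, "Ctrl")
        vals = np.log2(fc[fc > 0]).loc[sorted(sim.target_genes)].dropna()
        r = ks_two_sample(vals, vals)
        assert r.statistic == 0.0

    def test_null_calibration(self):
        """Without an injected effect the KS test rejects at ~alpha."""
        sim = make_expression_dataset(ExpressionSimSpec(
            seed=5, n_genes=2000, delta_log2fc=0.0))
        fc = group_fold_changes(sim.table, "Ctrl")
        log2fc = np.log2(fc[fc > 0])
        rate = ks_null_calibration(log2fc, n=500, n_replicates=200,
                                   alpha=0.05, seed=9)
        assert 0.01 <= rate <= 0.10  # coarse gate; tight band in acceptance

    def test_power_increases_with_shift(self):
        rates = []
        for delta in (0.25, 0.5, 1.0):
            sim = make_expression_dataset(ExpressionSimSpec(
                seed=6, n_genes=500, target_set_size=50,
                delta_log2fc=delta, dispersion=0.3))
            peaks, _ = make_peaks(PeakSimSpec(seed=6), sim.annotation,
                                  sim.target_genes)
            res = target_vs_background_analysis(
                sim.table, sim.annotation, peaks, seed=7)
            rates.append(res["Ctrl"].ks.statistic)
        assert rates[0] < rates[1] < rates[2]


class TestVenn:
    def test_two_sets(self):
        out = gene_panel_overlap({"1", "2", "3"}, {"3", "4"})
        assert out["A&B"]["count"] == 1
        assert out["A"]["count"] == 2
        assert out["B"]["count"] == 1

    def test_disjoint_sets(self):
        out = gene_panel_overlap({"a"}, {"b"})
        assert "A&B" not in out

    def test_three_sets_match_membership_oracle(self, rng):
        pool = [f"g{i}" for i in range(200)]
        sets = [set(rng.choice(pool, 50, replace=False)) for _ in range(3)]
        out = gene_panel_overlap(*sets)
        for key, payload in out.items():
            members = key.split("&")
            for gene in payload["genes"]:
                for label, s in zip("ABC", sets):
                    assert (gene in s) == (label in members)

    def test_ecdf_coordinates(self):
        df = ecdf([3.0, 1.0, 2.0])
        assert list(df["value"]) == [1.0, 2.0, 3.0]
        assert list(df["ecdf"]) == pytest.approx([1 / 3, 2 / 3, 1.0])
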