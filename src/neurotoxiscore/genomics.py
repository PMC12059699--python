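"""p53 target-gene analysis: promoter windows, peak intersection, ECDF/KS.

The question addressed: are putative p53 target genes (genes with a p53
ChIP-seq peak within 5,000 bp upstream of their transcription start)
preferentially upregulated after treatment, relative to a randomly drawn
background of equal size?

Components:

* RPKM normalization of a paired count matrix (one vehicle and one treated
  sample per individual, individuals grouped Ctrl/HD);
* an expressed-gene universe (mean RPKM strictly above 0.5 across all
  samples);
* per-individual treated/vehicle RPKM fold changes averaged within a group
  (mean of ratios, not ratio of means), reported as log2;
* strand-aware upstream promoter windows intersected with peak intervals
  (0-based half-open throughout; 1 bp overlap suffices);
* a uniformly drawn shuffled background of equal size from the universe;
* a two-sample Kolmogorov-Smirnov comparison of the two log2 fold-change
  distributions (sup ECDF gap; asymptotic p-value).

Coordinates are 0-based half-open internally; GTF input is converted on
read (see `neurotoxiscore.io`), BED is used as-is.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import special

__all__ = [
    "GeneAnnotation",
    "PeakSet",
    "ExpressionTable",
    "KSResult",
    "TargetAnalysis",
    "compute_rpkm",
    "expressed_universe",
    "group_fold_changes",
    "upstream_windows",
    "genes_with_peak",
    "shuffled_background",
    "ks_two_sample",
    "ks_null_calibration",
    "ecdf",
    "target_vs_background_analysis",
    "gene_panel_overlap",
]

logger = logging.getLogger(__name__)

DEFAULT_SPAN = 5000
DEFAULT_RPKM_CUTOFF = 0.5
DEFAULT_PSEUDOCOUNT = 0.1


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene-level annotation table.

    ``table`` columns: gene_id, chrom, start, end (0-based half-open),
    strand (+/-), length_bp (transcript-model length used for RPKM).
    """

    table: pd.DataFrame

    REQUIRED = ("gene_id", "chrom", "start", "end", "strand", "length_bp")

    def __post_init__(self) -> None:
        df = self.table
        missing = set(self.REQUIRED) - set(df.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if not (df["start"] < df["end"]).all():
            raise ValueError("annotation requires start < end")
        bad = ~df["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(
                f"unknown strand for genes: {df.loc[bad, 'gene_id'].tolist()[:5]}")
        if not (df["length_bp"] > 0).all():
            raise ValueError("length_bp must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.table["gene_id"])

    def lengths(self) -> pd.Series:
        return self.table.set_index("gene_id")["length_bp"]


@dataclass(frozen=True)
class PeakSet:
    """ChIP-seq peak intervals, 0-based half-open, as (chrom, start, end)."""

    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"empty peak interval {chrom}:{start}-{end}")

    def __len__(self) -> int:
        return len(self.intervals)

    def chromosomes(self) -> set[str]:
        return {c for c, _, _ in self.intervals}


@dataclass
class ExpressionTable:
    """Gene x sample count matrix with pairing metadata.

    ``counts``: DataFrame indexed by gene_id, columns = sample ids.
    ``meta``: DataFrame with sample_id, individual, group (Ctrl/HD),
    treatment (DMSO/treated). Every individual must contribute exactly one
    DMSO and one treated sample.
    ``lengths``: per-gene transcript length in bp (Series indexed by gene).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    lengths: pd.Series
    rpkm: pd.DataFrame | None = field(default=None, repr=False)

    VEHICLE = "DMSO"

    def __post_init__(self) -> None:
        meta = self.meta
        required = {"sample_id", "individual", "group", "treatment"}
        missing = required - set(meta.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        unknown = set(meta["sample_id"]) - set(self.counts.columns)
        if unknown:
            raise ValueError(f"metadata samples absent from counts: {sorted(unknown)}")
        for ind, grp in meta.groupby("individual"):
            arms = set(grp["treatment"])
            if self.VEHICLE not in arms or len(arms) != 2:
                raise ValueError(
                    f"individual {ind!r} must have exactly one {self.VEHICLE} "
                    f"and one treated sample (has {sorted(arms)})")
        missing_len = set(self.counts.index) - set(self.lengths.index)
        if missing_len:
            raise ValueError(
                f"{len(missing_len)} genes lack a length (e.g. "
                f"{sorted(missing_len)[:3]})")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")


def compute_rpkm(table: ExpressionTable) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    rpkm[g, s] = counts[g, s] / (length_bp[g] / 1e3) / (library_size[s] / 1e6)
    where library_size is the per-sample count total. Cached on the table.
    """
    if table.rpkm is not None:
        return table.rpkm
    lib = table.counts.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples: {bad}")
    kb = table.lengths.reindex(table.counts.index) / 1e3
    rpkm = table.counts.div(kb, axis=0).div(lib / 1e6, axis=1)
    table.rpkm = rpkm
    return rpkm


def expressed_universe(table: ExpressionTable,
                       cutoff: float = DEFAULT_RPKM_CUTOFF) -> set[str]:
    """Genes with mean RPKM across all samples strictly above ``cutoff``."""
    rpkm = compute_rpkm(table)
    mean = rpkm.mean(axis=1)
    return set(mean.index[mean > cutoff])


def group_fold_changes(
    table: ExpressionTable,
    group: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    genes: Optional[Iterable[str]] = None,
) -> pd.Series:
    """Per-gene treated/vehicle fold change, averaged over a group's individuals.

    For each individual i, FC_i[g] = (rpkm_treated + pseudocount) /
    (rpkm_vehicle + pseudocount); the group value is the arithmetic mean of
    FC_i over the group's individuals (mean of ratios). With pseudocount 0,
    genes hitting 0/0 or x/0 in any individual are dropped and logged.
    Returns the linear fold change; take ``np.log2`` for ECDF plotting.
    """
    rpkm = compute_rpkm(table)
    meta = table.meta
    sub = meta[meta["group"] == group]
    if sub.empty:
        raise ValueError(f"no samples in group {group!r}")
    if genes is not None:
        genes = [g for g in genes]
        rpkm = rpkm.loc[rpkm.index.intersection(genes)]
    fcs = []
    for ind, grp in sub.groupby("individual"):
        vehicle = grp.loc[grp["treatment"] == table.VEHICLE, "sample_id"]
        treated = grp.loc[grp["treatment"] != table.VEHICLE, "sample_id"]
        if len(vehicle) != 1 or len(treated) != 1:
            raise ValueError(f"individual {ind!r} is not properly paired")
        num = rpkm[treated.iloc[0]] + pseudocount
        den = rpkm[vehicle.iloc[0]] + pseudocount
        fcs.append(num / den)
    fc = pd.concat(fcs, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_fc = fc.mean(axis=1)
    bad = ~np.isfinite(mean_fc)
    if bad.any():
        logger.info("dropping %d genes with undefined fold change "
                    "(zero denominator at pseudocount 0)", int(bad.sum()))
        mean_fc = mean_fc[~bad]
    return mean_fc


def upstream_windows(annotation: GeneAnnotation,
                     span: int = DEFAULT_SPAN) -> pd.DataFrame:
    """Strand-aware promoter windows of ``span`` bp upstream of the 5' end.

    + strand gene [s, e) -> [max(0, s - span), s); - strand -> [e, e + span).
    Windows clipped at the chromosome origin; a window may be empty for a
    + strand gene starting at 0. Columns: gene_id, chrom, start, end.
    """
    df = annotation.table
    plus = df["strand"] == "+"
    start = np.where(plus, np.maximum(0, df["start"] - span), df["end"])
    end = np.where(plus, df["start"], df["end"] + span)
    return pd.DataFrame(
        {"gene_id": df["gene_id"].to_numpy(), "chrom": df["chrom"].to_numpy(),
         "start": start.astype(np.int64), "end": end.astype(np.int64)}
    )


def genes_with_peak(windows: pd.DataFrame, peaks: PeakSet) -> set[str]:
    """Genes whose window overlaps at least one peak by >= 1 bp.

    Intervals are half-open, so touching intervals do not overlap. Emits a
    warning naming chromosomes present on only one side.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in peaks.intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    window_chroms = set(windows["chrom"].unique())
    unmatched = sorted(window_chroms ^ set(trees))
    if unmatched:
        warnings.warn(
            "chromosomes present on only one side of the intersection: "
            f"{unmatched}", stacklevel=2)
    hits: set[str] = set()
    for gene_id, chrom, start, end in windows[
            ["gene_id", "chrom", "start", "end"]].itertuples(index=False):
        if start >= end:
            continue
        tree = trees.get(chrom)
        if tree is not None and tree.overlap(start, end):
            hits.add(gene_id)
    return hits


def shuffled_background(universe: Iterable[str], n: int,
                        seed: int | np.random.Generator) -> set[str]:
    """Uniform sample of ``n`` genes without replacement from the universe."""
    pool = sorted(universe)
    if n > len(pool):
        raise ValueError(f"cannot draw {n} genes from a universe of {len(pool)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return {pool[i] for i in idx}


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov-Smirnov comparison."""

    statistic: float
    p_value: float
    n_target: int
    n_background: int


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> KSResult:
    """Two-sided two-sample KS test.

    D is the supremum ECDF gap over all pooled breakpoints; the p-value is
    the asymptotic Kolmogorov survival function evaluated at sqrt(n_eff)*D
    with n_eff = n_a*n_b/(n_a+n_b).
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    n_eff = a.size * b.size / (a.size + b.size)
    p = float(special.kolmogorov(np.sqrt(n_eff) * d))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return KSResult(d, p, int(a.size), int(b.size))


def ecdf(values: Sequence[float]) -> pd.DataFrame:
    """Empirical CDF coordinates (columns value, ecdf), step at each point."""
    x = np.sort(np.asarray(values, dtype=float))
    y = np.arange(1, x.size + 1) / x.size
    return pd.DataFrame({"value": x, "ecdf": y})


def ks_null_calibration(values: pd.Series | Sequence[float], n: int,
                        n_replicates: int, alpha: float,
                        seed: int) -> float:
    """Type-I error rate of the target-vs-background KS comparison.

    Repeatedly draws two disjoint gene sets of size ``n`` uniformly from the
    index of ``values`` (disjointness keeps the two samples independent, as
    the KS test assumes) and tests them against each other; returns the
    fraction of replicates with p < ``alpha``. Under the null of no target
    effect this should be close to ``alpha``.
    """
    series = pd.Series(values) if not isinstance(values, pd.Series) else values
    pool = sorted(series.index)
    if 2 * n > len(pool):
        raise ValueError("universe too small for two disjoint draws")
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        idx = rng.choice(len(pool), size=2 * n, replace=False)
        a = series.iloc[idx[:n]].to_numpy()
        b = series.iloc[idx[n:]].to_numpy()
        if ks_two_sample(a, b).p_value < alpha:
            rejections += 1
    return rejections / n_replicates


@dataclass(frozen=True)
class TargetAnalysis:
    """Result of one group's target-vs-background ECDF/KS comparison."""

    group: str
    target_genes: tuple[str, ...]
    background_genes: tuple[str, ...]
    target_log2fc: pd.Series
    background_log2fc: pd.Series
    ks: KSResult
    target_ecdf: pd.DataFrame
    background_ecdf: pd.DataFrame


def target_vs_background_analysis(
    table: ExpressionTable,
    annotation: GeneAnnotation,
    peaks: PeakSet,
    seed: int,
    groups: Sequence[str] = ("Ctrl", "HD"),
    span: int = DEFAULT_SPAN,
    cutoff: float = DEFAULT_RPKM_CUTOFF,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    restrict_to_universe: bool = True,
) -> dict[str, TargetAnalysis]:
    """Full promoter-peak target analysis per group.

    Targets = expressed genes whose upstream window holds a peak; the
    background is an equal-size uniform draw from the expressed universe
    (one draw per group, derived from ``seed``). When
    ``restrict_to_universe`` is False the target list is computed on the
    full annotation instead (reported for comparison when reconciling
    counts against annotation-wide intersections).
    """
    universe = expressed_universe(table, cutoff)
    windows = upstream_windows(annotation, span)
    if restrict_to_universe:
        windows = windows[windows["gene_id"].isin(universe)]
    hit_genes = genes_with_peak(windows, peaks)
    targets = sorted(hit_genes & universe) if restrict_to_universe else sorted(hit_genes)
    if not targets:
        raise ValueError("no expressed target genes found")
    rng = np.random.default_rng(seed)
    out: dict[str, TargetAnalysis] = {}
    for group in groups:
        fc = group_fold_changes(table, group, pseudocount)
        fc = fc[fc > 0]
        log2fc = np.log2(fc)
        background = sorted(shuffled_background(
            set(log2fc.index) & universe, len(targets), rng))
        t_vals = log2fc.reindex(targets).dropna()
        b_vals = log2fc.reindex(background).dropna()
        ks = ks_two_sample(t_vals.to_numpy(), b_vals.to_numpy())
        out[group] = TargetAnalysis(
            group, tuple(targets), tuple(background), t_vals, b_vals,
            ks, ecdf(t_vals), ecdf(b_vals))
    return out


def gene_panel_overlap(
    set_a: Iterable[str], set_b: Iterable[str],
    set_c: Optional[Iterable[str]] = None,
    names: Sequence[str] = ("A", "B", "C"),
) -> dict[str, dict]:
    """Venn region counts (and memberships) for two or three gene sets.

    Region keys are like "A", "A&B", "A&B&C": genes in exactly those sets.
    """
    sets: dict[str, set[str]] = {names[0]: set(set_a), names[1]: set(set_b)}
    if set_c is not None:
        sets[names[2]] = set(set_c)
    labels = list(sets)
    all_genes = set().union(*sets.values())
    regions: dict[str, set[str]] = {}
    for gene in all_genes:
        member = [lab for lab in labels if gene in sets[lab]]
        key = "&".join(member)
        regions.setdefault(key, set()).add(gene)
    return {
        key: {"count": len(genes), "genes": sorted(genes)}
        for key, genes in sorted(regions.items())
    }
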