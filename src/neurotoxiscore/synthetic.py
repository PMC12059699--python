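"""Seeded synthetic-data generators with machine-readable ground truth.

Every input modality the package quantifies can be generated here with a
known answer, so each pipeline stage is testable end-to-end without any
external download:

* neurite fields — random-walk tubes of beta-III-Tubulin-like signal in
  which a chosen fraction of neurite pixels is elevated into bright,
  bead-like "disintegrated" runs;
* nucleus fields — DAPI / tubulin / NPM1 channel triplets with circular
  nuclei, one nucleolus each, and a translocation parameter ``s`` that
  moves NPM1 from nucleolus to nucleoplasm at conserved total intensity;
* paired expression tables — negative-binomial counts for vehicle/treated
  pairs with a log2 fold-change shift injected into a designated target
  gene set, plus a matching toy gene annotation;
* peak files — ChIP-seq-like intervals placed inside the upstream windows
  of target genes, with uniformly placed decoys excluded from all windows;
* FACS event tables — bimodal DNA content (2n/4n lognormal modes, S-phase
  events in between) with EdU-positive S events and known phase fractions.

Determinism: one top-level seed derives an independent child stream per
modality through fixed ``numpy.random.SeedSequence`` spawn keys, so adding
a generator never perturbs the data produced by another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genomics import ExpressionTable, GeneAnnotation, PeakSet, upstream_windows
from .cellcycle import FacsEvents
from .images import ChannelImage

__all__ = [
    "NeuriteImageSpec",
    "NucleusImageSpec",
    "ExpressionSimSpec",
    "PeakSimSpec",
    "FacsSimSpec",
    "NeuriteField",
    "NucleusField",
    "make_neurite_images",
    "make_nucleus_images",
    "make_expression_dataset",
    "make_peaks",
    "make_facs_events",
    "child_rng",
]

# fixed spawn keys: one independent stream per modality
_SPAWN_KEYS = {"neurites": 0, "nuclei": 1, "expression": 2, "peaks": 3, "facs": 4}


def child_rng(seed: int, modality: str, index: int = 0) -> np.random.Generator:
    """Deterministic per-modality child generator of a top-level seed."""
    key = _SPAWN_KEYS[modality]
    ss = np.random.SeedSequence(seed, spawn_key=(key, index))
    return np.random.default_rng(ss)


# --------------------------------------------------------------------------
# neurite fields
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuriteImageSpec:
    """Parameters of a synthetic beta-III-Tubulin field of view.

    Geometry emulates 20x imaging of motor-neuron cultures: a few long,
    gently curving neurite bundles of ~5 px width over a dark background.
    ``fragmentation_fraction`` is the fraction of neurite pixels elevated
    to ``swelling_intensity_multiplier x base_intensity`` in contiguous
    bead-like runs, emulating disintegrated, high-intensity segments
    (swellings roughly double the shaft intensity).
    """

    image_size: tuple[int, int] = (256, 256)
    n_neurites: int = 5
    neurite_width: int = 5
    base_intensity: float = 100.0
    background_intensity: float = 10.0
    noise_sd: float = 5.0
    fragmentation_fraction: float = 0.0
    swelling_intensity_multiplier: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fragmentation_fraction <= 1.0:
            raise ValueError("fragmentation_fraction must lie in [0, 1]")
        if self.swelling_intensity_multiplier <= 1.0:
            raise ValueError("swelling_intensity_multiplier must be > 1")
        if self.noise_sd < 0 or self.base_intensity <= 0:
            raise ValueError("invalid intensity parameters")


@dataclass(frozen=True)
class NeuriteField:
    """One synthetic field: image + ground truth."""

    image: ChannelImage
    neurite_mask: np.ndarray
    elevated_mask: np.ndarray
    truth_fraction: float


def _stamp_disk(canvas: np.ndarray, cy: float, cx: float, radius: float) -> None:
    h, w = canvas.shape
    y0, y1 = max(0, int(cy - radius) - 1), min(h, int(cy + radius) + 2)
    x0, x1 = max(0, int(cx - radius) - 1), min(w, int(cx + radius) + 2)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2


def _random_walk_tube(rng: np.random.Generator, shape: tuple[int, int],
                      radius: float) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """A smooth random-walk tube; returns its mask and ordered path points."""
    h, w = shape
    margin = radius + 2
    y = rng.uniform(margin, h - margin)
    x = rng.uniform(margin, w - margin)
    theta = rng.uniform(0, 2 * np.pi)
    mask = np.zeros(shape, dtype=bool)
    path: list[tuple[float, float]] = []
    n_steps = int(1.2 * max(h, w))
    for _ in range(n_steps):
        path.append((y, x))
        _stamp_disk(mask, y, x, radius)
        theta += rng.normal(0, 0.12)
        y += math.sin(theta)
        x += math.cos(theta)
        if not (margin <= y < h - margin and margin <= x < w - margin):
            # bounce back toward the interior
            theta += np.pi / 2
            y = min(max(y, margin), h - margin - 1)
            x = min(max(x, margin), w - margin - 1)
    return mask, path


def make_neurite_images(spec: NeuriteImageSpec, n_images: int = 1,
                        ) -> list[NeuriteField]:
    """Generate seeded neurite fields with exact elevated-pixel truth.

    Bead-like elevated runs are stamped along the tube paths until exactly
    ``round(f * neurite_area)`` pixels are elevated (the last bead is
    trimmed pixel-wise), so the recorded truth fraction equals the
    requested one up to rounding.
    """
    fields: list[NeuriteField] = []
    for i in range(n_images):
        rng = child_rng(spec.seed, "neurites", i)
        h, w = spec.image_size
        radius = spec.neurite_width / 2.0
        mask = np.zeros((h, w), dtype=bool)
        paths: list[list[tuple[float, float]]] = []
        for _ in range(spec.n_neurites):
            tube, path = _random_walk_tube(rng, (h, w), radius)
            mask |= tube
            paths.append(path)
        total = int(mask.sum())
        target_elevated = int(round(spec.fragmentation_fraction * total))
        elevated = np.zeros((h, w), dtype=bool)
        if target_elevated > 0 and paths:
            guard = 0
            while int((elevated & mask).sum()) < target_elevated and guard < 10000:
                guard += 1
                path = paths[rng.integers(len(paths))]
                start = rng.integers(len(path))
                run_len = int(rng.integers(8, 25))
                for (py, px) in path[start:start + run_len]:
                    _stamp_disk(elevated, py, px, radius)
                elevated &= mask
            # trim the surplus from the last bead's pixels, keeping runs compact
            excess = int(elevated.sum()) - target_elevated
            if excess > 0:
                ys, xs = np.nonzero(elevated)
                drop = rng.choice(ys.size, size=excess, replace=False)
                elevated[ys[drop], xs[drop]] = False
        image = np.full((h, w), spec.background_intensity, dtype=float)
        image[mask] = spec.base_intensity
        image[elevated] = spec.swelling_intensity_multiplier * spec.base_intensity
        image += rng.normal(0, spec.noise_sd, size=(h, w))
        np.clip(image, 0, None, out=image)
        truth = elevated.sum() / total if total else 0.0
        fields.append(NeuriteField(ChannelImage(image, "tubulin"), mask,
                                   elevated, float(truth)))
    return fields


# --------------------------------------------------------------------------
# nucleus / NPM1 fields
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleusImageSpec:
    """Parameters of a synthetic DAPI/tubulin/NPM1 field.

    ``translocation`` s in [0, 1] linearly moves NPM1 from the nucleolus
    into the nucleoplasm while conserving total nuclear NPM1: at s = 0 the
    compartments hold their nominal intensities, at s = 1 both equal the
    nuclear mean (complete dispersal). Geometry emulates 63x imaging:
    nuclei of ~22 px radius, one ~7 px nucleolus each.
    """

    n_nuclei: int = 10
    image_size: tuple[int, int] = (512, 512)
    nucleus_radius: float = 22.0
    nucleolus_radius: float = 7.0
    nucleolar_intensity: float = 200.0
    nucleoplasm_intensity: float = 60.0
    translocation: float = 0.0
    noise_sd: float = 4.0
    dapi_intensity: float = 150.0
    tubulin_intensity: float = 120.0
    background_intensity: float = 6.0
    neuron_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.translocation <= 1.0:
            raise ValueError("translocation must lie in [0, 1]")
        if self.nucleolus_radius >= self.nucleus_radius:
            raise ValueError("nucleolus must be smaller than the nucleus")
        if not 0.0 <= self.neuron_fraction <= 1.0:
            raise ValueError("neuron_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class NucleusTruth:
    """Ground truth for one synthetic nucleus."""

    label: int
    nucleus_mask: np.ndarray
    nucleolus_mask: np.ndarray
    nucleolar_intensity: float
    nucleoplasm_intensity: float
    ratio: float
    in_neuron: bool


@dataclass(frozen=True)
class NucleusField:
    """One synthetic three-channel field with per-nucleus truth."""

    dapi: ChannelImage
    tubulin: ChannelImage
    npm1: ChannelImage
    nuclei: list[NucleusTruth]
    neuron_mask: np.ndarray


def _compartment_intensities(spec: NucleusImageSpec, a_no: int, a_np: int,
                             ) -> tuple[float, float]:
    """Nucleolar/nucleoplasm intensities at translocation s, total conserved."""
    s = spec.translocation
    total = spec.nucleolar_intensity * a_no + spec.nucleoplasm_intensity * a_np
    uniform = total / (a_no + a_np)
    i_no = (1 - s) * spec.nucleolar_intensity + s * uniform
    i_np = (1 - s) * spec.nucleoplasm_intensity + s * uniform
    return i_no, i_np


def make_nucleus_images(spec: NucleusImageSpec, n_images: int = 1,
                        ) -> list[NucleusField]:
    """Generate seeded nucleus fields with per-cell compartment truth.

    Nuclei are placed without overlap (bounded rejection sampling); a
    ``neuron_fraction`` of them falls inside the tubulin-positive neuron
    region (left part of the field), the rest outside it.
    """
    fields: list[NucleusField] = []
    for i in range(n_images):
        rng = child_rng(spec.seed, "nuclei", i)
        h, w = spec.image_size
        r = spec.nucleus_radius
        margin = r + 4
        centers: list[tuple[float, float, bool]] = []
        n_inside = int(round(spec.neuron_fraction * spec.n_nuclei))
        # neuron region: left 60% of the field
        split = 0.6 * w
        attempts = 0
        while len(centers) < spec.n_nuclei:
            attempts += 1
            if attempts > 20000:
                raise RuntimeError("could not pack nuclei without overlap; "
                                   "reduce n_nuclei or nucleus_radius")
            inside = len(centers) < n_inside
            if inside:
                cx = rng.uniform(margin, split - margin)
            else:
                cx = rng.uniform(split + margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            if all((cy - y0) ** 2 + (cx - x0) ** 2 > (2 * r + 4) ** 2
                   for y0, x0, _ in centers):
                centers.append((cy, cx, inside))
        yy, xx = np.mgrid[0:h, 0:w]
        neuron_mask = xx < split
        dapi = np.full((h, w), spec.background_intensity, dtype=float)
        tub = np.where(neuron_mask, spec.tubulin_intensity,
                       spec.background_intensity).astype(float)
        npm1 = np.full((h, w), spec.background_intensity, dtype=float)
        truths: list[NucleusTruth] = []
        for label, (cy, cx, inside) in enumerate(centers, start=1):
            dist2 = (yy - cy) ** 2 + (xx - cx) ** 2
            nucleus = dist2 <= r ** 2
            nucleolus = dist2 <= spec.nucleolus_radius ** 2
            a_no = int(nucleolus.sum())
            a_np = int(nucleus.sum()) - a_no
            i_no, i_np = _compartment_intensities(spec, a_no, a_np)
            dapi[nucleus] = spec.dapi_intensity
            npm1[nucleus & ~nucleolus] = i_np
            npm1[nucleolus] = i_no
            truths.append(NucleusTruth(
                label, nucleus, nucleolus, i_no, i_np,
                i_np / i_no, inside))
        for channel in (dapi, tub, npm1):
            channel += rng.normal(0, spec.noise_sd, size=(h, w))
            np.clip(channel, 0, None, out=channel)
        fields.append(NucleusField(
            ChannelImage(dapi, "dapi"), ChannelImage(tub, "tubulin"),
            ChannelImage(npm1, "npm1"), truths, neuron_mask))
    return fields


# --------------------------------------------------------------------------
# expression tables and peak files
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionSimSpec:
    """Paired vehicle/treated count matrix with an injected target shift.

    Mirrors the fibroblast cohort design: ``n_individuals`` per group
    (Ctrl and HD), each contributing one DMSO and one treated sample.
    ``delta_log2fc`` is added (in expectation) to the designated target
    genes in every treated sample. Counts are negative-binomial
    (gamma-Poisson) around log-normal baselines.
    """

    n_genes: int = 2000
    n_individuals: int = 4
    target_set_size: int = 200
    delta_log2fc: float = 0.0
    dispersion: float = 0.05
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_set_size > self.n_genes:
            raise ValueError("target_set_size cannot exceed n_genes")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass(frozen=True)
class ExpressionSim:
    """Simulated expression dataset with its toy annotation and truth."""

    table: ExpressionTable
    annotation: GeneAnnotation
    target_genes: tuple[str, ...]


def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Gamma-Poisson (NB2) draw: var = mean + dispersion * mean^2."""
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def make_expression_dataset(spec: ExpressionSimSpec) -> ExpressionSim:
    """Simulate the paired count matrix, annotation and target truth set."""
    rng = child_rng(spec.seed, "expression")
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    targets = tuple(sorted(
        np.array(genes)[rng.choice(spec.n_genes, spec.target_set_size,
                                   replace=False)]))
    is_target = np.isin(genes, targets)
    baseline = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd,
                             spec.n_genes)
    lengths = pd.Series(
        rng.integers(500, 10000, spec.n_genes).astype(float),
        index=genes, name="length_bp")
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for group in ("Ctrl", "HD"):
        for k in range(spec.n_individuals):
            individual = f"{group}{k + 1}"
            indiv_effect = rng.lognormal(0, 0.05, spec.n_genes)
            for treatment in ("DMSO", "branaplam"):
                sample = f"{individual}_{treatment}"
                mu = baseline * indiv_effect
                if treatment == "branaplam":
                    mu = mu * np.where(is_target, 2.0 ** spec.delta_log2fc, 1.0)
                columns[sample] = _nb_sample(rng, mu, spec.dispersion)
                meta_rows.append({"sample_id": sample, "individual": individual,
                                  "group": group, "treatment": treatment})
    counts = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    meta = pd.DataFrame(meta_rows)
    table = ExpressionTable(counts, meta, lengths)
    # toy genome: genes laid out on 4 chromosomes with generous spacing
    n_chroms = 4
    per_chrom = -(-spec.n_genes // n_chroms)
    rows = []
    for i, gene in enumerate(genes):
        chrom = f"chr{i // per_chrom + 1}"
        pos = 20000 + (i % per_chrom) * 30000
        length = int(rng.integers(2000, 15000))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append({"gene_id": gene, "chrom": chrom, "start": pos,
                     "end": pos + length, "strand": strand,
                     "length_bp": float(lengths[gene])})
    annotation = GeneAnnotation(pd.DataFrame(rows))
    return ExpressionSim(table, annotation, targets)


@dataclass(frozen=True)
class PeakSimSpec:
    """Peak placement: a fraction of target genes get an upstream peak."""

    target_fraction: float = 1.0
    n_decoys: int = 100
    peak_width: int = 300
    span: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValueError("target_fraction must lie in [0, 1]")


def make_peaks(spec: PeakSimSpec, annotation: GeneAnnotation,
               targets: Sequence[str]) -> tuple[PeakSet, set[str]]:
    """Place peaks inside target upstream windows, decoys outside all windows.

    Returns the peak set and the genes that actually received a peak
    (the recorded truth membership). Windows too small for the requested
    peak width get a shrunken peak instead.
    """
    target_set = set(targets)
    unknown = target_set - set(annotation.table["gene_id"])
    if unknown:
        raise ValueError(f"targets absent from annotation: {sorted(unknown)[:5]}")
    rng = child_rng(spec.seed, "peaks")
    windows = upstream_windows(annotation, spec.span)
    windows = windows.set_index("gene_id")
    chrom_max = annotation.table.groupby("chrom")["end"].max() + spec.span + 100000
    chosen_n = int(round(spec.target_fraction * len(targets)))
    chosen = sorted(rng.choice(sorted(target_set), chosen_n, replace=False))
    intervals: list[tuple[str, int, int]] = []
    placed: set[str] = set()
    for gene in chosen:
        win = windows.loc[gene]
        size = int(win["end"] - win["start"])
        if size <= 0:
            continue
        width = min(spec.peak_width, size)
        start = int(win["start"]) + int(rng.integers(0, size - width + 1))
        intervals.append((str(win["chrom"]), start, start + width))
        placed.add(gene)
    # decoys: uniform, rejected if overlapping any gene's upstream window
    all_windows: dict[str, list[tuple[int, int]]] = {}
    for _, row in windows.reset_index().iterrows():
        all_windows.setdefault(row["chrom"], []).append(
            (int(row["start"]), int(row["end"])))
    chroms = sorted(chrom_max.index)
    n_placed_decoys = 0
    guard = 0
    while n_placed_decoys < spec.n_decoys and guard < 100 * spec.n_decoys + 100:
        guard += 1
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, int(chrom_max[chrom]) - spec.peak_width))
        end = start + spec.peak_width
        if any(start < we and ws < end
               for ws, we in all_windows.get(chrom, [])):
            continue
        intervals.append((chrom, start, end))
        n_placed_decoys += 1
    return PeakSet(tuple(intervals)), placed


# --------------------------------------------------------------------------
# FACS events
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FacsSimSpec:
    """Bimodal DNA-content event stream with known phase fractions.

    G0/G1 events sit on a lognormal mode at ``mode_2n`` (CV ``cv_2n``),
    G2/M on ``mode_4n``; S-phase DNA content is uniform between the modes
    and S events draw EdU from the positive distribution, everything else
    from the negative one.
    """

    n_events: int = 20000
    fractions: tuple[float, float, float] = (0.55, 0.30, 0.15)  # G0/G1, S, G2/M
    mode_2n: float = 100.0
    mode_4n: float = 200.0
    cv_2n: float = 0.05
    cv_4n: float = 0.05
    edu_negative_median: float = 80.0
    edu_positive_median: float = 2000.0
    edu_log_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("phase fractions must sum to 1")


def make_facs_events(spec: FacsSimSpec) -> tuple[FacsEvents, tuple[float, float, float]]:
    """Simulate events; returns (events, realized phase fractions)."""
    rng = child_rng(spec.seed, "facs")
    phases = rng.choice(3, size=spec.n_events, p=list(spec.fractions))
    dna = np.empty(spec.n_events)
    g1 = phases == 0
    s = phases == 1
    g2 = phases == 2
    dna[g1] = spec.mode_2n * np.exp(rng.normal(0, spec.cv_2n, g1.sum()))
    dna[g2] = spec.mode_4n * np.exp(rng.normal(0, spec.cv_4n, g2.sum()))
    dna[s] = rng.uniform(spec.mode_2n, spec.mode_4n, s.sum())
    edu = np.where(
        s,
        spec.edu_positive_median * np.exp(rng.normal(0, spec.edu_log_sd,
                                                     spec.n_events)),
        spec.edu_negative_median * np.exp(rng.normal(0, spec.edu_log_sd,
                                                     spec.n_events)))
    realized = (float(g1.mean()), float(s.mean()), float(g2.mean()))
    return FacsEvents(dna, edu), realized
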