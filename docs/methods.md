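# Methods

This note records the models, parameter choices and numerical conventions
behind each quantification stage, what the synthetic generators do and do
not emulate, and the known limitations.

## Imaging primitives

All segmentation steps are composed from a small operator set with fixed
conventions:

* **Smoothing scale** is a Gaussian σ in pixels; scale 0 is the identity.
  (Acquisition software exposes a similarly named parameter whose internal
  convention is not documented; this package fixes the simplest monotone
  interpretation.)
* **Otsu thresholding** maximizes between-class variance over a 256-bin
  histogram spanning the image's own [min, max]; candidate thresholds are
  interior bin edges, pixels ≥ threshold are foreground, and ties break
  toward the lowest edge. The tie-break matters: on a cleanly bimodal
  histogram every cut through the empty gap gives the same variance, and
  choosing the lowest edge keeps bright objects fully segmented even under
  a correction factor of 2. The computed threshold is multiplied by the
  step's *correction factor* before binarization.
* **Adaptive Otsu** tiles the image (window 50 px by default), computes a
  per-tile Otsu threshold and interpolates bilinearly between tile
  centers. Tiles with standard deviation below 5% of the global intensity
  range inherit the global threshold — without this guard a featureless
  tile would Otsu-split its own noise.
* **Line-structure enhancement** is Hessian tubeness at σ = feature_size/2:
  the magnitude of the most negative Hessian eigenvalue (bright ridges
  curve downward across their width), scale-normalized by σ², clipped at
  zero. The image mean is subtracted before filtering — mathematically a
  no-op, numerically it suppresses the small DC leakage of sampled
  derivative kernels so constants map to exactly zero.
* **Edge enhancement** is plain Sobel gradient magnitude with no
  normalization: a vertical step of height h scores 4h on the adjacent
  interior columns.
* **Labelling** is 8-connected; background holes (4-connected, not
  touching the border) of area ≤ the hole limit and enclosed by a single
  object are filled into it.

All operators are deterministic and geometry-preserving.

## Neurite disintegration index

The index rests on the observation that destabilized microtubules in
fragmenting neurites occupy higher fluorescence intensities. Pipeline:
ridge enhancement (feature size 10 px) → global Otsu, correction 1.3, no
hole filling → merge all foreground into one neurite-area object.
Per cell line, vehicle images supply a calibration threshold
T = mean + k·SD (k = 3) of in-neurite intensity, where the per-image means
and per-image SDs (population SD, ddof 0) are averaged across vehicle
images; pooling all vehicle pixels instead is available as an option.
"Above threshold" is strict inequality — fixed so results are bit-exact.

Decisions worth noting:

* Images whose neurite mask is empty produce a flagged-undefined index
  rather than 0; scoring a fully degenerated image as 0 would bias treated
  groups toward "healthy". Undefined images are excluded from group means
  with a logged count.
* Otsu happily splits noise on a blank field, so a candidate mask whose
  mean intensity is less than 2× the out-of-mask mean is treated as blank
  (empty mask). The 2× contrast floor is far below any real stain contrast
  and scale-invariant.

## NPM1 translocation ratio

Per field of view: nuclei from DAPI (global Otsu, smoothing 0.5,
correction 2), neuron area from beta-III-Tubulin (adaptive Otsu, smoothing
1.3488, correction 1.3), neuronal nuclei by ≥50% area overlap (the
boundary case retained; centroid containment would be the alternative
parentage rule). Nucleoli: NPM1 masked to neuronal nuclei, Sobel, Gaussian
σ 2.5, adaptive Otsu (smoothing 1, correction 1), merged per nucleus,
holes ≤ 50 px filled. Intensity is always measured on the original NPM1
image; measuring on the edge-enhanced derivative would corrupt the ratio.
The ratio is of compartment *mean* intensities (area-independent), not
integrated intensities.

Two guards:

* Masking NPM1 to the nucleus manufactures a strong artificial edge at the
  nucleus boundary; its Sobel ring must not be counted as nucleolar
  signal, so nucleolar pixels are collected only within the nucleus eroded
  by 5 px (the edge-detector support).
* Cells with no detected nucleolar pixels are flagged invalid and excluded
  from medians (not given an infinite ratio); exclusion counts are logged
  because complete NPM1 dispersal is itself informative — at full
  translocation there is no edge structure left to segment, and that is
  the expected behaviour, not a failure.

Accuracy note: the edge-based segmentation localizes nucleoli but its
objects are dilated by the detector support (roughly the Gaussian σ plus
the Sobel footprint), so pipeline-measured ratios are biased toward 1 by
nucleoplasm contamination of the nucleolar compartment. The pipeline is
therefore validated as a *ranking* instrument (medians strictly increase
with true translocation), while quantitative recovery of the constructed
ratio is validated with the measurement operator on given compartments,
where it is exact up to noise. Per-cell compartment disjointness and
containment are asserted for every measurement.

## p53 promoter-target analysis

RPKM = counts / (gene length in kb) / (library size in millions), with
library size the per-sample column total. The expressed universe is genes
with mean RPKM strictly > 0.5 across all samples. Fold changes are
computed per individual as (RPKM_treated + c)/(RPKM_vehicle + c) and then
averaged across a group's individuals — mean of ratios, which is what
"calculated first for each individual and then averaged" pins down; the
pseudocount c defaults to 0.1 RPKM (c = 0 is allowed, with 0/0 and x/0
genes dropped and logged). Note the mean-of-ratios estimator carries a
small positive Jensen bias that applies to every gene equally; target
effects are always judged against a background drawn from the same
distribution, so the bias cancels in the comparison.

Promoter windows are strand-aware: [start − 5000, start) for + genes,
[end, end + 5000) for − genes, clipped at the chromosome origin, one
window per gene-level record. Coordinates are 0-based half-open
everywhere; BED is read as-is, GTF converted on read. A gene is a target
when its window overlaps any peak by ≥ 1 bp; touching half-open intervals
do not overlap. The shuffled background is drawn uniformly without
replacement from the expressed universe (fold changes exist only for
expressed genes), with equal size to the target set.

The KS test is two-sided: D is the supremum ECDF gap over all pooled
breakpoints, p the asymptotic Kolmogorov survival function at
√(n₁n₂/(n₁+n₂))·D. Small-sample p-values from this asymptotic form are
conservative; at the set sizes this analysis runs at (hundreds of genes)
the null rejection rate at α = 0.05 calibrates to 5% ± 1.5% (checked over
500 seeded replicates at n = 865 per arm, the set size of the motivating
analysis).

## Cell-cycle gating

Events are assumed pre-gated single nuclei. The 2n/4n DNA-content modes
are found on a Gaussian KDE (bandwidth 0.08 relative); among the most
prominent density peaks, the first pair with ratio in [1.7, 2.3] is taken
as (2n, 4n) — outside that window the data do not look like a DNA-content
histogram and the fit errors out, suggesting manual gates. Gate
half-widths are 3σ with σ recovered from the KDE half-width at
half-maximum; the G1/G2 divide at the geometric mean of the modes keeps
the gates disjoint. EdU positivity comes from the 99.5th percentile of an
EdU-negative control when available, otherwise from the valley of the
bimodal log-intensity distribution (two-class split). EdU⁺ events are S
regardless of DNA content; percentages are over classified events and
unclassified events are reported, never silently dropped. Classification
is invariant under common positive rescaling of intensities.

## Exposure comparison

ng/mL = nM × (g/mol)/1000; AUC of a constant profile is concentration ×
duration. The compound's molar mass defaults to 393.5 g/mol (the registry
value ≈ 393.48 gives identical results at reporting precision). Ratios
are reported rounded half-up to one decimal, full precision retained
internally. The dosing-period comparison (17 weeks × 7 / 5 days = 23.8) is
computed but carries no accuracy claim beyond its arithmetic: constant
bath concentration is an idealization — uptake, elimination and medium
changes are not modelled.

## Synthetic data

Generators emulate the statistical structure each pipeline keys on, not
photorealism:

* **Neurite fields** (256², 5 random-walk tubes of 5 px width, shaft
  intensity 100 over background 10, read noise σ 5): a requested fraction
  f of neurite pixels is elevated to 2× shaft intensity in contiguous
  bead-like runs, trimmed pixel-wise so the realized fraction equals
  round(f·area)/area exactly. The 2× swelling contrast keeps beads well
  above the vehicle calibration threshold while leaving the Otsu
  segmentation of the ridge-enhanced image unbiased; much brighter beads
  would stretch the response histogram and starve the shaft of mask
  coverage — a real failure mode of intensity-threshold pipelines that
  the defaults deliberately avoid.
* **Nucleus fields** (512², nuclei r = 22 px, one nucleolus r = 7 px,
  nucleolar/nucleoplasm intensities 200/60, noise σ 4): the translocation
  parameter s linearly interpolates both compartments toward the nuclear
  mean, conserving total nuclear NPM1 exactly; DAPI nuclei carry a flat
  profile and the neuron region covers a configurable fraction of nuclei.
* **Expression tables** (2,000 genes, 4 individuals per group with paired
  vehicle/treated samples, log-normal baselines, gamma-Poisson counts at
  dispersion 0.05, 200 designated targets): the treated arms of target
  genes are shifted by δ log₂ units in expectation. A toy 4-chromosome
  annotation with generous inter-gene spacing accompanies each table.
* **Peak files**: one peak (300 bp) uniformly placed inside the upstream
  window of each chosen target; decoys sampled uniformly and rejected if
  they touch any gene's window, so decoy hits are impossible by
  construction.
* **FACS events** (20,000; fractions 55/30/15%): lognormal DNA modes at
  100/200 (CV 5%), S-phase DNA uniform between modes, lognormal EdU with
  a 25× positive/negative separation.

One top-level seed derives an independent child stream per modality via
fixed `SeedSequence` spawn keys, so adding a generator never perturbs
another's output; every generator is bit-deterministic under its seed.

What passing synthetic tests does *not* show: robustness to uneven
illumination beyond the constructed gradients, to touching/overlapping
nuclei (declumping is out of scope), to autofluorescence or debris, to
batch effects or library-composition bias in the counts, or to cytometry
spillover and doublets. Real-data behaviour of the thresholds (correction
factors, the 50 px hole limit, the 2n/4n ratio window) inherits from the
original acquisition settings and may need adjustment for other
microscopes or stains; every such parameter is surfaced in the
configuration with the original value as default.

## Problem sizes

The test suite and the acceptance script run at sizes chosen to make the
stochastic recoveries statistically meaningful while staying lightweight:
10 images per fragmentation level (index SE ≪ the ±0.02 check), 100 cells
per translocation level, 500 null replicates at n = 865 per arm for the
KS calibration (SE of the rejection rate ≈ 1%), 20,000 cytometry events
(phase SE ≤ 0.35 points), 100 random toy genomes for the interval oracle.
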