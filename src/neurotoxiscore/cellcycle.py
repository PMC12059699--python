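"""EdU/DAPI cell-cycle gating of flow-cytometry event tables.

Events are pre-gated single nuclei with a DNA-stain (DAPI) intensity and an
EdU (replication-label) intensity. Classification semantics:

* EdU above the positivity threshold -> S phase, regardless of DNA content
  (an EdU+ event near 4n is still replicating);
* otherwise DNA content in the 2n gate -> G0/G1, in the 4n gate -> G2/M;
* anything else is counted as unclassified, never silently dropped.

The original gating is done by eye in acquisition software; here the gates
are reproducible: the two dominant DNA-content modes are located on a
kernel-density estimate (their ratio must look like 2n/4n, i.e. fall in
[1.7, 2.3]), gate half-widths are 3 sigma with sigma recovered from the
half-width at half-maximum of each mode, and the G1/G2 divide is the
geometric mean of the two modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal, stats

from .images import _otsu_scalar

__all__ = [
    "FacsEvents",
    "DnaGates",
    "PhaseFractions",
    "fit_dna_modes",
    "edu_threshold_from_control",
    "edu_threshold_from_mixture",
    "classify_events",
]

MODE_RATIO_RANGE = (1.7, 2.3)
HWHM_TO_SIGMA = 1.0 / np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class FacsEvents:
    """Per-event DNA-stain and EdU intensities plus sample metadata."""

    dna_intensity: np.ndarray
    edu_intensity: np.ndarray
    cell_line: str = ""
    group: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        dna = np.asarray(self.dna_intensity, dtype=float)
        edu = np.asarray(self.edu_intensity, dtype=float)
        if dna.shape != edu.shape or dna.ndim != 1:
            raise ValueError("dna and edu intensities must be 1-D and aligned")
        if not (np.isfinite(dna).all() and np.isfinite(edu).all()):
            raise ValueError("intensities must be finite")
        if (dna <= 0).any() or (edu <= 0).any():
            raise ValueError("intensities must be positive")
        object.__setattr__(self, "dna_intensity", dna)
        object.__setattr__(self, "edu_intensity", edu)

    def __len__(self) -> int:
        return self.dna_intensity.size


@dataclass(frozen=True)
class DnaGates:
    """2n/4n mode locations and the derived gate boundaries."""

    mode_2n: float
    mode_4n: float
    g1_gate: tuple[float, float]
    g2m_gate: tuple[float, float]


@dataclass(frozen=True)
class PhaseFractions:
    """Phase percentages over classified events."""

    pct_g0g1: float
    pct_s: float
    pct_g2m: float
    n_events: int
    n_unclassified: int

    def __post_init__(self) -> None:
        total = self.pct_g0g1 + self.pct_s + self.pct_g2m
        if abs(total - 100.0) > 0.01:
            raise ValueError(f"phase percentages sum to {total}, not 100")


class ModeFitError(RuntimeError):
    """The 2n/4n DNA-content modes could not be located automatically."""


def fit_dna_modes(events: FacsEvents) -> DnaGates:
    """Locate the 2n and 4n DNA-content modes and derive gate boundaries.

    A Gaussian KDE of the DNA intensities is scanned for local maxima; the
    pair of the two most prominent peaks whose ratio falls in [1.7, 2.3] is
    taken as (2n, 4n). Gates are mode +/- 3 sigma (sigma from the KDE
    half-width at half-maximum), truncated at the geometric mean of the two
    modes so the G1 and G2/M gates cannot overlap.
    """
    dna = events.dna_intensity
    if dna.size < 200:
        raise ModeFitError("need at least 200 events to fit DNA modes")
    kde = stats.gaussian_kde(dna, bw_method=0.08)
    lo, hi = dna.min(), dna.max()
    grid = np.linspace(lo, hi, 1024)
    dens = kde(grid)
    peaks, props = signal.find_peaks(dens, prominence=0.05 * dens.max())
    if peaks.size < 2:
        raise ModeFitError(
            "fewer than two DNA-content modes found; supply gates manually")
    order = np.argsort(props["prominences"])[::-1]
    candidates = peaks[order][:5]
    best: Optional[tuple[float, float]] = None
    for i in range(len(candidates)):
        for j in range(len(candidates)):
            m1, m2 = grid[candidates[i]], grid[candidates[j]]
            if m2 <= m1:
                continue
            if MODE_RATIO_RANGE[0] <= m2 / m1 <= MODE_RATIO_RANGE[1]:
                best = (m1, m2)
                break
        if best:
            break
    if best is None:
        raise ModeFitError(
            "no pair of modes with a 4n/2n ratio in [1.7, 2.3]; "
            "supply gates manually")
    mode_2n, mode_4n = best

    def hwhm_sigma(mode: float) -> float:
        peak_dens = float(kde(mode)[0])
        half = peak_dens / 2.0
        # walk outward from the mode until density falls below half-maximum
        step = (hi - lo) / 2048.0
        left = mode
        while left > lo and float(kde(left)[0]) > half:
            left -= step
        right = mode
        while right < hi and float(kde(right)[0]) > half:
            right += step
        hwhm = (right - left) / 2.0
        return hwhm * HWHM_TO_SIGMA

    s2, s4 = hwhm_sigma(mode_2n), hwhm_sigma(mode_4n)
    divide = float(np.sqrt(mode_2n * mode_4n))
    g1 = (mode_2n - 3 * s2, min(mode_2n + 3 * s2, divide))
    g2m = (max(mode_4n - 3 * s4, divide), mode_4n + 3 * s4)
    return DnaGates(float(mode_2n), float(mode_4n), g1, g2m)


def edu_threshold_from_control(edu_negative: np.ndarray,
                               quantile: float = 0.995) -> float:
    """EdU positivity threshold: 99.5th percentile of an EdU- control."""
    edu_negative = np.asarray(edu_negative, dtype=float)
    if edu_negative.size == 0:
        raise ValueError("empty control sample")
    return float(np.quantile(edu_negative, quantile))


def edu_threshold_from_mixture(edu: np.ndarray) -> float:
    """Valley of the bimodal log-EdU distribution (two-class Otsu split)."""
    edu = np.asarray(edu, dtype=float)
    return float(np.exp(_otsu_scalar(np.log(edu))))


def classify_events(events: FacsEvents, gates: DnaGates,
                    edu_threshold: float) -> PhaseFractions:
    """Assign each event to G0/G1, S or G2/M and report percentages.

    S takes precedence (EdU above threshold); percentages are over
    classified events; unclassified counts are carried in the result.
    """
    dna = events.dna_intensity
    edu = events.edu_intensity
    s_mask = edu > edu_threshold
    g1_mask = (~s_mask) & (dna >= gates.g1_gate[0]) & (dna <= gates.g1_gate[1])
    g2_mask = (~s_mask) & (dna >= gates.g2m_gate[0]) & (dna <= gates.g2m_gate[1])
    n_s = int(s_mask.sum())
    n_g1 = int(g1_mask.sum())
    n_g2 = int(g2_mask.sum())
    n_classified = n_s + n_g1 + n_g2
    if n_classified == 0:
        raise ValueError("no events classified; check gates and threshold")
    n_unclassified = len(events) - n_classified
    return PhaseFractions(
        pct_g0g1=100.0 * n_g1 / n_classified,
        pct_s=100.0 * n_s / n_classified,
        pct_g2m=100.0 * n_g2 / n_classified,
        n_events=len(events),
        n_unclassified=n_unclassified,
    )
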