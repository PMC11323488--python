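"""Histogramming, smoothing, peak/valley detection, and the four-group
classification of species-level ANI distributions.

The analysis follows the ANI-gap recipe: bin pairwise intra-species ANI
values into 0.1%-wide bins on [95, 100] (51 bins), smooth the counts,
detect peaks and valleys in the smoothed series, and validate valleys by
requiring them to sit in a region of low pair frequency (smoothed count
below half the smoothed mean). Species distributions are then classified:

* group 2 — highly clonal, mean ANI above the clonal threshold (99.8%);
* group 1 — a validated valley inside the gap range (99.2-99.8%);
* group 4 — a peak (and no validated valley) inside the gap range;
* group 3 — neither: undetermined.

Bootstrapped subsampling to a fixed number of pairs per species, repeated
with fresh random subsets, yields per-bin peak/valley detection frequencies
and the deepest consistent valley across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.signal import find_peaks

from .types import AniPair, AniTable

DEFAULT_RANGE = (95.0, 100.0)
DEFAULT_BIN_WIDTH = 0.1
DEFAULT_GAP_RANGE = (99.2, 99.8)
DEFAULT_CLONAL_THRESHOLD = 99.8
LONG_READ_GAP_RANGE = (98.8, 99.5)
LONG_READ_CLONAL_THRESHOLD = 99.5


@dataclass
class SmootherSpec:
    """Which smoothing backend to use.

    ``method`` is "spline" (penalized cubic spline; the default) or
    "moving_average" (reflect-padded window mean; simple enough to verify
    by hand, used as the test oracle).

    ``lam`` is the spline roughness penalty, calibrated for the standard
    0.1%-wide ANI bins: the default 1e-3 damps bin-to-bin noise while
    preserving bimodal structure. ``lam=None`` selects the penalty by
    generalized cross-validation instead, which on spiky histograms tends
    to over-smooth and is therefore not the default.
    """

    method: str = "spline"
    window: int = 5  # moving_average only; must be odd
    lam: Optional[float] = 1e-3

    def __post_init__(self) -> None:
        if self.method not in ("spline", "moving_average"):
            raise ValueError(f"unknown smoothing method {self.method!r}")
        if self.method == "moving_average" and (self.window < 1 or self.window % 2 == 0):
            raise ValueError("moving-average window must be a positive odd integer")


@dataclass
class PeakParams:
    """Peak/valley detection settings.

    ``min_prominence_frac`` is expressed as a fraction of the maximum
    smoothed count; ``min_distance_bins`` is the minimum separation between
    reported extrema of the same kind.
    """

    min_prominence_frac: float = 0.02
    min_distance_bins: int = 2


@dataclass
class AniHistogram:
    """Counts (raw and optionally smoothed) over fixed-width ANI bins."""

    bin_centers: np.ndarray
    counts: np.ndarray
    smoothed: Optional[np.ndarray] = None
    width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        if len(self.bin_centers) != len(self.counts):
            raise ValueError("bin_centers and counts must have equal length")


@dataclass
class PeakValleyResult:
    positions: List[float]  # bin centers, ascending
    kinds: List[str]  # "peak" | "valley", parallel to positions
    prominences: List[float]

    def peaks(self) -> List[float]:
        return [p for p, k in zip(self.positions, self.kinds) if k == "peak"]

    def valleys(self) -> List[float]:
        return [p for p, k in zip(self.positions, self.kinds) if k == "valley"]


@dataclass
class SpeciesGroup:
    """Outcome of the four-group ANI-distribution classification."""

    group: int
    mean_ani: float
    validated_valleys_in_gap: List[float]
    gap_range: Tuple[float, float]
    peaks: List[float] = field(default_factory=list)
    valleys: List[float] = field(default_factory=list)


@dataclass
class BootstrapConsensus:
    bin_centers: np.ndarray
    peak_freq: np.ndarray
    valley_freq: np.ndarray
    mean_smoothed: np.ndarray
    reps: int
    deepest_consistent_valley: Optional[float]


def uniform_expectation(total_pairs: int, n_bins: int) -> float:
    """Pairs per bin if values were spread evenly over the bins."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    return total_pairs / n_bins


def build_histogram(
    anis: Sequence[float],
    range_low: float = DEFAULT_RANGE[0],
    range_high: float = DEFAULT_RANGE[1],
    width: float = DEFAULT_BIN_WIDTH,
) -> AniHistogram:
    """Bin ANI values by nearest bin center.

    Bin b is centered at ``range_low + b*width``; a value belongs to the
    half-open interval [center - width/2, center + width/2), with the upper
    edge closed at the final bin. Values outside the covered interval raise
    an error naming the offenders.
    """
    n_bins = int(round((range_high - range_low) / width)) + 1
    centers = range_low + width * np.arange(n_bins)
    vals = np.asarray(anis, dtype=float)
    counts = np.zeros(n_bins, dtype=int)
    if vals.size:
        idx = np.floor((vals - range_low) / width + 0.5 + 1e-9).astype(int)
        # final bin accepts its closed upper edge
        idx[np.isclose(vals, range_high + width / 2)] = n_bins - 1
        bad = (idx < 0) | (idx > n_bins - 1)
        if bad.any():
            offenders = vals[bad][:10].tolist()
            raise ValueError(
                f"{int(bad.sum())} ANI value(s) outside "
                f"[{range_low - width / 2}, {range_high + width / 2}]: {offenders}"
            )
        np.add.at(counts, idx, 1)
    return AniHistogram(bin_centers=centers, counts=counts, width=width)


def subsample_pairs(
    table: AniTable,
    species_of: Dict[str, str],
    per_species: int,
    seed: int,
) -> AniTable:
    """Subsample to the same number of pairs per species.

    A pair belongs to a species when both its genomes carry that label;
    cross-species pairs are ignored. Species with at least ``per_species``
    pairs contribute exactly that many, sampled without replacement;
    species with fewer are excluded entirely.
    """
    if per_species < 1:
        raise ValueError("per_species must be >= 1")
    by_species: Dict[str, List[AniPair]] = {}
    for p in table.pairs:
        sq, ss = species_of.get(p.query_id), species_of.get(p.subject_id)
        if sq is not None and sq == ss:
            by_species.setdefault(sq, []).append(p)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chosen: List[AniPair] = []
    for sp in sorted(by_species):
        pool = by_species[sp]
        if len(pool) < per_species:
            continue
        sel = rng.choice(len(pool), size=per_species, replace=False)
        chosen.extend(pool[i] for i in sorted(int(j) for j in sel))
    if not chosen:
        raise ValueError(
            f"no species has at least {per_species} pairs; nothing to subsample"
        )
    return AniTable(pairs=chosen)


def smooth_counts(hist: AniHistogram, smoother: Optional[SmootherSpec] = None) -> AniHistogram:
    """Fill ``hist.smoothed`` using the selected backend.

    Smoothed values are clamped at zero; a constant input series is
    preserved exactly.
    """
    if len(hist.counts) < 5:
        raise ValueError("smoothing requires at least 5 bins")
    smoother = smoother or SmootherSpec()
    y = hist.counts.astype(float)
    if np.allclose(y, y[0]):
        smoothed = y.copy()
    elif smoother.method == "moving_average":
        w = smoother.window
        pad = w // 2
        padded = np.pad(y, pad, mode="reflect")
        kernel = np.ones(w) / w
        smoothed = np.convolve(padded, kernel, mode="valid")
    else:
        x = hist.bin_centers
        spl = make_smoothing_spline(x, y, lam=smoother.lam)
        smoothed = spl(x)
    smoothed = np.maximum(smoothed, 0.0)
    return AniHistogram(
        bin_centers=hist.bin_centers, counts=hist.counts, smoothed=smoothed,
        width=hist.width,
    )


def detect_peaks_valleys(
    hist: AniHistogram, peak_params: Optional[PeakParams] = None
) -> PeakValleyResult:
    """Local maxima (peaks) and minima (valleys) of the smoothed series.

    Both kinds are found with the same prominence and distance settings;
    valleys are peaks of the negated series. Plateaus are reported once at
    their leftmost center bin.
    """
    if hist.smoothed is None:
        raise ValueError("histogram has no smoothed values; call smooth_counts first")
    pp = peak_params or PeakParams()
    s = hist.smoothed
    prom = pp.min_prominence_frac * float(np.max(s)) if np.max(s) > 0 else 0.0
    found: List[Tuple[float, str, float]] = []
    for kind, series in (("peak", s), ("valley", -s)):
        idx, props = find_peaks(
            series,
            prominence=max(prom, 1e-12),
            distance=max(pp.min_distance_bins, 1),
            plateau_size=(None, None),
        )
        for j, i in enumerate(idx):
            le, re = props["left_edges"][j], props["right_edges"][j]
            center = (le + re) // 2  # leftmost center bin of a plateau
            found.append(
                (float(hist.bin_centers[center]), kind, float(props["prominences"][j]))
            )
    found.sort(key=lambda t: t[0])
    return PeakValleyResult(
        positions=[t[0] for t in found],
        kinds=[t[1] for t in found],
        prominences=[t[2] for t in found],
    )


def validate_valleys(hist: AniHistogram, candidates: PeakValleyResult) -> List[float]:
    """Keep candidate valleys lying in an area of low pair frequency.

    A valley survives iff its smoothed count is below 0.5 x the mean of the
    smoothed series, i.e. it sits at the genuine bottom of the distribution.
    """
    if hist.smoothed is None:
        raise ValueError("histogram has no smoothed values")
    half_mean = 0.5 * float(np.mean(hist.smoothed))
    out = []
    for pos in candidates.valleys():
        i = int(np.argmin(np.abs(hist.bin_centers - pos)))
        if hist.smoothed[i] < half_mean:
            out.append(pos)
    return out


def bootstrap_gap(
    table: AniTable,
    species_of: Dict[str, str],
    reps: int = 1000,
    per_species: int = 150,
    seed: int = 0,
    smoother: Optional[SmootherSpec] = None,
    peak_params: Optional[PeakParams] = None,
    range_low: float = DEFAULT_RANGE[0],
    range_high: float = DEFAULT_RANGE[1],
    width: float = DEFAULT_BIN_WIDTH,
) -> BootstrapConsensus:
    """Bootstrap the subsample -> smooth -> detect -> validate chain.

    Each replicate subsamples ``per_species`` pairs per species with a
    fresh seed derived from ``seed``, and contributes its detected peaks
    and validated valleys to per-bin detection frequencies. The deepest
    consistent valley is the validated-valley bin with the highest
    frequency; ties break toward the lower replicate-averaged smoothed
    count, then toward lower ANI.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(reps) % (2**31)
    n_bins = int(round((range_high - range_low) / width)) + 1
    centers = range_low + width * np.arange(n_bins)
    peak_hits = np.zeros(n_bins)
    valley_hits = np.zeros(n_bins)
    smoothed_sum = np.zeros(n_bins)
    for r in range(reps):
        sub = subsample_pairs(table, species_of, per_species, int(child_seeds[r]))
        hist = build_histogram(sub.anis(), range_low, range_high, width)
        hist = smooth_counts(hist, smoother)
        pv = detect_peaks_valleys(hist, peak_params)
        valid = validate_valleys(hist, pv)
        smoothed_sum += hist.smoothed
        for pos in pv.peaks():
            peak_hits[int(np.argmin(np.abs(centers - pos)))] += 1
        for pos in valid:
            valley_hits[int(np.argmin(np.abs(centers - pos)))] += 1
    mean_smoothed = smoothed_sum / reps
    deepest = None
    if valley_hits.any():
        best = sorted(
            np.flatnonzero(valley_hits),
            key=lambda i: (-valley_hits[i], mean_smoothed[i], centers[i]),
        )[0]
        deepest = float(centers[best])
    return BootstrapConsensus(
        bin_centers=centers,
        peak_freq=peak_hits / reps,
        valley_freq=valley_hits / reps,
        mean_smoothed=mean_smoothed,
        reps=reps,
        deepest_consistent_valley=deepest,
    )


def classify_species(
    anis: Sequence[float],
    gap_range: Tuple[float, float] = DEFAULT_GAP_RANGE,
    clonal_threshold: float = DEFAULT_CLONAL_THRESHOLD,
    smoother: Optional[SmootherSpec] = None,
    peak_params: Optional[PeakParams] = None,
    range_low: float = DEFAULT_RANGE[0],
    range_high: float = DEFAULT_RANGE[1],
    width: float = DEFAULT_BIN_WIDTH,
) -> SpeciesGroup:
    """Assign a species' ANI distribution to one of the four groups.

    Precedence is fixed: group 2 (mean ANI above ``clonal_threshold``),
    then group 1 (validated valley inside ``gap_range``, inclusive), then
    group 4 (peak inside the range), else group 3. The mean is computed
    over all input values; the histogram covers [range_low, range_high]
    and values below that window are ignored for shape detection.
    """
    anis = [float(a) for a in anis]
    if len(anis) < 2:
        raise ValueError("classification requires at least 2 ANI values")
    mean_ani = float(np.mean(anis))
    lo, hi = gap_range
    in_window = [
        a for a in anis if range_low - width / 2 <= a <= range_high + width / 2
    ]
    peaks: List[float] = []
    valleys: List[float] = []
    validated: List[float] = []
    if len(in_window) >= 1:
        hist = build_histogram(in_window, range_low, range_high, width)
        hist = smooth_counts(hist, smoother)
        pv = detect_peaks_valleys(hist, peak_params)
        peaks, valleys = pv.peaks(), pv.valleys()
        validated = validate_valleys(hist, pv)
    eps = 1e-9
    valleys_in_gap = [v for v in validated if lo - eps <= v <= hi + eps]
    peaks_in_gap = [p for p in peaks if lo - eps <= p <= hi + eps]
    if mean_ani > clonal_threshold:
        group = 2
    elif valleys_in_gap:
        group = 1
    elif peaks_in_gap:
        group = 4
    else:
        group = 3
    return SpeciesGroup(
        group=group,
        mean_ani=mean_ani,
        validated_valleys_in_gap=valleys_in_gap,
        gap_range=gap_range,
        peaks=peaks,
        valleys=valleys,
    )
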