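"""Variant-label concordance analysis (SARS-CoV-2-style).

Workflow: discard genomes with undetermined positions (Ns), cap the number
of genomes per variant label, compute all-vs-all ANI, locate the
data-driven gap threshold (the least-populated interior ANI bin), and
measure how often pairs above/below that threshold share a variant label.
A clean gap shows nearly all above-threshold pairs sharing a label and
nearly none below it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .types import AniPair, GenomeSeq

DEFAULT_CONCORDANCE_BIN_WIDTH = 0.01


@dataclass
class ConcordanceResult:
    threshold: float
    frac_same_label_above: float
    frac_same_label_below: float
    n_above: int
    n_below: int


def filter_n_genomes(genomes: Sequence[GenomeSeq], max_n: int = 0) -> List[GenomeSeq]:
    """Retain genomes whose N count is at most ``max_n`` (default: none allowed)."""
    return [g for g in genomes if g.n_count <= max_n]


def subsample_per_label(
    genomes: Sequence[GenomeSeq], cap_per_label: int, seed: int
) -> List[GenomeSeq]:
    """Cap each variant label at ``cap_per_label`` genomes.

    Over-represented labels are sampled without replacement; smaller labels
    are kept whole. Genomes without a variant label raise an error.
    """
    by_label: Dict[str, List[GenomeSeq]] = {}
    for g in genomes:
        if g.variant_label is None:
            raise ValueError(f"genome {g.id!r} has no variant label")
        by_label.setdefault(g.variant_label, []).append(g)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out: List[GenomeSeq] = []
    for label in sorted(by_label):
        pool = by_label[label]
        if len(pool) <= cap_per_label:
            out.extend(pool)
        else:
            sel = rng.choice(len(pool), size=cap_per_label, replace=False)
            out.extend(pool[i] for i in sorted(int(j) for j in sel))
    return out


def find_gap_threshold(
    anis: Sequence[float],
    range_low: Optional[float] = None,
    range_high: Optional[float] = None,
    width: float = DEFAULT_CONCORDANCE_BIN_WIDTH,
) -> float:
    """ANI bin center with the fewest pairs, restricted to the occupied range.

    Bins outside [first, last] nonzero bin are excluded so empty edge bins
    can never win; ties break toward the lower ANI. The bin range defaults
    to the data's own span, snapped to the bin grid.
    """
    vals = np.asarray(anis, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot find a gap threshold in an empty ANI list")
    lo = range_low if range_low is not None else np.floor(vals.min() / width) * width
    hi = range_high if range_high is not None else np.ceil(vals.max() / width) * width
    n_bins = int(round((hi - lo) / width)) + 1
    centers = lo + width * np.arange(n_bins)
    idx = np.clip(np.floor((vals - lo) / width + 0.5 + 1e-9).astype(int), 0, n_bins - 1)
    counts = np.zeros(n_bins, dtype=int)
    np.add.at(counts, idx, 1)
    nz = np.flatnonzero(counts)
    interior = counts[nz[0] : nz[-1] + 1]
    if interior.size < 3:
        raise ValueError("ANI distribution too narrow to locate an interior minimum")
    best = int(np.argmin(interior)) + nz[0]  # argmin takes the first (lowest ANI) tie
    return float(centers[best])


def concordance(
    pairs: Sequence[AniPair],
    labels: Dict[str, str],
    threshold: float,
) -> ConcordanceResult:
    """Fraction of same-label pairs above and below an ANI threshold.

    "Above" is strict (ani > threshold). Every genome referenced by the
    pairs must be labeled; an unlabeled genome raises an error naming it.
    """
    same_above = same_below = n_above = n_below = 0
    for p in pairs:
        for gid in (p.query_id, p.subject_id):
            if gid not in labels:
                raise ValueError(f"genome {gid!r} has no variant label")
        same = labels[p.query_id] == labels[p.subject_id]
        if p.ani > threshold:
            n_above += 1
            same_above += same
        else:
            n_below += 1
            same_below += same
    return ConcordanceResult(
        threshold=threshold,
        frac_same_label_above=same_above / n_above if n_above else float("nan"),
        frac_same_label_below=same_below / n_below if n_below else float("nan"),
        n_above=n_above,
        n_below=n_below,
    )
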