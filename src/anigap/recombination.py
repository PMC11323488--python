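"""Reciprocal best-match genes, the F100 statistic, and the
no-recombination null band.

F100 is the fraction of reciprocal best-match (RBM) genes between a genome
pair whose nucleotide identity exceeds 99.8% — a proxy for recently
recombined genes, since point mutation alone rarely leaves whole genes
untouched between diverged genomes. Observed F100 values are compared
against an empirical quantile envelope (the null band) obtained by
simulating a population that evolves by point mutation only and measuring
its F100-vs-ANI cloud.

Per-pair gene classification follows the three-way scheme: a shared gene is
``recombinant`` (identity above the cutoff within the pair — cohesion),
``third_partner`` (below the cutoff in the pair but above it against some
other genome in the panel — diversification), or ``non_recombinant``
(below the cutoff everywhere — recent point mutation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

import edlib

from .alignment import GeneSet, align_genes
from .types import F100Point, Gene, RbmPair

IDENTITY_CUTOFF = 99.8
CANDIDATE_IDENTITY_FLOOR = 85.0  # below this, the k-mer shortlist is distrusted


def _nw_distance(a_masked_query: str, b_masked_subject: str, k: int = -1) -> int:
    return edlib.align(a_masked_query, b_masked_subject, mode="NW",
                       task="distance", k=k)["editDistance"]


def _best_hit(ga_idx: int, set_a: GeneSet, set_b: GeneSet,
              candidates: Sequence[int]) -> Optional[int]:
    """Index in B of the best match for gene ``ga_idx`` of A, or None.

    The best hit minimizes the global edit distance over both strands of
    each candidate (score = -edit distance); ties break by lexicographic
    gene id. When the shortlisted best stays below an identity floor (or
    no k-mer is shared), every gene in B is scanned so the true best is
    never missed.
    """
    a_masked = set_a.masked_fwd[ga_idx]
    a_len = len(set_a.genes[ga_idx].seq)

    def scan(indices: Iterable[int]) -> Tuple[Optional[int], int]:
        best_j, best_ed = None, -1
        for j in indices:
            for b_masked in (set_b.masked_fwd_subject[j], set_b.masked_rc_subject[j]):
                k = -1 if best_ed < 0 else best_ed  # allow ties for id tie-break
                ed = _nw_distance(a_masked, b_masked, k)
                if ed < 0:
                    continue
                if best_ed < 0 or ed < best_ed or (
                    ed == best_ed
                    and best_j is not None
                    and set_b.genes[j].gene_id < set_b.genes[best_j].gene_id
                ):
                    best_j, best_ed = j, ed
        return best_j, best_ed

    best_j, best_ed = scan(candidates)
    rough_identity = (
        100.0 * (1.0 - best_ed / max(a_len, 1)) if best_j is not None else -1.0
    )
    if best_j is None or rough_identity < CANDIDATE_IDENTITY_FLOOR:
        full_j, full_ed = scan(range(len(set_b.genes)))
        if full_j is not None and (best_j is None or full_ed <= best_ed):
            best_j, best_ed = full_j, full_ed
    return best_j


def _best_hits(set_a: GeneSet, set_b: GeneSet) -> Dict[int, int]:
    out: Dict[int, int] = {}
    for i in range(len(set_a.genes)):
        sf, sr = set_a.sampled_kmers[i]
        j = _best_hit(i, set_a, set_b, set_b.candidates(sf, sr))
        if j is not None:
            out[i] = j
    return out


def find_rbm_genes(genes_a, genes_b) -> List[RbmPair]:
    """Reciprocal best-match gene pairs between two genomes.

    A pair is retained iff each gene is the other's best match (both
    strands considered). Identity is computed over alignment columns of
    the global alignment, counting internal gaps as differences.
    ``genes_a``/``genes_b`` are sequences of :class:`~anigap.types.Gene`
    or prebuilt :class:`~anigap.alignment.GeneSet` objects (cheaper when
    the same genome appears in many pairs).
    """
    set_a = genes_a if isinstance(genes_a, GeneSet) else GeneSet(genes_a)
    set_b = genes_b if isinstance(genes_b, GeneSet) else GeneSet(genes_b)
    if not set_a.genes or not set_b.genes:
        raise ValueError("both gene lists must be non-empty")
    fwd = _best_hits(set_a, set_b)
    rev = _best_hits(set_b, set_a)
    rbms: List[RbmPair] = []
    for i, j in fwd.items():
        if rev.get(j) != i:
            continue
        aln = align_genes(set_a.genes[i].seq, set_b.genes[j].seq)
        rbms.append(
            RbmPair(
                gene_a=set_a.genes[i].gene_id,
                gene_b=set_b.genes[j].gene_id,
                identity=aln.identity,
                aln_length=aln.aln_length,
                mismatches=aln.edit_distance,
            )
        )
    rbms.sort(key=lambda r: (r.gene_a, r.gene_b))
    return rbms


def compute_f100(rbms: Sequence[RbmPair], identity_cutoff: float = IDENTITY_CUTOFF) -> float:
    """Fraction of RBM genes with identity strictly above the cutoff.

    Returns NaN for an empty input (no RBM genes: F100 undefined).
    """
    if not rbms:
        return math.nan
    hits = sum(1 for r in rbms if r.identity > identity_cutoff)
    return hits / len(rbms)


@dataclass
class NullBand:
    """Empirical per-ANI-bin quantile envelope of F100 under no recombination."""

    bin_centers: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    quantiles: Tuple[float, float]
    width: float
    n_points: np.ndarray  # points observed per bin before interpolation

    def bounds_at(self, ani: float) -> Optional[Tuple[float, float]]:
        i = int(round((ani - self.bin_centers[0]) / self.width))
        if i < 0 or i >= len(self.bin_centers):
            return None
        return float(self.lower[i]), float(self.upper[i])


def f100_points(
    genes_by_genome: Mapping[str, Sequence[Gene]],
    ani_by_pair: Mapping[Tuple[str, str], float],
    identity_cutoff: float = IDENTITY_CUTOFF,
    rbm_cache: Optional[Dict[Tuple[str, str], List[RbmPair]]] = None,
) -> List[F100Point]:
    """F100 for every unordered genome pair present in ``ani_by_pair``.

    ``ani_by_pair`` maps (id_a, id_b) with id_a < id_b to the symmetrized
    ANI (e.g. from AniTable.symmetrized()). Pairs whose RBM set is empty
    are skipped. ``rbm_cache`` (optional) collects the RBM lists computed.
    """
    gene_sets: Dict[str, GeneSet] = {}

    def get_set(gid: str) -> GeneSet:
        if gid not in gene_sets:
            gene_sets[gid] = GeneSet(genes_by_genome[gid])
        return gene_sets[gid]

    pts: List[F100Point] = []
    for (a, b), ani in sorted(ani_by_pair.items()):
        rbms = find_rbm_genes(get_set(a), get_set(b))
        if rbm_cache is not None:
            rbm_cache[(a, b)] = rbms
        if not rbms:
            continue
        pts.append(
            F100Point(
                genome_a=a,
                genome_b=b,
                f100=compute_f100(rbms, identity_cutoff),
                ani=ani,
                n_rbm=len(rbms),
            )
        )
    return pts


def build_null_band_from_points(
    points: Sequence[F100Point],
    quantiles: Tuple[float, float] = (0.025, 0.975),
    ani_bin_width: float = 0.1,
    min_points_per_bin: int = 5,
) -> NullBand:
    """Quantile envelope of an F100-vs-ANI cloud.

    Points are binned by ANI (nearest center); per-bin empirical quantiles
    form the band. Bins with fewer than ``min_points_per_bin`` points are
    linearly interpolated from the nearest adequately filled bins (edge
    bins are extended flat).
    """
    if len(points) < min_points_per_bin:
        raise ValueError(
            f"only {len(points)} F100 points; need at least {min_points_per_bin}"
        )
    anis = np.array([p.ani for p in points])
    f = np.array([p.f100 for p in points])
    lo_edge = math.floor(anis.min() / ani_bin_width) * ani_bin_width
    hi_edge = math.ceil(anis.max() / ani_bin_width) * ani_bin_width
    n_bins = int(round((hi_edge - lo_edge) / ani_bin_width)) + 1
    centers = lo_edge + ani_bin_width * np.arange(n_bins)
    idx = np.clip(
        np.floor((anis - lo_edge) / ani_bin_width + 0.5).astype(int), 0, n_bins - 1
    )
    lower = np.full(n_bins, np.nan)
    upper = np.full(n_bins, np.nan)
    n_pts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = f[idx == b]
        n_pts[b] = sel.size
        if sel.size >= min_points_per_bin:
            lower[b] = np.quantile(sel, quantiles[0])
            upper[b] = np.quantile(sel, quantiles[1])
    good = np.flatnonzero(~np.isnan(lower))
    if good.size == 0:
        raise ValueError("no ANI bin has enough F100 points to form the band")
    xi = np.arange(n_bins)
    lower = np.interp(xi, good, lower[good])
    upper = np.interp(xi, good, upper[good])
    return NullBand(
        bin_centers=centers,
        lower=lower,
        upper=upper,
        quantiles=quantiles,
        width=ani_bin_width,
        n_points=n_pts,
    )


def build_null_band(
    sim_params,
    quantiles: Tuple[float, float] = (0.025, 0.975),
    ani_bin_width: float = 0.1,
    fragment_len: int = 1000,
    min_report_ani: float = 90.0,
) -> Tuple[NullBand, List[F100Point]]:
    """Simulate a no-recombination population and build its F100 null band.

    Runs the population simulator with ``sim_params`` (which must have
    recombination disabled), computes the all-vs-all fragment ANI and the
    per-pair F100, and returns the per-ANI-bin quantile envelope together
    with the simulated points.
    """
    from .ani import all_vs_all_ani
    from .simulate import simulate_population

    if sim_params.recomb_rate != 0:
        raise ValueError("the null model requires recomb_rate == 0")
    pop = simulate_population(sim_params)
    table = all_vs_all_ani(
        pop.genomes, fragment_len=fragment_len, min_report_ani=min_report_ani
    )
    pts = f100_points(pop.genes, table.symmetrized())
    band = build_null_band_from_points(pts, quantiles, ani_bin_width)
    return band, pts


def compare_to_null(points: Sequence[F100Point], band: NullBand) -> List[str]:
    """Flag each point as above / inside / below the band (bounds closed).

    Points whose ANI falls outside the band's covered range are flagged
    ``uncovered`` rather than silently dropped.
    """
    flags = []
    for p in points:
        bounds = band.bounds_at(p.ani)
        if bounds is None:
            flags.append("uncovered")
        elif p.f100 > bounds[1]:
            flags.append("above")
        elif p.f100 < bounds[0]:
            flags.append("below")
        else:
            flags.append("inside")
    return flags


@dataclass
class GeneCategoryRecord:
    """Per-pair classification of one shared reference gene."""

    gene_id: str
    partner_genome: str
    category: str  # recombinant | third_partner | non_recombinant
    identity: float
    aln_length: int
    mismatches: int
    gene_length: int
    best_third_identity: Optional[float] = None


def classify_genes(
    reference_genes: Sequence[Gene],
    partner_genes: Sequence[Gene],
    panel: Mapping[str, Sequence[Gene]],
    identity_cutoff: float = IDENTITY_CUTOFF,
) -> Tuple[List[GeneCategoryRecord], List[str]]:
    """Three-way classification of the reference genes shared with a partner.

    Returns (records, unshared_gene_ids); the latter lists reference genes
    without an RBM in the partner. The panel holds the gene sets of every
    other genome in the collection and may be empty.
    """
    partner_id = partner_genes[0].genome_id if partner_genes else "partner"
    rbms = find_rbm_genes(reference_genes, partner_genes)
    rbm_by_ref = {r.gene_a: r for r in rbms}
    ref_by_id = {g.gene_id: g for g in reference_genes}
    # best identity of each reference gene against each panel genome's RBMs
    third_best: Dict[str, float] = {}
    for pid in sorted(panel):
        genes_p = panel[pid]
        if not genes_p:
            continue
        for r in find_rbm_genes(reference_genes, genes_p):
            if r.gene_a not in third_best or r.identity > third_best[r.gene_a]:
                third_best[r.gene_a] = r.identity
    records: List[GeneCategoryRecord] = []
    unshared: List[str] = []
    for g in reference_genes:
        r = rbm_by_ref.get(g.gene_id)
        if r is None:
            unshared.append(g.gene_id)
            continue
        third = third_best.get(g.gene_id)
        if r.identity > identity_cutoff:
            cat = "recombinant"
        elif third is not None and third > identity_cutoff:
            cat = "third_partner"
        else:
            cat = "non_recombinant"
        records.append(
            GeneCategoryRecord(
                gene_id=g.gene_id,
                partner_genome=partner_id,
                category=cat,
                identity=r.identity,
                aln_length=r.aln_length,
                mismatches=r.mismatches,
                gene_length=ref_by_id[g.gene_id].length,
                best_third_identity=third,
            )
        )
    return records, unshared


def cumulative_recombinant_curve(
    reference_genes: Sequence[Gene],
    ordered_partners: Sequence[Tuple[str, Sequence[Gene]]],
    identity_cutoff: float = IDENTITY_CUTOFF,
) -> pd.DataFrame:
    """Cumulative fraction of reference genes seen recombined as partners accrue.

    A reference gene counts as recombined once any processed partner shows
    an RBM with identity above the cutoff. Partners should be ordered by
    decreasing ANI to the reference (the caller decides). Returns a frame
    with columns partner, cumulative_fraction, newly_detected.
    """
    total = len(reference_genes)
    seen: set = set()
    rows = []
    for pid, genes_p in ordered_partners:
        new = 0
        for r in find_rbm_genes(reference_genes, genes_p):
            if r.identity > identity_cutoff and r.gene_a not in seen:
                seen.add(r.gene_a)
                new += 1
        rows.append(
            {
                "partner": pid,
                "cumulative_fraction": len(seen) / total,
                "newly_detected": new,
            }
        )
    return pd.DataFrame(rows)


def summarize_forces(
    records_by_pair: Mapping[Tuple[str, str], Sequence[GeneCategoryRecord]],
) -> pd.DataFrame:
    """Totals per category over a set of pairwise classifications.

    For each category (recombinant / third_partner / non_recombinant):
    number of gene records, summed reference-gene lengths, and summed
    alignment mismatches. The per-pair category counts always partition the
    shared genes of that pair.
    """
    if not records_by_pair:
        raise ValueError("no records to summarize")
    cats = ["recombinant", "third_partner", "non_recombinant"]
    acc = {c: {"n_genes": 0, "total_length": 0, "total_mismatches": 0} for c in cats}
    for recs in records_by_pair.values():
        for r in recs:
            acc[r.category]["n_genes"] += 1
            acc[r.category]["total_length"] += r.gene_length
            acc[r.category]["total_mismatches"] += r.mismatches
    return pd.DataFrame.from_dict(acc, orient="index").loc[cats]
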