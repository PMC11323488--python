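"""Fragment-based ANI computation and threshold clustering.

The approach mirrors the FastANI recipe — chop the query genome into
consecutive non-overlapping fragments (default 1 kbp), place each fragment
at its best location in the subject on either strand, and average the
percent identities of the fragments that map — but aligns every fragment
exactly instead of sketching, which makes results deterministic on
desk-scale inputs.

Clustering at an ANI threshold (95% for species / vOTUs, 99.5% for
genomovars) uses the mean of the two directed ANI values per genome pair
and, by default, single-linkage transitive closure.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence

import networkx as nx

from .alignment import QueryProfile, SubjectIndex, best_fragment_hit
from .types import AniPair, AniTable, GenomeSeq, check_unique_ids

DEFAULT_FRAGMENT_LEN = 1000
DEFAULT_MIN_FRAGMENT_IDENTITY = 80.0
DEFAULT_MIN_REPORT_ANI = 95.0


def fragment_genome(genome: GenomeSeq, fragment_len: int = DEFAULT_FRAGMENT_LEN) -> List[str]:
    """Cut a genome into consecutive non-overlapping fragments.

    A trailing remainder shorter than ``fragment_len`` is discarded, so the
    number of fragments is ``floor(length / fragment_len)``.
    """
    if fragment_len < 100:
        raise ValueError(f"fragment_len must be >= 100, got {fragment_len}")
    if genome.length < fragment_len:
        raise ValueError(
            f"genome {genome.id!r} is {genome.length} bp, shorter than the "
            f"fragment length {fragment_len} bp"
        )
    n = genome.length // fragment_len
    return [genome.seq[i * fragment_len : (i + 1) * fragment_len] for i in range(n)]


def compute_pair_ani(
    query: GenomeSeq,
    subject: GenomeSeq,
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
    min_fragment_identity: float = DEFAULT_MIN_FRAGMENT_IDENTITY,
    subject_index: Optional[SubjectIndex] = None,
    query_profile: Optional[QueryProfile] = None,
) -> AniPair:
    """Directed ANI of ``query`` against ``subject``.

    Each query fragment is aligned to its best-matching location in the
    subject (both strands); fragments whose best identity falls below
    ``min_fragment_identity`` are unmapped. ANI is the mean identity of
    mapped fragments and is NaN when nothing maps.

    A prebuilt ``subject_index`` / ``query_profile`` may be passed to
    amortize indexing across many comparisons of the same genomes.
    """
    frags = fragment_genome(query, fragment_len)
    if subject.length < fragment_len:
        raise ValueError(
            f"subject {subject.id!r} is {subject.length} bp, shorter than the "
            f"fragment length {fragment_len} bp"
        )
    idx = subject_index if subject_index is not None else SubjectIndex(subject.seq)
    prof = query_profile if query_profile is not None else QueryProfile(frags)
    identities = []
    for frag, entry in zip(frags, prof.fragments):
        hit = best_fragment_hit(
            frag, idx, min_fragment_identity, profile_entry=entry, stride=prof.stride
        )
        if hit is not None:
            identities.append(hit.identity)
    ani = sum(identities) / len(identities) if identities else math.nan
    return AniPair(
        query_id=query.id,
        subject_id=subject.id,
        ani=ani,
        fragments_mapped=len(identities),
        fragments_total=len(frags),
    )


def all_vs_all_ani(
    genomes: Sequence[GenomeSeq],
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
    min_fragment_identity: float = DEFAULT_MIN_FRAGMENT_IDENTITY,
    min_report_ani: float = DEFAULT_MIN_REPORT_ANI,
) -> AniTable:
    """Many-to-many directed ANI table with self-matches removed.

    Both directions are computed for every ordered pair; directions that map
    zero fragments or score below ``min_report_ani`` are excluded from the
    table (mirroring the reporting floor of the species-level analysis).
    """
    genomes = list(genomes)
    if len(genomes) < 2:
        raise ValueError("all_vs_all_ani requires at least 2 genomes")
    check_unique_ids(genomes)
    indexes = {g.id: SubjectIndex(g.seq) for g in genomes}
    profiles = {
        g.id: QueryProfile(fragment_genome(g, fragment_len)) for g in genomes
    }
    pairs: List[AniPair] = []
    for q in genomes:
        for s in genomes:
            if q.id == s.id:
                continue
            p = compute_pair_ani(
                q, s, fragment_len, min_fragment_identity,
                subject_index=indexes[s.id], query_profile=profiles[q.id],
            )
            if p.defined and p.ani >= min_report_ani:
                pairs.append(p)
    return AniTable(pairs=pairs, genome_ids={g.id for g in genomes})


def cluster_by_threshold(
    table: AniTable,
    threshold: float,
    linkage: str = "single",
) -> Dict[str, int]:
    """Partition genomes into clusters at an ANI threshold.

    With single-linkage (default), two genomes share a cluster iff they are
    connected by a path of pairs whose mean-of-both-directions ANI exceeds
    ``threshold`` — the transitive closure of the pairwise relation, so
    chains can join genomes whose direct ANI is below the threshold.
    The greedy-centroid alternative assigns each unclustered genome (in
    lexicographic order) as a centroid and attaches all unclustered genomes
    above the threshold to it, which never chains.

    Cluster ids are consecutive integers starting at 1, ordered by each
    cluster's lexicographically smallest member. Genomes without qualifying
    pairs become singletons.
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    if linkage not in ("single", "greedy"):
        raise ValueError(f"unknown linkage {linkage!r}")
    sym = table.symmetrized()
    ids = sorted(table.genome_ids)
    groups: List[List[str]]
    if linkage == "single":
        g = nx.Graph()
        g.add_nodes_from(ids)
        g.add_edges_from(k for k, v in sym.items() if v > threshold)
        groups = [sorted(c) for c in nx.connected_components(g)]
    else:
        edges: Dict[str, Dict[str, float]] = {i: {} for i in ids}
        for (a, b), v in sym.items():
            if v > threshold:
                edges[a][b] = v
                edges[b][a] = v
        assigned: Dict[str, int] = {}
        groups = []
        for gid in ids:
            if gid in assigned:
                continue
            members = [gid] + sorted(
                m for m in edges[gid] if m not in assigned
            )
            for m in members:
                assigned[m] = len(groups)
            groups.append(sorted(members))
    groups.sort(key=lambda ms: ms[0])
    return {m: i + 1 for i, ms in enumerate(groups) for m in ms}
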