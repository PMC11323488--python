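"""Core domain types shared across the toolkit.

All genomic coordinates are 0-based, half-open. ANI and identity values are
percentages in [0, 100]; fractions are in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

VALID_BASES = frozenset("ACGTN")


@dataclass
class GenomeSeq:
    """A named nucleotide sequence with optional species/variant labels.

    Parameters
    ----------
    id : str
        Unique identifier within a collection.
    seq : str
        Uppercase nucleotide string over {A, C, G, T, N}.
    species_label, variant_label : str, optional
        Ground-truth or user-supplied labels used by the gap-classification
        and concordance analyses.
    """

    id: str
    seq: str
    species_label: Optional[str] = None
    variant_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be a non-empty string")
        if len(self.seq) < 1:
            raise ValueError(f"genome {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def n_count(self) -> int:
        return self.seq.count("N")


@dataclass
class AniPair:
    """Directed fragment-based comparison of two genomes.

    ``ani`` is the mean percent identity of mapped query fragments; it is NaN
    when no fragment mapped (callers filter such pairs).
    ``shared_fraction`` = fragments_mapped / fragments_total, the fraction of
    the query genome recruited by the subject.
    """

    query_id: str
    subject_id: str
    ani: float
    fragments_mapped: int
    fragments_total: int

    def __post_init__(self) -> None:
        if self.fragments_total < 1:
            raise ValueError("fragments_total must be >= 1")
        if not 0 <= self.fragments_mapped <= self.fragments_total:
            raise ValueError("fragments_mapped out of range")
        if self.fragments_mapped == 0 and not math.isnan(self.ani):
            raise ValueError("ani must be NaN when no fragment mapped")

    @property
    def shared_fraction(self) -> float:
        return self.fragments_mapped / self.fragments_total

    @property
    def defined(self) -> bool:
        return self.fragments_mapped >= 1


@dataclass
class AniTable:
    """All-vs-all directed ANI comparisons with self-matches removed."""

    pairs: List[AniPair]
    genome_ids: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for p in self.pairs:
            if p.query_id == p.subject_id:
                raise ValueError(f"self-match retained for {p.query_id!r}")
        if not self.genome_ids:
            self.genome_ids = {p.query_id for p in self.pairs} | {
                p.subject_id for p in self.pairs
            }

    def __len__(self) -> int:
        return len(self.pairs)

    def anis(self) -> List[float]:
        return [p.ani for p in self.pairs]

    def symmetrized(self) -> Dict[Tuple[str, str], float]:
        """Mean-of-both-directions ANI per unordered pair.

        When only one direction is present (the other mapped zero fragments
        or fell below the reporting floor) the single value is used.
        """
        acc: Dict[Tuple[str, str], List[float]] = {}
        for p in self.pairs:
            key = (min(p.query_id, p.subject_id), max(p.query_id, p.subject_id))
            acc.setdefault(key, []).append(p.ani)
        return {k: sum(v) / len(v) for k, v in acc.items()}


@dataclass
class Gene:
    """A protein-coding (or other) gene located on a genome."""

    genome_id: str
    gene_id: str
    seq: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id!r}: bad coordinates")
        if self.end - self.start != len(self.seq):
            raise ValueError(f"gene {self.gene_id!r}: seq length != end - start")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RbmPair:
    """A reciprocal best-match gene pair between two genomes.

    ``mismatches`` counts edit operations (substitutions plus indels) of the
    global alignment; identity = 100 * (1 - mismatches / aln_length).
    """

    gene_a: str
    gene_b: str
    identity: float
    aln_length: int
    mismatches: int


@dataclass
class F100Point:
    """Per-genome-pair fraction of near-identical reciprocal best matches."""

    genome_a: str
    genome_b: str
    f100: float
    ani: float
    n_rbm: int


def check_unique_ids(genomes: Sequence[GenomeSeq]) -> None:
    seen: Set[str] = set()
    for g in genomes:
        if g.id in seen:
            raise ValueError(f"duplicate genome id {g.id!r}")
        seen.add(g.id)
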