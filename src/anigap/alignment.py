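"""Low-level pairwise alignment helpers built on edlib.

Fragment mapping uses an anchored search: exact k-mers sampled from the
fragment vote for candidate diagonals in the subject, and only the best
candidate windows are aligned (infix mode, both strands). When no anchor
is found, or the anchored hit stays below the identity floor, the whole
subject is scanned, so divergent or repeat-poor inputs still receive the
true best placement. Positions involving N always count as mismatches: N
is translated to distinct sentinel letters on the two sides before any
edlib call, so N never matches anything, not even another N.

K-mers are 2-bit encoded with numpy so genome-scale indexing stays cheap;
per-genome profiles (masked strings, k-mer integer arrays, k-mer position
index) are built once and reused across all pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")
# distinct sentinels so N never matches anything, including another N
_QUERY_N = str.maketrans("N", "!")
_SUBJECT_N = str.maketrans("N", "?")

ANCHOR_K = 13
ANCHOR_STRIDE = 48  # sampling stride of fragment k-mers used for voting
MAX_KMER_HITS = 50  # positions kept per k-mer; repeats beyond this are ignored
WINDOW_PAD = 60
MAX_CANDIDATE_OFFSETS = 3

_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _mask_query(seq: str) -> str:
    return seq.translate(_QUERY_N)


def _mask_subject(seq: str) -> str:
    return seq.translate(_SUBJECT_N)


def kmer_ints(seq: str, k: int = ANCHOR_K) -> np.ndarray:
    """2-bit packed k-mer integers at every position; -1 where the window has an N."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        win = codes[j : j + n]
        out = (out << 2) | np.where(win < 4, win, 0)
        bad |= win >= 4
    out[bad] = -1
    return out


@dataclass
class FragmentHit:
    """Best placement of a fragment on a subject genome."""

    identity: float  # percent over the fragment length
    edit_distance: int
    strand: str


class SubjectIndex:
    """Masked sequence plus a k-mer -> positions index (forward strand).

    Fragments are looked up on both their own strands against this single
    forward index, which covers reverse-complement placements.
    """

    def __init__(self, seq: str, k: int = ANCHOR_K):
        self.seq = seq
        self.masked = _mask_subject(seq)
        self.k = k
        index: Dict[int, List[int]] = {}
        for pos, km in enumerate(kmer_ints(seq, k)):
            if km < 0:
                continue
            hits = index.get(km)
            if hits is None:
                index[km] = [pos]
            elif len(hits) < MAX_KMER_HITS:
                hits.append(pos)
        self.index = index


class QueryProfile:
    """Per-query-genome precomputation shared across subjects.

    Holds masked fragment strings and sampled k-mer integers for both
    strands of every fragment.
    """

    def __init__(self, fragments: Sequence[str], k: int = ANCHOR_K,
                 stride: int = ANCHOR_STRIDE):
        self.fragments: List[Tuple[str, np.ndarray, str, np.ndarray]] = []
        for frag in fragments:
            rc = revcomp(frag)
            kf, kr = kmer_ints(frag, k), kmer_ints(rc, k)
            self.fragments.append(
                (
                    _mask_query(frag),
                    kf[::stride] if kf.size else kf,
                    _mask_query(rc),
                    kr[::stride] if kr.size else kr,
                )
            )
        self.stride = stride
        self.k = k


def _vote_offsets(sampled: np.ndarray, idx: SubjectIndex, stride: int) -> List[int]:
    """Candidate diagonal offsets ranked by k-mer anchor votes."""
    votes: Dict[int, int] = {}
    for i, km in enumerate(sampled):
        if km < 0:
            continue
        for spos in idx.index.get(int(km), ()):
            off = spos - i * stride
            votes[off] = votes.get(off, 0) + 1
    ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    return [off for off, _ in ranked[:MAX_CANDIDATE_OFFSETS]]


def _align_infix(frag_masked: str, subject_masked: str, max_ed: int) -> int:
    """Edit distance of the best infix placement, or -1 if above max_ed."""
    if max_ed < 0:
        return -1
    res = edlib.align(frag_masked, subject_masked, mode="HW", task="distance", k=max_ed)
    return res["editDistance"]


def best_fragment_hit(
    frag: str,
    idx: SubjectIndex,
    min_identity: float,
    profile_entry: Optional[Tuple[str, np.ndarray, str, np.ndarray]] = None,
    stride: int = ANCHOR_STRIDE,
) -> Optional[FragmentHit]:
    """Map one fragment to its best location in the subject (both strands).

    Returns None when the best alignment identity is below ``min_identity``.
    """
    flen = len(frag)
    if profile_entry is None:
        rc = revcomp(frag)
        kf, kr = kmer_ints(frag, idx.k), kmer_ints(rc, idx.k)
        profile_entry = (
            _mask_query(frag),
            kf[::stride] if kf.size else kf,
            _mask_query(rc),
            kr[::stride] if kr.size else kr,
        )
    fwd_masked, fwd_kmers, rc_masked, rc_kmers = profile_entry
    max_ed = int(flen * (1.0 - min_identity / 100.0))
    best_ed, best_strand = -1, "+"
    anchored = False
    for strand, masked, sampled in (
        ("+", fwd_masked, fwd_kmers),
        ("-", rc_masked, rc_kmers),
    ):
        for off in _vote_offsets(sampled, idx, stride):
            anchored = True
            lo = max(0, off - WINDOW_PAD)
            hi = min(len(idx.masked), off + flen + WINDOW_PAD)
            k = max_ed if best_ed < 0 else best_ed - 1
            ed = _align_infix(masked, idx.masked[lo:hi], k)
            if ed >= 0 and (best_ed < 0 or ed < best_ed):
                best_ed, best_strand = ed, strand
    if best_ed < 0 and not anchored:
        # no anchor anywhere: scan the full subject on both strands
        for strand, masked in (("+", fwd_masked), ("-", rc_masked)):
            k = max_ed if best_ed < 0 else best_ed - 1
            ed = _align_infix(masked, idx.masked, k)
            if ed >= 0 and (best_ed < 0 or ed < best_ed):
                best_ed, best_strand = ed, strand
    if best_ed < 0:
        return None
    identity = 100.0 * (1.0 - best_ed / flen)
    if identity < min_identity:
        return None
    return FragmentHit(identity=identity, edit_distance=best_ed, strand=best_strand)


@dataclass
class GlobalAlignment:
    """Global (NW) alignment summary between two gene sequences.

    ``score`` is the negated edit distance (unit costs), the quantity
    best-hit search maximizes; ``identity`` is computed over alignment
    columns, counting internal gaps as differences.
    """

    identity: float
    aln_length: int
    edit_distance: int
    score: int
    strand: str


def align_genes(seq_a: str, seq_b: str) -> GlobalAlignment:
    """Global alignment of two genes, best of the two strands of ``seq_b``."""
    a = _mask_query(seq_a)
    best: Optional[GlobalAlignment] = None
    for strand, b in (("+", seq_b), ("-", revcomp(seq_b))):
        k = -1 if best is None else best.edit_distance - 1
        res = edlib.align(a, _mask_subject(b), mode="NW", task="path", k=k)
        ed = res["editDistance"]
        if ed < 0:
            continue
        cols = _cigar_columns(res["cigar"], len(seq_a), len(seq_b))
        cand = GlobalAlignment(
            identity=100.0 * (1.0 - ed / cols) if cols else 0.0,
            aln_length=cols,
            edit_distance=ed,
            score=-ed,
            strand=strand,
        )
        if best is None or cand.edit_distance < best.edit_distance:
            best = cand
    assert best is not None
    return best


def _cigar_columns(cigar: Optional[str], len_a: int, len_b: int) -> int:
    if not cigar:
        return max(len_a, len_b)
    total, num = 0, ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            total += int(num)
            num = ""
    return total


class GeneSet:
    """Per-genome gene collection with cached masked strands and k-mer index."""

    def __init__(self, genes, k: int = ANCHOR_K, stride: int = 16):
        self.genes = list(genes)
        self.k = k
        self.stride = stride
        self.masked_fwd = [_mask_query(g.seq) for g in self.genes]
        self.masked_fwd_subject = [_mask_subject(g.seq) for g in self.genes]
        self.masked_rc_subject = [_mask_subject(revcomp(g.seq)) for g in self.genes]
        self.sampled_kmers: List[Tuple[np.ndarray, np.ndarray]] = []
        index: Dict[int, List[int]] = {}
        for j, g in enumerate(self.genes):
            kf = kmer_ints(g.seq, k)
            kr = kmer_ints(revcomp(g.seq), k)
            sf = kf[::stride] if kf.size else kf
            sr = kr[::stride] if kr.size else kr
            self.sampled_kmers.append((sf, sr))
            for km in np.unique(kf[kf >= 0]):
                hits = index.setdefault(int(km), [])
                if not hits or hits[-1] != j:
                    hits.append(j)
        self.index = index

    def candidates(self, sampled_fwd: np.ndarray, sampled_rc: np.ndarray,
                   max_candidates: int = 3) -> List[int]:
        votes: Dict[int, int] = {}
        for sampled in (sampled_fwd, sampled_rc):
            for km in sampled:
                if km < 0:
                    continue
                for j in self.index.get(int(km), ()):
                    votes[j] = votes.get(j, 0) + 1
        return sorted(votes, key=lambda j: (-votes[j], j))[:max_candidates]


def hamming_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of two equal-length sequences, N counted as mismatch."""
    if len(seq_a) != len(seq_b):
        raise ValueError("hamming_identity requires equal-length sequences")
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    mism = int(np.sum((a != b) | (a == ord("N")) | (b == ord("N"))))
    return 100.0 * (1.0 - mism / len(seq_a))
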