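"""Synthetic viral population generator.

Populations evolve from a single random ancestor by point mutation only
(the no-recombination null): the ancestor is a single replicon of ``n_genes``
genes (lengths Normal(gene_len_mean, gene_len_sd), truncated at 150 bp)
separated by short random intergenic spacers. Optional planted clusters
derive their own ancestors by Poisson-distributed substitutions from the
root, producing a bimodal pairwise-ANI distribution with a valley between
the within- and between-cluster modes. Gene-level recombination (whole-gene
replacement from a donor genome) and labeled variant collections with
optional N-masking are layered on top.

Every stochastic choice flows from a single integer seed, and every
mutation, deletion, and transfer is recorded in an event log that suffices
to replay each genome from the ancestor exactly.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .types import Gene, GenomeSeq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

MIN_GENE_LEN = 150
SPACER_LEN = 50
ACCESSORY_DELETION_P = 0.5


@dataclass
class SimParams:
    """Parameters of a simulated population.

    ``mu``/``sd`` give the per-genome substitution count as
    round(max(0, Normal(mu, sd))); ``core_ratio`` is the percentage of genes
    present in every genome (the rest are accessory, each independently
    deleted from each genome with probability 0.5); ``between_cluster_mu``
    is the mean substitution count separating each cluster ancestor from the
    root ancestor.
    """

    n_genomes: int = 100
    n_genes: int = 70
    gene_len_mean: float = 1000.0
    gene_len_sd: float = 200.0
    core_ratio: float = 90.0
    mu: float = 690.0
    sd: float = 150.0
    n_clusters: int = 1
    between_cluster_mu: float = 0.0
    recomb_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genomes < 1 or self.n_genes < 1:
            raise ValueError("n_genomes and n_genes must be >= 1")
        if self.mu < 0 or self.sd < 0:
            raise ValueError("mu and sd must be >= 0")
        if not 0 < self.core_ratio <= 100:
            raise ValueError("core_ratio must be in (0, 100]")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_clusters > 1 and self.between_cluster_mu <= 0:
            raise ValueError("between_cluster_mu must be > 0 when n_clusters > 1")
        if not 0 <= self.recomb_rate <= 1:
            raise ValueError("recomb_rate must be in [0, 1]")


@dataclass
class SimPopulation:
    """A simulated population with full ground truth."""

    genomes: List[GenomeSeq]
    genes: Dict[str, List[Gene]]  # genome_id -> genes, in genomic order
    cluster_labels: Dict[str, int]
    event_log: List[dict]
    params: Optional[SimParams] = None
    ancestor_seq: str = ""
    ancestor_genes: List[Gene] = field(default_factory=list)


def _random_seq_arr(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _arr_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _build_ancestor(
    rng: np.random.Generator, n_genes: int, gene_len_mean: float, gene_len_sd: float
) -> Tuple[np.ndarray, List[Tuple[str, int, int]]]:
    """Random ancestor replicon: genes with trailing spacers.

    Returns the sequence as a uint8 array and (gene_id, start, end) spans.
    """
    lengths = np.maximum(
        MIN_GENE_LEN, np.rint(rng.normal(gene_len_mean, gene_len_sd, n_genes))
    ).astype(int)
    parts, spans, pos = [], [], 0
    for i, glen in enumerate(lengths):
        parts.append(_random_seq_arr(rng, glen))
        spans.append((f"g{i:04d}", pos, pos + glen))
        pos += glen
        parts.append(_random_seq_arr(rng, SPACER_LEN))
        pos += SPACER_LEN
    return np.concatenate(parts), spans


def _substitute(
    rng: np.random.Generator, seq: np.ndarray, n_subs: int
) -> Tuple[np.ndarray, List[Tuple[int, str, str]]]:
    """Apply ``n_subs`` substitutions at distinct uniform sites."""
    seq = seq.copy()
    n_subs = min(n_subs, len(seq))
    sites = rng.choice(len(seq), size=n_subs, replace=False)
    events = []
    for pos in sorted(int(p) for p in sites):
        old = seq[pos]
        choices = _BASES[_BASES != old]
        new = choices[rng.integers(0, 3)]
        seq[pos] = new
        events.append((pos, chr(old), chr(new)))
    return seq, events


def simulate_population(params: SimParams) -> SimPopulation:
    """Simulate a (possibly clustered) population under the mutation-only model."""
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    ancestor, spans = _build_ancestor(
        rng, params.n_genes, params.gene_len_mean, params.gene_len_sd
    )
    event_log: List[dict] = []

    n_acc = int(round(params.n_genes * (100.0 - params.core_ratio) / 100.0))
    gene_ids = [gid for gid, _, _ in spans]
    accessory = set(
        rng.choice(params.n_genes, size=n_acc, replace=False).tolist()
    )
    accessory_ids = sorted(gene_ids[i] for i in accessory)
    event_log.append({"type": "accessory_set", "gene_ids": accessory_ids})

    cluster_ancestors: List[np.ndarray] = []
    for c in range(params.n_clusters):
        if params.n_clusters > 1:
            k = int(rng.poisson(params.between_cluster_mu))
            anc, subs = _substitute(rng, ancestor, k)
            event_log.append(
                {"type": "cluster_divergence", "cluster": c, "substitutions": subs}
            )
        else:
            anc = ancestor
        cluster_ancestors.append(anc)

    genomes: List[GenomeSeq] = []
    genes: Dict[str, List[Gene]] = {}
    cluster_labels: Dict[str, int] = {}
    for i in range(params.n_genomes):
        gid = f"G{i:04d}"
        cluster = i % params.n_clusters
        n_mut = int(round(max(0.0, rng.normal(params.mu, params.sd))))
        seq, subs = _substitute(rng, cluster_ancestors[cluster], n_mut)
        deleted = sorted(
            j for j in accessory if rng.random() < ACCESSORY_DELETION_P
        )
        seq_str, gene_list = _excise(seq, spans, deleted, gid)
        genomes.append(GenomeSeq(id=gid, seq=seq_str))
        genes[gid] = gene_list
        cluster_labels[gid] = cluster
        event_log.append(
            {
                "type": "genome",
                "genome_id": gid,
                "cluster": cluster,
                "substitutions": subs,
                "deleted_genes": [gene_ids[j] for j in deleted],
            }
        )
    return SimPopulation(
        genomes=genomes,
        genes=genes,
        cluster_labels=cluster_labels,
        event_log=event_log,
        params=params,
        ancestor_seq=_arr_to_str(ancestor),
        ancestor_genes=[
            Gene(genome_id="ancestor", gene_id=g, seq=_arr_to_str(ancestor[s:e]), start=s, end=e)
            for g, s, e in spans
        ],
    )


def _excise(
    seq: np.ndarray,
    spans: List[Tuple[str, int, int]],
    deleted: List[int],
    genome_id: str,
) -> Tuple[str, List[Gene]]:
    """Drop deleted genes (with their trailing spacer) and re-coordinate."""
    deleted_set = set(deleted)
    parts: List[np.ndarray] = []
    gene_list: List[Gene] = []
    pos = 0
    for j, (gid, s, e) in enumerate(spans):
        if j in deleted_set:
            continue
        chunk = seq[s : e + SPACER_LEN]
        parts.append(chunk)
        gene_list.append(
            Gene(
                genome_id=genome_id,
                gene_id=gid,
                seq=_arr_to_str(seq[s:e]),
                start=pos,
                end=pos + (e - s),
            )
        )
        pos += len(chunk)
    out = np.concatenate(parts) if parts else seq[:0]
    return _arr_to_str(out), gene_list


def replay_event_log(pop: SimPopulation) -> Dict[str, str]:
    """Rebuild every genome from the ancestor using only the event log.

    Used to verify event-log soundness: the returned sequences must equal
    ``pop.genomes`` exactly.
    """
    if pop.params is None:
        raise ValueError("population carries no parameters")
    ancestor = np.frombuffer(pop.ancestor_seq.encode(), dtype=np.uint8)
    spans = [(g.gene_id, g.start, g.end) for g in pop.ancestor_genes]
    id_to_idx = {gid: j for j, (gid, _, _) in enumerate(spans)}
    cluster_anc: Dict[int, np.ndarray] = {}
    rebuilt: Dict[str, np.ndarray] = {}
    meta: Dict[str, dict] = {}
    for ev in pop.event_log:
        if ev["type"] == "cluster_divergence":
            anc = ancestor.copy()
            for pos, _old, new in ev["substitutions"]:
                anc[pos] = ord(new)
            cluster_anc[ev["cluster"]] = anc
        elif ev["type"] == "genome":
            base = cluster_anc.get(ev["cluster"], ancestor)
            seq = base.copy()
            for pos, _old, new in ev["substitutions"]:
                seq[pos] = ord(new)
            rebuilt[ev["genome_id"]] = seq
            meta[ev["genome_id"]] = ev
    out: Dict[str, str] = {}
    for gid, seq in rebuilt.items():
        deleted = [id_to_idx[g] for g in meta[gid]["deleted_genes"]]
        seq_str, gene_list = _excise(seq, spans, deleted, gid)
        # replay any recombination events recorded for this genome
        gene_map = {g.gene_id: g for g in gene_list}
        transfers = [
            ev
            for ev in pop.event_log
            if ev["type"] == "recombination" and ev["recipient"] == gid
        ]
        if transfers:
            arr = bytearray(seq_str.encode())
            for ev in transfers:
                g = gene_map[ev["gene_id"]]
                arr[g.start : g.end] = ev["donor_seq"].encode()
            seq_str = arr.decode()
        out[gid] = seq_str
    return out


def apply_recombination(
    pop: SimPopulation,
    recomb_rate: float,
    donor_scope: str = "any",
    seed: int = 0,
) -> SimPopulation:
    """Transfer whole genes between genomes.

    Each gene of each genome is independently replaced, with probability
    ``recomb_rate``, by the homologous gene copied from a random donor in
    scope (``within`` = same cluster, ``between`` = different cluster,
    ``any``). Donor sequences are taken from the population as it was before
    this call, so transfers do not chain within one invocation.
    """
    if len(pop.genomes) < 2:
        raise ValueError("recombination requires at least 2 genomes")
    if donor_scope not in ("within", "between", "any"):
        raise ValueError(f"unknown donor_scope {donor_scope!r}")
    n_clusters = len(set(pop.cluster_labels.values()))
    if donor_scope == "between" and n_clusters < 2:
        raise ValueError("donor_scope='between' needs at least 2 clusters")
    if donor_scope == "within" and any(
        sum(1 for c in pop.cluster_labels.values() if c == cl) < 2
        for cl in set(pop.cluster_labels.values())
    ):
        raise ValueError("donor_scope='within' needs >= 2 genomes per cluster")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    # snapshot of donor gene sequences
    donor_genes: Dict[str, Dict[str, str]] = {
        gid: {g.gene_id: g.seq for g in gl} for gid, gl in pop.genes.items()
    }
    new_pop = SimPopulation(
        genomes=[replace(g) for g in pop.genomes],
        genes={gid: [replace(g) for g in gl] for gid, gl in pop.genes.items()},
        cluster_labels=dict(pop.cluster_labels),
        event_log=copy.deepcopy(pop.event_log),
        params=pop.params,
        ancestor_seq=pop.ancestor_seq,
        ancestor_genes=pop.ancestor_genes,
    )
    ids = [g.id for g in new_pop.genomes]
    for gi, genome in enumerate(new_pop.genomes):
        my_cluster = pop.cluster_labels[genome.id]
        arr = bytearray(genome.seq.encode())
        for gene in new_pop.genes[genome.id]:
            if rng.random() >= recomb_rate:
                continue
            pool = [
                d
                for d in ids
                if d != genome.id
                and gene.gene_id in donor_genes[d]
                and (
                    donor_scope == "any"
                    or (donor_scope == "within" and pop.cluster_labels[d] == my_cluster)
                    or (donor_scope == "between" and pop.cluster_labels[d] != my_cluster)
                )
            ]
            if not pool:
                continue
            donor = pool[rng.integers(0, len(pool))]
            dseq = donor_genes[donor][gene.gene_id]
            arr[gene.start : gene.end] = dseq.encode()
            gene.seq = dseq
            new_pop.event_log.append(
                {
                    "type": "recombination",
                    "recipient": genome.id,
                    "donor": donor,
                    "gene_id": gene.gene_id,
                    "donor_seq": dseq,
                }
            )
        new_pop.genomes[gi] = replace(genome, seq=arr.decode())
    return new_pop


def simulate_labeled_variants(
    n_labels: int,
    genomes_per_label: int,
    within_label_mu: float,
    between_label_mu: float,
    n_mask_fraction: float = 0.0,
    masked_genome_fraction: float = 0.5,
    genome_len: int = 30000,
    within_label_sd: float = 0.0,
    seed: int = 0,
) -> SimPopulation:
    """Labeled variant collection emulating VOC-style data.

    One ancestor per label diverges from a shared root by
    Poisson(``between_label_mu``) substitutions; members receive
    round(max(0, Normal(within_label_mu, within_label_sd))) substitutions.
    Optionally, ``n_mask_fraction`` of positions are replaced by N in
    ``masked_genome_fraction`` of the genomes, emulating low-quality
    consensus sequences. Masking draws from its own random stream, so the
    underlying genomes are identical across masked/unmasked runs with the
    same seed.
    """
    if n_labels < 2:
        raise ValueError("n_labels must be >= 2")
    if not 0 <= n_mask_fraction <= 1 or not 0 <= masked_genome_fraction <= 1:
        raise ValueError("mask fractions must be in [0, 1]")
    ss = np.random.SeedSequence(seed)
    rng_main, rng_mask = (np.random.default_rng(s) for s in ss.spawn(2))
    root = _random_seq_arr(rng_main, genome_len)
    event_log: List[dict] = []
    genomes: List[GenomeSeq] = []
    cluster_labels: Dict[str, int] = {}
    for li in range(n_labels):
        label = f"V{li}"
        k = int(rng_main.poisson(between_label_mu))
        anc, subs = _substitute(rng_main, root, k)
        event_log.append({"type": "label_divergence", "label": label, "substitutions": subs})
        for m in range(genomes_per_label):
            gid = f"{label}_{m:03d}"
            n_mut = int(round(max(0.0, rng_main.normal(within_label_mu, within_label_sd))))
            seq, gsubs = _substitute(rng_main, anc, n_mut)
            genomes.append(
                GenomeSeq(id=gid, seq=_arr_to_str(seq), variant_label=label)
            )
            cluster_labels[gid] = li
            event_log.append(
                {"type": "genome", "genome_id": gid, "cluster": li, "substitutions": gsubs,
                 "deleted_genes": []}
            )
    if n_mask_fraction > 0 and masked_genome_fraction > 0:
        n_masked = int(round(masked_genome_fraction * len(genomes)))
        masked_idx = rng_mask.choice(len(genomes), size=n_masked, replace=False)
        for i in sorted(int(j) for j in masked_idx):
            g = genomes[i]
            arr = bytearray(g.seq.encode())
            n_pos = int(round(n_mask_fraction * len(arr)))
            sites = rng_mask.choice(len(arr), size=n_pos, replace=False)
            for pos in sites:
                arr[pos] = ord("N")
            genomes[i] = replace(g, seq=arr.decode())
            event_log.append(
                {"type": "n_mask", "genome_id": g.id, "n_positions": n_pos}
            )
    return SimPopulation(
        genomes=genomes,
        genes={g.id: [] for g in genomes},
        cluster_labels=cluster_labels,
        event_log=event_log,
        params=None,
        ancestor_seq=_arr_to_str(root),
        ancestor_genes=[],
    )


def planted_gap_params(
    seed: int,
    target_between_ani: float = 98.8,
    n_genomes: int = 30,
    n_genes: int = 20,
) -> SimParams:
    """Parameters for a two-cluster population with a planted ANI valley.

    Within-cluster ANI lands near 99.9 (mu=10, sd=3 on a ~21 kbp genome)
    and between-cluster ANI near ``target_between_ani``, so the pairwise
    ANI distribution is bimodal with an empty stretch — the planted gap —
    between the modes. Cluster ancestors each diverge from the root, so
    the between-cluster substitution separation is ~2*(between_cluster_mu
    + mu); the divergence parameter is solved from the target ANI using
    the nominal genome length.
    """
    mu = 10.0
    nominal_len = n_genes * 1000 + n_genes * SPACER_LEN
    divergence = (100.0 - target_between_ani) / 100.0
    bcmu = max(1.0, (divergence * nominal_len - 2 * mu) / 2.0)
    return SimParams(
        n_genomes=n_genomes,
        n_genes=n_genes,
        gene_len_mean=1000.0,
        gene_len_sd=150.0,
        core_ratio=100.0,
        mu=mu,
        sd=3.0,
        n_clusters=2,
        between_cluster_mu=bcmu,
        seed=seed,
    )


def voc_like_variants(seed: int, n_mask_fraction: float = 0.0) -> SimPopulation:
    """Labeled collection emulating the scale of VOC-annotated genomes.

    Six variant labels on a 30 kbp genome, label ancestors ~35 substitutions
    from the root (label-pair separation ~70), members ~15 +/- 5 substitutions
    from their label ancestor. Same-label pairs then sit near 99.90% ANI and
    different-label pairs near 99.67%, leaving an empty stretch around 99.8%
    — a bimodal distribution whose least-populated interior bin is the
    data-driven variant threshold. ``n_mask_fraction`` > 0 additionally
    N-masks that fraction of positions in half of the genomes.
    """
    return simulate_labeled_variants(
        n_labels=6,
        genomes_per_label=10,
        within_label_mu=15.0,
        within_label_sd=5.0,
        between_label_mu=35.0,
        n_mask_fraction=n_mask_fraction,
        masked_genome_fraction=0.5,
        genome_len=30000,
        seed=seed,
    )


def expected_pairwise_ani(params: SimParams) -> float:
    """First-order closed-form pairwise ANI for a single-cluster population.

    Two genomes carry ~mu substitutions each at (almost surely) disjoint
    sites, so expected identity is 1 - 2*mu/L with L the realized ancestor
    length. Coincident hits are ignored; the value is clamped at 0.
    """
    params.validate()
    if params.n_clusters != 1 or params.recomb_rate != 0:
        raise ValueError("closed form requires n_clusters == 1 and recomb_rate == 0")
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    ancestor, _ = _build_ancestor(
        rng, params.n_genes, params.gene_len_mean, params.gene_len_sd
    )
    L = len(ancestor)
    val = 100.0 * (1.0 - 2.0 * params.mu / L)
    if val < 0:
        warnings.warn("mutation load exceeds genome length; ANI clamped at 0")
        return 0.0
    return val
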