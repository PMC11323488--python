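"""Readers and writers for the toolkit's plain-text formats.

FASTA goes through Biopython; tables are fixed-dialect TSV (tab separator,
'.' decimal, no quoting, one header row) so they round-trip exactly and
diff cleanly. Every writer can drop a JSON metadata sidecar recording the
parameters and seeds that produced the file.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from Bio import SeqIO

from .types import AniPair, AniTable, Gene, GenomeSeq

PathLike = Union[str, Path]

PAIR_HEADER = ["query", "subject", "ani", "fragments_mapped", "fragments_total"]
RBM_HEADER = ["gene_a", "gene_b", "identity", "aln_len", "mismatches"]


def read_fasta(path: PathLike) -> List[GenomeSeq]:
    """Read a multi-FASTA file into GenomeSeq records.

    Wrapped lines and CRLF endings are handled; sequences are uppercased.
    Duplicate ids, empty records, and empty files are errors.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out: List[GenomeSeq] = []
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        out.append(GenomeSeq(id=rec.id, seq=seq))
    return out


def write_fasta(genomes: Sequence[GenomeSeq], path: PathLike, wrap: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.seq), wrap):
                fh.write(g.seq[i : i + wrap] + "\n")


def read_gene_fasta(path: PathLike) -> Dict[str, List[Gene]]:
    """Read per-genome gene sequences from a FASTA with ``genomeID|geneID`` headers.

    Coordinates are not carried by this format; genes receive consecutive
    placeholder coordinates within their genome.
    """
    path = Path(path)
    genes: Dict[str, List[Gene]] = {}
    offsets: Dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(
                f"{path}: header {rec.id!r} is not of the form genomeID|geneID"
            )
        genome_id, gene_id = rec.id.split("|", 1)
        seq = str(rec.seq).upper()
        start = offsets.get(genome_id, 0)
        genes.setdefault(genome_id, []).append(
            Gene(genome_id=genome_id, gene_id=gene_id, seq=seq,
                 start=start, end=start + len(seq))
        )
        offsets[genome_id] = start + len(seq)
    if not genes:
        raise ValueError(f"{path}: no gene records found")
    return genes


def read_genes_from_gff(
    fasta_path: PathLike, gff_path: PathLike, feature_type: str = "CDS"
) -> Dict[str, List[Gene]]:
    """Extract gene sequences from a genome FASTA plus a GFF3 annotation.

    GFF3 coordinates are 1-based inclusive and are converted to 0-based
    half-open; minus-strand genes are reverse-complemented so ``Gene.seq``
    is always the coding-strand sequence. The record's ``ID`` attribute
    (or a positional fallback) names the gene.
    """
    from .alignment import revcomp

    genomes = {g.id: g.seq for g in read_fasta(fasta_path)}
    genes: Dict[str, List[Gene]] = {gid: [] for gid in genomes}
    counter = 0
    with Path(gff_path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{gff_path}:{lineno}: expected 9 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != feature_type:
                continue
            if seqid not in genomes:
                raise ValueError(f"{gff_path}:{lineno}: unknown sequence id {seqid!r}")
            s, e = int(start) - 1, int(end)
            gene_id = None
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    gene_id = item[3:]
                    break
            if gene_id is None:
                gene_id = f"gene{counter:05d}"
            counter += 1
            seq = genomes[seqid][s:e]
            if strand == "-":
                seq = revcomp(seq)
            genes[seqid].append(
                Gene(genome_id=seqid, gene_id=gene_id, seq=seq,
                     start=s, end=e, strand=strand if strand in "+-" else "+")
            )
    return genes


def write_gene_fasta(genes_by_genome: Mapping[str, Sequence[Gene]], path: PathLike) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for genome_id in sorted(genes_by_genome):
            for g in genes_by_genome[genome_id]:
                fh.write(f">{genome_id}|{g.gene_id}\n{g.seq}\n")


def write_pair_table(table: AniTable, path: PathLike) -> None:
    """Write the directed ANI pair table (FastANI-like column order)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(PAIR_HEADER) + "\n")
        for p in table.pairs:
            ani = "NA" if math.isnan(p.ani) else f"{p.ani:.6f}"
            fh.write(
                f"{p.query_id}\t{p.subject_id}\t{ani}\t"
                f"{p.fragments_mapped}\t{p.fragments_total}\n"
            )


def read_pair_table(path: PathLike) -> AniTable:
    """Read a pair table written by :func:`write_pair_table`.

    Malformed lines raise an error naming the 1-based line number.
    """
    path = Path(path)
    pairs: List[AniPair] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\r\n")
        if header.split("\t") != PAIR_HEADER:
            raise ValueError(f"{path}:1: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            try:
                ani = math.nan if fields[2] == "NA" else float(fields[2])
                mapped, total = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            pairs.append(
                AniPair(
                    query_id=fields[0], subject_id=fields[1], ani=ani,
                    fragments_mapped=mapped, fragments_total=total,
                )
            )
    return AniTable(pairs=pairs)


def read_labels(path: PathLike) -> Dict[str, Tuple[Optional[str], Optional[str]]]:
    """Read a label TSV with header ``genome_id<TAB>species<TAB>variant``.

    Missing fields may be left empty; returns genome_id -> (species, variant).
    """
    path = Path(path)
    out: Dict[str, Tuple[Optional[str], Optional[str]]] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if header[:1] != ["genome_id"]:
            raise ValueError(f"{path}:1: expected header starting with 'genome_id'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 1:
                raise ValueError(f"{path}:{lineno}: empty line")
            gid = fields[0]
            species = fields[1] if len(fields) > 1 and fields[1] else None
            variant = fields[2] if len(fields) > 2 and fields[2] else None
            if gid in out:
                raise ValueError(f"{path}:{lineno}: duplicate genome id {gid!r}")
            out[gid] = (species, variant)
    return out


def write_labels(
    labels: Mapping[str, Tuple[Optional[str], Optional[str]]], path: PathLike
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("genome_id\tspecies\tvariant\n")
        for gid in sorted(labels):
            sp, var = labels[gid]
            fh.write(f"{gid}\t{sp or ''}\t{var or ''}\n")


def write_clusters(clusters: Mapping[str, int], path: PathLike) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("genome_id\tcluster_id\n")
        for gid in sorted(clusters):
            fh.write(f"{gid}\t{clusters[gid]}\n")


def write_metadata(path: PathLike, **payload) -> None:
    """Drop a JSON sidecar (``<path>.meta.json``) describing how a file was made."""
    path = Path(path)
    side = path.with_name(path.name + ".meta.json")
    with side.open("w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
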