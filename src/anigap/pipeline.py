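"""End-to-end workflows binding the analysis stages together.

Two workflows are provided: ``gap`` (all-vs-all ANI -> subsampled
bootstrap valley consensus -> four-group classification -> genomovar
clustering) and ``mechanism`` (genes -> reciprocal best matches -> F100 ->
no-recombination null band -> per-gene classification -> cumulative
recombinant curves). Each stage writes its artifact as TSV/JSON plus a
metadata sidecar carrying the seeds and parameters that produced it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from . import io
from .ani import all_vs_all_ani, cluster_by_threshold
from .gap import (
    SmootherSpec,
    bootstrap_gap,
    classify_species,
)
from .recombination import (
    build_null_band,
    classify_genes,
    compare_to_null,
    cumulative_recombinant_curve,
    f100_points,
)
from .simulate import SimParams

logger = logging.getLogger("anigap")


@dataclass
class RunConfig:
    """Parameters for :func:`run_pipeline`; unknown keys are rejected."""

    fasta: Optional[str] = None
    labels: Optional[str] = None
    genes_fasta: Optional[str] = None
    out_dir: str = "anigap_out"
    fragment_len: int = 1000
    min_fragment_identity: float = 80.0
    min_report_ani: float = 95.0
    species_threshold: float = 95.0
    genomovar_threshold: float = 99.5
    linkage: str = "single"
    gap_range: Tuple[float, float] = (99.2, 99.8)
    clonal_threshold: float = 99.8
    bootstrap_reps: int = 100
    per_species: int = 150
    smoother: str = "spline"
    identity_cutoff: float = 99.8
    null_sim: Optional[dict] = None  # SimParams overrides for the null band
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.gap_range, list):
            cfg.gap_range = tuple(cfg.gap_range)
        return cfg

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RunConfig":
        with Path(path).open() as fh:
            return cls.from_dict(json.load(fh))


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: RunConfig, workflow: str) -> Dict[str, Path]:
    """Run a named workflow; returns the artifact paths written.

    A stage failure propagates as an exception whose message names the
    stage (the CLI converts this to a nonzero exit status).
    """
    if workflow not in ("gap", "mechanism"):
        raise ValueError(f"unknown workflow {workflow!r}")
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.fasta is None:
        raise ValueError("config.fasta is required")
    artifacts: Dict[str, Path] = {}
    common_meta = dict(workflow=workflow, seed=config.seed,
                       config=dataclasses.asdict(config))

    try:
        _stage("read input")
        genomes = io.read_fasta(config.fasta)
        labels = io.read_labels(config.labels) if config.labels else {}
        species_of = {g: sp for g, (sp, _v) in labels.items() if sp is not None}

        _stage("all-vs-all ANI")
        table = all_vs_all_ani(
            genomes,
            fragment_len=config.fragment_len,
            min_fragment_identity=config.min_fragment_identity,
            min_report_ani=config.min_report_ani,
        )
        pair_path = out / "pairs.tsv"
        io.write_pair_table(table, pair_path)
        io.write_metadata(pair_path, **common_meta)
        artifacts["pairs"] = pair_path
    except Exception as exc:
        raise RuntimeError(f"[ani] stage failed: {exc}") from exc

    if workflow == "gap":
        return _run_gap(config, table, species_of, out, common_meta, artifacts)
    return _run_mechanism(config, genomes, table, out, common_meta, artifacts)


def _run_gap(config, table, species_of, out, meta, artifacts):
    smoother = SmootherSpec(method=config.smoother)
    if not species_of:
        # single unlabeled collection: treat it as one species
        species_of = {gid: "all" for gid in table.genome_ids}
    try:
        _stage("bootstrap valley consensus")
        boots = bootstrap_gap(
            table, species_of,
            reps=config.bootstrap_reps, per_species=config.per_species,
            seed=config.seed, smoother=smoother,
        )
        bpath = out / "bootstrap_consensus.tsv"
        with bpath.open("w") as fh:
            fh.write("bin_center\tpeak_freq\tvalley_freq\n")
            for c, pf, vf in zip(boots.bin_centers, boots.peak_freq, boots.valley_freq):
                fh.write(f"{c:.1f}\t{pf:.4f}\t{vf:.4f}\n")
        io.write_metadata(bpath, **meta, deepest_valley=boots.deepest_consistent_valley)
        artifacts["bootstrap"] = bpath
    except Exception as exc:
        raise RuntimeError(f"[bootstrap] stage failed: {exc}") from exc

    try:
        _stage("classify species")
        sym = table.symmetrized()
        by_species: Dict[str, List[float]] = {}
        for (a, b), ani in sym.items():
            sp = species_of.get(a)
            if sp is not None and sp == species_of.get(b):
                by_species.setdefault(sp, []).append(ani)
        cpath = out / "species_groups.tsv"
        with cpath.open("w") as fh:
            fh.write("species\tgroup\tmean_ani\tvalleys\tpeaks\n")
            for sp in sorted(by_species):
                res = classify_species(
                    by_species[sp], gap_range=config.gap_range,
                    clonal_threshold=config.clonal_threshold, smoother=smoother,
                )
                fh.write(
                    f"{sp}\t{res.group}\t{res.mean_ani:.4f}\t"
                    f"{','.join(f'{v:.1f}' for v in res.valleys)}\t"
                    f"{','.join(f'{p:.1f}' for p in res.peaks)}\n"
                )
        io.write_metadata(cpath, **meta)
        artifacts["species_groups"] = cpath

        _stage("genomovar clustering")
        gv = cluster_by_threshold(table, config.genomovar_threshold, config.linkage)
        gpath = out / "genomovars.tsv"
        io.write_clusters(gv, gpath)
        io.write_metadata(gpath, **meta, threshold=config.genomovar_threshold)
        artifacts["genomovars"] = gpath
    except Exception as exc:
        raise RuntimeError(f"[classify] stage failed: {exc}") from exc
    return artifacts


def _run_mechanism(config, genomes, table, out, meta, artifacts):
    try:
        _stage("gene input")
        if config.genes_fasta is None:
            raise ValueError("mechanism workflow requires config.genes_fasta")
        genes = io.read_gene_fasta(config.genes_fasta)
    except Exception as exc:
        raise RuntimeError(f"[genes] stage failed: {exc}") from exc

    try:
        _stage("F100 points")
        sym = table.symmetrized()
        sym = {k: v for k, v in sym.items() if k[0] in genes and k[1] in genes}
        pts = f100_points(genes, sym, identity_cutoff=config.identity_cutoff)
        fpath = out / "f100.tsv"
        with fpath.open("w") as fh:
            fh.write("genome_a\tgenome_b\tf100\tani\tn_rbm\n")
            for p in pts:
                fh.write(f"{p.genome_a}\t{p.genome_b}\t{p.f100:.4f}\t{p.ani:.4f}\t{p.n_rbm}\n")
        io.write_metadata(fpath, **meta)
        artifacts["f100"] = fpath
    except Exception as exc:
        raise RuntimeError(f"[f100] stage failed: {exc}") from exc

    try:
        _stage("null band")
        overrides = dict(config.null_sim or {})
        overrides.setdefault("seed", config.seed)
        params = SimParams(**overrides)
        band, _null_pts = build_null_band(params)
        npath = out / "null_band.json"
        with npath.open("w") as fh:
            json.dump(
                {
                    "bin_centers": band.bin_centers.tolist(),
                    "lower": band.lower.tolist(),
                    "upper": band.upper.tolist(),
                    "quantiles": list(band.quantiles),
                    "width": band.width,
                    "sim_params": dataclasses.asdict(params),
                },
                fh, indent=2,
            )
            fh.write("\n")
        io.write_metadata(npath, **meta)
        artifacts["null_band"] = npath

        _stage("compare to null")
        flags = compare_to_null(pts, band)
        opath = out / "f100_flags.tsv"
        with opath.open("w") as fh:
            fh.write("genome_a\tgenome_b\tf100\tani\tflag\n")
            for p, fl in zip(pts, flags):
                fh.write(f"{p.genome_a}\t{p.genome_b}\t{p.f100:.4f}\t{p.ani:.4f}\t{fl}\n")
        io.write_metadata(opath, **meta)
        artifacts["f100_flags"] = opath
    except Exception as exc:
        raise RuntimeError(f"[null-band] stage failed: {exc}") from exc

    try:
        _stage("gene classification + cumulative curve")
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        ref_id = sorted(genes)[int(rng.integers(0, len(genes)))]
        ani_to_ref = {}
        for (a, b), ani in sym.items():
            if a == ref_id:
                ani_to_ref[b] = ani
            elif b == ref_id:
                ani_to_ref[a] = ani
        partners = sorted(ani_to_ref, key=lambda g: (-ani_to_ref[g], g))
        recs_by_pair = {}
        for pid in partners:
            panel = {g: genes[g] for g in genes if g not in (ref_id, pid)}
            recs, _unshared = classify_genes(
                genes[ref_id], genes[pid], panel, config.identity_cutoff
            )
            recs_by_pair[(ref_id, pid)] = recs
        cat_path = out / "gene_categories.tsv"
        with cat_path.open("w") as fh:
            fh.write("reference\tpartner\tgene_id\tcategory\tidentity\tbest_third_identity\n")
            for (r, p), recs in recs_by_pair.items():
                for rec in recs:
                    third = "" if rec.best_third_identity is None else f"{rec.best_third_identity:.4f}"
                    fh.write(f"{r}\t{p}\t{rec.gene_id}\t{rec.category}\t{rec.identity:.4f}\t{third}\n")
        io.write_metadata(cat_path, **meta, reference=ref_id)
        artifacts["gene_categories"] = cat_path

        curve = cumulative_recombinant_curve(
            genes[ref_id], [(p, genes[p]) for p in partners], config.identity_cutoff
        )
        curve_path = out / "cumulative_curve.tsv"
        curve.to_csv(curve_path, sep="\t", index=False)
        io.write_metadata(curve_path, **meta, reference=ref_id)
        artifacts["curve"] = curve_path
    except Exception as exc:
        raise RuntimeError(f"[classify-genes] stage failed: {exc}") from exc
    return artifacts
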