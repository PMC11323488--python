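"""Reciprocal best matches, F100, the null band, and gene classification."""

from __future__ import annotations

import math

import numpy as np
import pytest
from Bio import Align

import anigap as ag
from anigap.types import Gene
from conftest import BASES, mutate


def make_gene(rng, genome_id, gene_id, length=300, seq=None):
    if seq is None:
        seq = "".join(rng.choice(BASES, size=length))
    return Gene(genome_id=genome_id, gene_id=gene_id, seq=seq, start=0, end=len(seq))


def biopython_best_hits(genes_a, genes_b):
    """Independent oracle: all-vs-all global alignment with Bio.Align,
    best hit per gene by score (both strands), then the reciprocity rule."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    comp = str.maketrans("ACGT", "TGCA")

    def best(src, dst):
        out = {}
        for i, ga in enumerate(src):
            scored = []
            for j, gb in enumerate(dst):
                sc = max(aligner.score(ga.seq, gb.seq),
                         aligner.score(ga.seq, gb.seq.translate(comp)[::-1]))
                scored.append((sc, -ord(gb.gene_id[-1]), j))
            scored.sort(reverse=True)
            out[i] = scored[0][2]
        return out

    fwd, rev = best(genes_a, genes_b), best(genes_b, genes_a)
    return {(i, j) for i, j in fwd.items() if rev[j] == i}


class TestFindRbm:
    def test_identical_gene_sets(self, rng):
        a = [make_gene(rng, "A", f"g{i}") for i in range(5)]
        b = [Gene(genome_id="B", gene_id=g.gene_id, seq=g.seq, start=0, end=len(g.seq))
             for g in a]
        rbms = ag.find_rbm_genes(a, b)
        assert len(rbms) == 5
        assert all(r.identity == 100.0 and r.mismatches == 0 for r in rbms)
        assert all(r.gene_a == r.gene_b for r in rbms)

    def test_gene_without_homolog_absent(self, rng):
        a = [make_gene(rng, "A", "g0"), make_gene(rng, "A", "orphan")]
        b = [Gene(genome_id="B", gene_id="g0", seq=a[0].seq, start=0, end=len(a[0].seq))]
        rbms = ag.find_rbm_genes(a, b)
        assert [r.gene_a for r in rbms] == ["g0"]

    def test_reverse_complement_homolog_found(self, rng):
        g = make_gene(rng, "A", "g0")
        comp = str.maketrans("ACGT", "TGCA")
        b = [Gene(genome_id="B", gene_id="g0", seq=g.seq.translate(comp)[::-1],
                  start=0, end=len(g.seq))]
        rbms = ag.find_rbm_genes([g], b)
        assert len(rbms) == 1 and rbms[0].identity == 100.0

    def test_chimera_excluded_by_reciprocity(self, rng):
        """A chimeric gene whose best hit is not reciprocal is dropped;
        checked against a Bio.Align all-vs-all oracle."""
        x = make_gene(rng, "A", "ga1", 300)
        y = make_gene(rng, "A", "ga2", 300)
        z = make_gene(rng, "A", "ga3", 300)
        genes_a = [x, y, z]
        # B carries near-copies of x and y, plus a chimera of x and y that
        # best-matches x's copy but is nobody's best partner reciprocally
        bx = Gene(genome_id="B", gene_id="gb1", seq=mutate(rng, x.seq, 2), start=0, end=300)
        by = Gene(genome_id="B", gene_id="gb2", seq=mutate(rng, y.seq, 2), start=0, end=300)
        chim = Gene(genome_id="B", gene_id="gb3", seq=x.seq[:200] + y.seq[200:],
                    start=0, end=300)
        genes_b = [bx, by, chim]
        rbms = ag.find_rbm_genes(genes_a, genes_b)
        got = {(r.gene_a, r.gene_b) for r in rbms}
        oracle = biopython_best_hits(genes_a, genes_b)
        expected = {(genes_a[i].gene_id, genes_b[j].gene_id) for i, j in oracle}
        assert got == expected
        assert ("ga3", "gb3") not in got  # chimera not reciprocal

    def test_reciprocity_oracle_on_population(self, small_population):
        """Every reported RBM pair survives a brute-force all-vs-all check."""
        a = small_population.genes["G0000"]
        b = small_population.genes["G0001"]
        got = {(r.gene_a, r.gene_b) for r in ag.find_rbm_genes(a, b)}
        oracle = biopython_best_hits(a, b)
        expected = {(a[i].gene_id, b[j].gene_id) for i, j in oracle}
        assert got == expected

    def test_empty_input_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            ag.find_rbm_genes([], [make_gene(rng, "B", "g0")])


class TestComputeF100:
    def _rbm(self, identity):
        return ag.RbmPair(gene_a="a", gene_b="b", identity=identity,
                          aln_length=300, mismatches=0)

    def test_all_identical(self):
        assert ag.compute_f100([self._rbm(100.0)] * 4) == 1.0

    def test_all_below_cutoff(self):
        # one mismatch in a 300 bp gene: 99.67% < 99.8%
        assert ag.compute_f100([self._rbm(100 * 299 / 300)] * 3) == 0.0

    def test_counting(self):
        rbms = [self._rbm(99.9)] * 7 + [self._rbm(99.0)] * 3
        assert ag.compute_f100(rbms) == pytest.approx(0.7)

    def test_cutoff_is_strict(self):
        assert ag.compute_f100([self._rbm(99.8)]) == 0.0

    def test_empty_is_nan(self):
        assert math.isnan(ag.compute_f100([]))

    def test_self_pair_is_exactly_one(self, small_population):
        genes = small_population.genes["G0000"]
        copies = [Gene(genome_id="X", gene_id=g.gene_id, seq=g.seq,
                       start=g.start, end=g.end) for g in genes]
        assert ag.compute_f100(ag.find_rbm_genes(genes, copies)) == 1.0


class TestNullBand:
    def test_degenerate_clonal_band(self):
        p = ag.SimParams(n_genomes=6, n_genes=6, core_ratio=100, mu=0, sd=0, seed=1)
        band, pts = ag.build_null_band(p, min_report_ani=90.0)
        assert all(pt.ani == 100.0 and pt.f100 == 1.0 for pt in pts)
        assert np.allclose(band.lower, 1.0) and np.allclose(band.upper, 1.0)

    def test_determinism(self):
        p = ag.SimParams(n_genomes=8, n_genes=8, core_ratio=100, mu=40, sd=10, seed=6)
        b1, _ = ag.build_null_band(p, min_report_ani=90.0)
        b2, _ = ag.build_null_band(p, min_report_ani=90.0)
        assert np.array_equal(b1.lower, b2.lower)
        assert np.array_equal(b1.upper, b2.upper)

    def test_rejects_recombination_enabled(self):
        p = ag.SimParams(recomb_rate=0.1, seed=0)
        with pytest.raises(ValueError, match="recomb_rate"):
            ag.build_null_band(p)

    def test_self_coverage_of_own_band(self):
        """~95% of a no-recombination population's pairs sit inside its own
        95% band (closed bounds make this >= the nominal level)."""
        p = ag.SimParams(n_genomes=14, n_genes=12, gene_len_mean=800,
                         core_ratio=100, mu=40, sd=15, seed=13)
        band, pts = ag.build_null_band(p, min_report_ani=90.0)
        flags = ag.compare_to_null(pts, band)
        inside = flags.count("inside") / len(flags)
        assert inside >= 0.90

    def test_boundary_point_is_inside(self):
        band = ag.build_null_band_from_points(
            [ag.F100Point("a", "b", f, 99.0, 10) for f in np.linspace(0, 1, 21)],
        )
        lo, hi = band.bounds_at(99.0)
        flags = ag.compare_to_null(
            [ag.F100Point("x", "y", hi, 99.0, 10)], band)
        assert flags == ["inside"]

    def test_uncovered_point_flagged(self):
        band = ag.build_null_band_from_points(
            [ag.F100Point("a", "b", 0.5, 99.0, 10)] * 6)
        flags = ag.compare_to_null([ag.F100Point("x", "y", 0.5, 95.0, 10)], band)
        assert flags == ["uncovered"]


class TestClassifyGenes:
    def test_identical_pair_all_recombinant(self, small_population):
        genes = small_population.genes["G0000"]
        copies = [Gene(genome_id="X", gene_id=g.gene_id, seq=g.seq,
                       start=g.start, end=g.end) for g in genes]
        recs, unshared = ag.classify_genes(genes, copies, panel={})
        assert unshared == []
        assert all(r.category == "recombinant" for r in recs)

    def test_empty_panel_all_non_recombinant(self, rng):
        a = [make_gene(rng, "A", f"g{i}", 400) for i in range(4)]
        b = [Gene(genome_id="B", gene_id=g.gene_id, seq=mutate(rng, g.seq, 4),
                  start=0, end=400) for g in a]
        recs, _ = ag.classify_genes(a, b, panel={})
        assert all(r.category == "non_recombinant" for r in recs)

    def test_third_partner_rule(self, rng):
        """A gene below the cutoff within the pair but identical to a panel
        genome's copy is classified as recombinant-with-third-partner."""
        g = make_gene(rng, "A", "g0", 400)
        partner = [Gene(genome_id="B", gene_id="g0", seq=mutate(rng, g.seq, 4),
                        start=0, end=400)]
        panel_gene = Gene(genome_id="C", gene_id="g0", seq=g.seq, start=0, end=400)
        recs, _ = ag.classify_genes([g], partner, panel={"C": [panel_gene]})
        assert recs[0].category == "third_partner"
        assert recs[0].best_third_identity == 100.0

    def test_categories_partition_shared_genes(self, two_cluster_population):
        pop = ag.apply_recombination(two_cluster_population, 0.2,
                                     donor_scope="between", seed=3)
        ids = sorted(pop.genes)
        ref, partner = ids[0], ids[1]
        panel = {i: pop.genes[i] for i in ids[2:5]}
        recs, unshared = ag.classify_genes(pop.genes[ref], pop.genes[partner], panel)
        assert len(recs) + len(unshared) == len(pop.genes[ref])
        assert {r.category for r in recs} <= {
            "recombinant", "third_partner", "non_recombinant"
        }


class TestCumulativeCurve:
    def test_identical_partners_saturate_immediately(self, small_population):
        genes = small_population.genes["G0000"]
        partners = [("P1", [Gene(genome_id="P1", gene_id=g.gene_id, seq=g.seq,
                                 start=g.start, end=g.end) for g in genes]),
                    ("P2", genes)]
        curve = ag.cumulative_recombinant_curve(genes, partners)
        assert curve.cumulative_fraction.iloc[0] == 1.0
        assert curve.newly_detected.iloc[1] == 0

    def test_no_high_identity_flat_zero(self, rng):
        a = [make_gene(rng, "A", f"g{i}", 400) for i in range(3)]
        partners = [("P", [make_gene(rng, "P", f"g{i}", 400) for i in range(3)])]
        curve = ag.cumulative_recombinant_curve(a, partners)
        assert (curve.cumulative_fraction == 0).all()

    def test_nondecreasing_and_final_value_permutation_invariant(
            self, two_cluster_population):
        pop = ag.apply_recombination(two_cluster_population, 0.3,
                                     donor_scope="between", seed=9)
        ref = "G0000"
        others = [g for g in sorted(pop.genes) if g != ref][:6]
        fwd = ag.cumulative_recombinant_curve(
            pop.genes[ref], [(p, pop.genes[p]) for p in others])
        rev = ag.cumulative_recombinant_curve(
            pop.genes[ref], [(p, pop.genes[p]) for p in reversed(others)])
        assert fwd.cumulative_fraction.is_monotonic_increasing
        assert fwd.cumulative_fraction.iloc[-1] == rev.cumulative_fraction.iloc[-1]


class TestSummarizeForces:
    def _rec(self, cat, length=300, mism=3):
        return ag.GeneCategoryRecord(
            gene_id="g", partner_genome="p", category=cat, identity=99.0,
            aln_length=length, mismatches=mism, gene_length=length)

    def test_hand_computed_totals(self):
        records = {
            ("r", "p1"): [self._rec("recombinant", 300, 0),
                          self._rec("third_partner", 500, 5)],
            ("r", "p2"): [self._rec("recombinant", 400, 1)],
        }
        df = ag.summarize_forces(records)
        assert df.loc["recombinant", "n_genes"] == 2
        assert df.loc["recombinant", "total_length"] == 700
        assert df.loc["recombinant", "total_mismatches"] == 1
        assert df.loc["third_partner", "total_mismatches"] == 5
        assert df.loc["non_recombinant", "n_genes"] == 0

    def test_counts_sum_to_shared_genes(self):
        records = {("r", "p"): [self._rec("recombinant"),
                                self._rec("non_recombinant"),
                                self._rec("third_partner")]}
        df = ag.summarize_forces(records)
        assert df.n_genes.sum() == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ag.summarize_forces({})
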