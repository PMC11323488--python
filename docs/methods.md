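# Methods

## The problem

Viral species — especially bacteriophages — are usually delineated at >95%
genome-wide average nucleotide identity (ANI). Within a species, pairwise
ANI values are not spread evenly: comparisons pile up near 100% (members of
the same clonal cluster) and around 96–99% (members of different clusters),
leaving a depleted stretch of values, typically around 99.2–99.8% ANI, in
between. That depleted stretch — the intra-species ANI gap — is a natural
boundary for intra-species units (*genomovars*, clustered at >99.5% ANI by
default here). This package implements the full analysis: fragment-based
ANI, gap detection with bootstrap support, four-group classification of
species-level ANI distributions, genomovar clustering, the F100
recombination statistic against a mutation-only null model, and a
population simulator that provides ground truth for all of it.

## Fragment-based ANI

The query genome is cut into consecutive, non-overlapping fragments
(default 1 kbp, suited to short viral genomes; a trailing remainder is
discarded). Each fragment is placed at its best location in the subject
genome, on either strand, and the ANI of the directed comparison is the
mean percent identity of the fragments that map. Fragments whose best
identity falls below a floor (default 80%) are treated as unmapped;
`shared_fraction` = mapped/total fragments measures shared genome content.
Pairs below a reporting floor (default 95%, the species window) are
dropped from all-vs-all tables, as are self-matches.

Placement is exact rather than sketch-based: sampled 13-mers of the
fragment vote for candidate diagonals in a position index of the subject,
the top three candidate windows (±60 bp pad) are aligned with edlib in
infix mode, and if no anchor exists the whole subject is scanned. This
keeps results deterministic and makes the independent check simple: on
mutation-only genomes ≤10 kbp, an exhaustive sliding-window Hamming oracle
agrees with the engine to within 0.1 ANI points (enforced in the tests and
recomputed by the acceptance script). Identity is `1 − edits/fragment_len`;
positions involving N always count as mismatches (N is translated to
different sentinel characters on the two sides before alignment, so N
never matches anything, including another N).

For clustering, the two directed ANI values of a pair are averaged (one
direction is used alone if the other fell below the reporting floor).
Single-linkage transitive closure is the default linkage: "sharing more
than X% ANI" is a pairwise relation, and the closure is its canonical
partition, at the cost of possible chaining (documented; a greedy-centroid
mode that never chains is available). Cluster ids are assigned
deterministically by each cluster's lexicographically smallest member. No
minimum shared-fraction is imposed on pairs by default.

## Gap detection and the four groups

Intra-species ANI values are binned into 51 bins of 0.1% over [95, 100]
(nearest-center assignment, half-open intervals, upper edge closed at the
last bin). Counts are smoothed with a penalized cubic spline
(`scipy.interpolate.make_smoothing_spline`). The roughness penalty is a
fixed `lam = 1e-3` on this bin scale: penalty selection by generalized
cross-validation was evaluated and rejected because on spiky count
histograms (a few hundred pairs over 51 bins) it collapses the series to a
near-linear ramp, erasing the bimodal structure the analysis exists to
detect. A reflect-padded moving average (default window 5) is available as
a hand-checkable oracle backend. Smoothed values are clamped at zero;
constant series pass through unchanged.

Peaks are local maxima of the smoothed series with prominence ≥2% of the
maximum and separation ≥2 bins; valleys are peaks of the negated series
under the same settings; plateaus report their center bin once. A valley
is *validated* only if its smoothed count is below 0.5× the mean smoothed
count — i.e., it sits in a genuinely depleted region, not a dimple on a
slope.

Each species' distribution is classified with fixed precedence:

1. **group 2** (clonal) — mean ANI above the clonal threshold (99.8%);
2. **group 1** (gap) — a validated valley inside the gap range
   ([99.2, 99.8], inclusive at both edges);
3. **group 4** (contradictory) — a peak, and no validated valley, inside
   the gap range (a valley wins over a coexisting peak by construction);
4. **group 3** (undetermined) — otherwise.

A long-read preset shifts the gap range to [98.8, 99.5] and the clonal
threshold to 99.5%, reflecting the higher residual error rate of
unassembled long reads. The mean is computed over all supplied values;
only values inside [95, 100] contribute to shape detection.

Bootstrap support: each replicate subsamples the table to the same number
of pairs per species (default 150; species with fewer pairs are excluded
entirely), rebuilds and smooths the histogram, detects extrema, and
validates valleys. Per-bin detection frequencies accumulate over
replicates; the *deepest consistent valley* is the validated-valley bin
with the highest frequency, ties broken by lower replicate-averaged
smoothed count, then lower ANI. All replicate seeds derive from one seed,
so a run is reproducible bit-for-bit.

## F100 and the no-recombination null

Reciprocal best-match (RBM) genes between two genomes are found by exact
global alignment (edlib, both strands): the best hit minimizes edit
distance (ties break by gene id), and a pair is kept only if each gene is
the other's best. A k-mer shortlist prunes the candidate set, with a full
scan whenever the shortlisted best stays below 85% identity, so the true
best is never missed; a Biopython all-vs-all aligner serves as the
independent oracle in the tests. Identity is computed over alignment
columns (internal gaps count as differences); an RBM's `mismatches` field
is the edit distance of its alignment.

F100 is the fraction of a pair's RBM genes with identity strictly above
99.8% — genes essentially untouched since a recent common origin, which
point mutation alone rarely leaves in diverged genomes. Observed
(ANI, F100) points are judged against a *null band*: a population is
simulated under mutation only, its ANI and F100 are computed by the same
machinery, points are binned by ANI (0.1% bins), and per-bin empirical
2.5%/97.5% quantiles form the band (bins with <5 points interpolate from
their filled neighbors; bounds are closed, so a point on the band is
inside). Points above the band carry recombination signal; `uncovered` is
reported, never silently dropped, for points outside the band's ANI range.

Per-pair gene classification (cohesion vs diversification): a shared gene
is **recombinant** if its pair identity exceeds 99.8%; otherwise
**third_partner** if its best RBM identity against any panel genome
exceeds 99.8%; otherwise **non_recombinant**. All cutoffs are strict
comparisons. Cumulative recombinant curves process partners in decreasing
ANI order by default and count a reference gene once, at the step where
any partner first shows it above the cutoff; the curve is nondecreasing
and its final value is invariant to partner order. Force summaries total
gene counts, reference-gene lengths, and alignment mismatches per
category.

## The population simulator

The simulator is the ground truth for everything above. An ancestor
replicon is built from `n_genes` random genes (lengths ~
Normal(gene_len_mean=1000, gene_len_sd=200), truncated at 150 bp) each
followed by a 50 bp random spacer. If `n_clusters > 1`, each cluster
ancestor receives Poisson(`between_cluster_mu`) substitutions from the
root — so two clusters are separated by roughly `2·(between_cluster_mu +
mu)` substitutions. Each genome copies its cluster ancestor (assigned
round-robin) and receives `round(max(0, Normal(mu, sd)))` substitutions at
distinct uniform sites — the truncated-Normal rule accommodates
configurations where sd exceeds mu. A fixed random `(100 − core_ratio)%`
of genes are accessory; each genome deletes each accessory gene (plus its
trailing spacer) independently with probability 0.5. There are no indels
or rearrangements beyond whole-gene deletion, which keeps the closed form
`ANI ≈ 100·(1 − 2·mu/L)` exact to first order for single-cluster,
fully-core populations (coincident hits ignored; clamped at 0 with a
warning when the mutation load exceeds L).

Whole-gene recombination replaces a recipient's gene, with probability
`recomb_rate` per gene, by the homologous copy from a random donor in
scope (same cluster / different cluster / any); donors are snapshotted
before the pass, so transfers do not chain within one call. Labeled
variant collections place one ancestor per label Poisson(`between_label_mu`)
substitutions from a shared root and draw members as above; optionally a
fraction of positions is N-masked in a fraction of genomes (masking uses
its own random stream, so masked and unmasked runs share the underlying
genomes). Every substitution, deletion, transfer, and masking event is
logged, and replaying the log onto the ancestor must reproduce each genome
byte-for-byte (tested). All randomness in a simulation flows from one
integer seed; identical parameters give byte-identical FASTA.

Canonical study conditions used by the tests and the acceptance script:

* `planted_gap_params`: two clusters of 15 genomes on a ~21 kbp genome,
  within-cluster ANI ≈ 99.9 (mu=10, sd=3), between-cluster ANI targeted in
  [98.5, 99.1] by solving the divergence parameter from the nominal length.
* `voc_like_variants`: six labels × 10 genomes on 30 kbp, label ancestors
  ~35 substitutions from the root, members ~15±5 — same-label pairs near
  99.90% ANI, different-label pairs near 99.67%, an empty stretch around
  99.8%, and (optionally) N-masking of half the genomes. These rates were
  chosen so that both modes are *dense* at 0.01%-bin resolution, as in
  real heavily-sequenced collections; with only a handful of well-separated
  label ancestors the between-label mode fragments into discrete clumps
  and the least-populated-bin rule would land between clumps instead of in
  the true gap.
* the no-recombination null: 100 genomes, 70 genes, 90% core ratio,
  mutation counts ~N(690, 150) — a natural phage population scale.

## Variant concordance

Genomes with more than `max_n` undetermined positions (default 0) are
discarded first: Ns act as mismatches, inflate ANI dispersion, and blur
the gap (the tests assert the dispersion increase on masked copies).
Labels with more than `cap_per_label` genomes are subsampled without
replacement; smaller labels are kept whole. The variant threshold is
data-driven: the ANI bin (default width 0.01%) with the fewest pairs,
restricted to the interior of the occupied range so empty edge bins can
never win; ties go to the lower ANI. Concordance counts, on each side of
the threshold (above is strict), the fraction of pairs whose genomes share
a variant label; unlabeled genomes are an error, named individually.

## Numerical and interface choices

* Coordinates are 0-based half-open; ANI/identity are percentages;
  fractions are in [0, 1].
* A directed pair that maps zero fragments has ANI = NaN and is excluded
  from tables (`NA` in the TSV dialect).
* Histogram bin assignment is round-half-up to the nearest center with a
  1e-9 guard against float edge error.
* TSVs are a fixed dialect (tab separator, `.` decimal, no quoting, one
  header row) and round-trip exactly; malformed lines are reported with
  their line number. Every written artifact can carry a JSON sidecar with
  the parameters and seeds that produced it.
* The umbrella CLI (`anigap`) is a thin layer over the library; the
  Python API plus `examples/` is the primary interface.

## Problem sizes and limitations

The test suite and acceptance script run on simulated populations of
30–100 genomes of 20–100 kbp — sizes where exact alignment is comfortable
on one CPU: planted-valley recovery uses 50 populations of 30 genomes,
null-band calibration uses the full 100-genome null population (4,950
pairs), recombination detection uses 40 genomes in two lineages, and
concordance uses 60 labeled genomes.

The simulator emulates substitution-driven divergence, gene-content
variation, whole-gene transfer, and N-masking. It does **not** emulate
small indels, rearrangements, mosaicism at sub-gene scale, sequencing
error profiles, assembly artifacts, or selection — so passing tests
establish that the pipeline recovers planted structure under the stated
evolutionary model, not that every real collection shows a gap (the
four-group classification exists precisely because some real species do
not). Fragment-based ANI on genomes with different gene content is
systematically slightly below the mutation-only closed form, because
fragments spanning content boundaries map at reduced identity; the closed
form is therefore only asserted for fully-core populations. RBM
best-hit ties at equal edit distance resolve by gene id rather than by
recomputing column-level identity, a tie that essentially never occurs
outside duplicated genes.
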