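# Methods

## Intergenomic similarity

The statistic is the VIRIDIC definition: for genomes *A* and *B*,
`sim = 100 · (I_A/|A| + I_B/|B|)/2`, where `I_A` (resp. `I_B`) is the
number of positions of *A* (resp. *B*) credited as identical after merging
local alignment blocks so that each position counts at most once.
`distance = 100 − similarity`. Identical sequences score exactly 100; the
statistic is symmetric and bounded in [0, 100].

Blocks come from an exact k-mer seed-and-extend aligner rather than BLASTN:

* seeds are shared k-mers (default **k = 15**) on both strands, found by a
  sorted join of 2-bit packed k-mer codes; k-mers occurring more than 50
  times in the subject are masked (simple repeat control);
* every seeded diagonal is scanned as a vectorized match/mismatch profile
  and segmented with an ungapped **x-drop** criterion (match +1, mismatch
  −2, x-drop 20) — equivalent to extending every seed on that diagonal and
  merging, but linear in the diagonal length;
* blocks on nearby diagonals (offset and gap ≤ **band = 32**) are chained
  across short indels, with bridged positions counted as non-matching (a
  conservative stand-in for banded gapped extension);
* blocks shorter than **min_block = 100 bp** are discarded.

Overlaps on a genome are resolved by descending match count (ties by
coordinates), crediting a partly covered block pro-rata
(`matches × uncovered/length`). `N` mismatches everything.

Defaults were chosen for sensitivity in the 95–99% identity range where
species demarcation operates. The guard-rail is agreement with a full
dynamic-programming global aligner within 2 percentage points on pairs
≤ 2 kb (tested). Low-complexity sequences defeat the repeat mask and are
out of scope — phage genomes are not low-complexity.

## Protein clustering

All-vs-representative greedy centroid clustering (CD-HIT style), replacing
cascaded MMSeqs2 clustering: deterministic, dependency-free, and equivalent
at the scale of a few thousand phage proteins in the sense that every
greedy cluster refines a connected component of the all-pairs threshold
graph (tested against a brute-force oracle).

The comparison kernel is an exact Smith–Waterman local alignment (BLOSUM62,
gap open 11 / extend 1 — BLAST defaults). Identity = matches / alignment
columns *including gap columns*; coverage of a sequence = aligned footprint
on it / its length. Membership requires identity ≥ `min_identity` and
coverage per `coverage_mode`: `both` (default, mirroring MMSeqs2 cov-mode
0), `shorter`, or `target`. Proteins are processed longest-first (ties by
genome then gene id) and join the first qualifying cluster, so the result
is independent of input order. Records whose conceptual translation
contains an internal stop are flagged on input and excluded. Cluster labels
are the majority non-"hypothetical" annotation among members, falling back
to the representative's label.

Two clustering tiers match the two analysis scales: 0.70 identity / 0.50
coverage for a within-genus pangenome, 0.50/0.50 for family-wide analysis;
both configurable.

## Pangenome and signatures

The presence/absence matrix booleanizes cluster membership per genome (rows
ordered by prevalence). Core = present in ≥ ⌈prevalence·n⌉ genomes
(default: all). Upset summaries use *exclusive* intersections (each cluster
contributes to exactly the subset of genomes containing it), so counts sum
to the total. A clade-signature cluster is present in **every** member of
one group and **no** member of the contrast group; per-taxon unique-core
tables apply the same definition taxon-vs-rest. Core clusters at the 70%
threshold are reported without any second identity filter — the threshold
lives in the clustering step, matching the pipeline order.

## Gene-content similarity and rank demarcation

Shared-cluster similarity defaults to percent Jaccard (shared/union); a
`of_smaller` mode (shared/min) is available and the mode is recorded in
outputs. Species and genus are single-linkage connected components of the
similarity graph at thresholds 95% and 70% (the ICTV convention for tailed
phages); since the species threshold is the larger, species nest inside
genera by construction. Both thresholds are configurable, and the subfamily
level is reported descriptively (intra/inter shared-PC distributions)
rather than as an algorithmic cut, because subfamily judgment in practice
weighs phylogeny as well.

## Core-genome phylogeny

The conventional MSA + partitioned maximum-likelihood stack is deliberately
replaced by a distance design: per core cluster, one member per genome
(longest, then lexicographic gene id), pairwise distance 1 − local-alignment
identity, averaged over clusters into a genome distance matrix; classical
neighbor joining (ties in the Q criterion broken by the smallest label
pair; negative limb lengths clamped to zero with the deficit moved to the
sister edge); midpoint rooting on the longest leaf-to-leaf path
(lexicographic tie-break; all-zero trees root at a deterministic edge with
a warning). This preserves the conclusions the analysis actually uses —
clade membership and tree congruence — while removing heavyweight
dependencies; it does not estimate substitution-model parameters and its
branch lengths are mean protein distances, not substitutions/site.

Support is cluster resampling (gene-jackknife flavor): core clusters are
resampled with replacement, the tree is rebuilt per replicate from cached
per-cluster distance matrices, and support is the percentage of replicates
containing each internal bipartition. It is analogous to, not identical
with, a site bootstrap — there is no alignment to resample sites from.

Congruence between trees over the same leaves is the unrooted
Robinson–Foulds count plus the fraction of shared internal bipartitions.
Marker trees are built from a single universal cluster (terminase large
subunit and portal protein by annotation label, else the largest core
clusters).

The inferred **clade partition** is the pair of subtrees under the midpoint
root of the core tree. This mirrors how such clades are read off published
core-genome phylogenies and avoids introducing a third similarity
threshold.

## Synthetic communities

The generator emulates a community of ~45 kb tailed-phage genomes: a root
ancestor carries the core gene families; each clade ancestor adds its
signature families and substitution divergence; each genome adds further
substitutions and Bernoulli accessory genes. Genomes are assembled as
ordered genes (every sixth family on the minus strand) separated by
inherited intergenic spacers; emitted proteins are exactly the table-11
translations of the emitted CDS (tested). The model is substitution-only
(no indels) so divergence arithmetic stays exact for oracles; an optional
duplication probability plants paralogs, and a discordant-family mode
simulates a gene transfer (selected genomes inherit the other clade's
allele) for congruence testing.

Substitutions are i.i.d. per site to a uniformly chosen different base.
Mutations that would create an internal stop codon (or destroy the terminal
stop) are redrawn to a different base at the same site, preserving per-site
divergence. Configured within/between rates are target *pairwise*
substitution divergences: genomes mutate at within/2 from their clade
ancestor, clade ancestors at (between − within)/2 from the root; expected
pairwise divergences (with the uniform-model composition
p∘q = p + q − 4pq/3) are emitted in the truth file.

Default configuration — the study conditions:

| parameter | default | rationale |
|---|---|---|
| clades (genomes) | 2 (9 + 6) | two temporally distinct clades, 2021–22 and 1987–2013 |
| core families | 63, 160–260 aa | conserved structural/replication genes |
| signature families | 3 + 4, 45–65 aa | clade-exclusive loci (homing-endonuclease scale) |
| accessory families | 3, 35–55 aa, rate 0.10/genome | sporadic small ORFs |
| intergenic spacers | 2–60 bp | compact phage architecture |
| substitution divergence | 0.5% within, 2.0% between | see below |
| genome length | realized ~41–44 kb | matches ~45 kb target |

The substitution defaults are calibrated so the **realized** intergenomic
similarity — substitutions *plus* unaligned clade-exclusive/accessory
content — reproduces the observed community structure: >99% within clades,
~96% (minimum ~95.8%) between clades, hence a single species at the 95%
demarcation while every signature family still splits out at the 70%
protein threshold. Treating the quoted "~4% between-clade divergence" as
total rather than pure substitution divergence is deliberate: with 4%
substitutions *and* clade-exclusive content, no community could
simultaneously be one species at 95%.

What the generator does **not** emulate: genome rearrangement and mosaicism,
recombination within genes, indels (unless the discordant/paralog options
are engaged), codon bias, and realistic gene order. Passing tests therefore
demonstrate correctness of the pipeline's accounting and statistics on
colinear substitution-driven divergence, not robustness to structural
variation in real genomes.

## Numerical and degenerate-input choices

* Matrix TSVs serialize at fixed 4-decimal precision; round-trips are exact
  at that precision.
* Identical sequences short-circuit to similarity 100 / identity 1.0,
  avoiding block-edge artifacts on the diagonal.
* Single-cluster resampling yields support 100 everywhere (every replicate
  identical) rather than an error.
* Singleton taxa produce intra rows with `n_pairs = 0`, not errors.
* Genomes with zero protein clusters make Jaccard undefined and are
  reported as errors naming the genome.
* All randomness flows through a single integer seed per entry point
  (generator, resampling); identical seeds give byte-identical artifacts.

## Problem sizes

Default analyses run on 15 genomes of ~42 kb (105 genome pairs, ~1,000
proteins, 63 core clusters, 200 resampling replicates), completing in about
a minute on one CPU; unit and property tests use 4–6-genome communities
with 8–12 families.

## Known limitations

* The seed-extend aligner is a reproducible stand-in for BLASTN inside
  VIRIDIC/taxMyPhage; absolute similarities can differ from VIRIDIC by
  block-edge effects (the floor/threshold contracts, not exact cell values,
  are the reproduction targets on deposited data).
* Greedy centroid clustering does not reproduce MMSeqs2 cluster identifiers
  and can split borderline families differently near the thresholds; the
  MMSeqs2 coverage mode used for the printed core counts is not stated in
  the source analyses, so `both` is the documented default.
* NJ + midpoint rooting gives no model-based branch support; resampling
  support is over clusters, and within-clade resolution on near-identical
  genomes is noise (reported with low support, as it should be).
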