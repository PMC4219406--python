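# Methods

This note documents the models and procedures behind `symbioscreen`, the
parameters that matter, the design choices made where the design was open,
and what the synthetic-data validation does and does not show.

## Problem setting

Given proteomes and assemblies for a set of related bacterial genomes, some
isolated from a host (the *in-group*) and some free-living, the pipeline
asks two questions. First, which gene families are present in every
in-group genome but absent from the others (presence/absence signal)?
Second, within families shared more broadly, where do the in-group sequences
form a clade of their own on the gene tree (topology signal)? A family that
answers either question is a *candidate symbiosis factor* — a hypothesis
generator, not a verified functional claim.

## Ortholog clustering

**Similarity search.** Every protein pair is aligned with Smith–Waterman
under BLOSUM62, gap open 11 / extend 1 (a gap of length k costs 11 + k),
via Biopython's C aligner. Ambiguous residues are mapped to X on input and
X scores the matrix minimum against everything, keeping the scoring total.
Significance uses the Karlin–Altschul form E = K·m·n·e^(−λS) with fixed
gapped BLOSUM62 constants λ = 0.267, K = 0.041. Fixing the constants trades
composition-specific accuracy for exact reproducibility; the defaults
(E ≤ 1e-5, coverage ≥ 0.5 of the shorter sequence) follow long-standing
pre-clustering practice. An optional 4-mer prefilter (default off; minimum
8 shared distinct 4-mers) skips hopeless pairs: two unrelated 300-residue
proteins share ~0.5 distinct 4-mers in expectation while homologs share
tens, so enabling it does not change the surviving edge set on data of that
kind, only the running time.

**Graph construction.** Since the aligner is symmetric, a hit passing the
filters is reciprocal by construction. Edge weight is −log10(E) capped at
300 (so E = 0 stays finite for MCL). Within-genome pairs are kept only as
*in-paralogs*: both partners must score their mutual hit above either one's
best between-genome hit. Between-genome weights are normalized by the mean
between-genome weight of that genome pair; in-paralog weights by the mean
in-paralog weight of that genome. The pair-mean normalization corrects for
lineage-specific divergence so that MCL granularity is comparable across
near and far genome pairs; normalizing in-paralogs per genome keeps the two
edge classes on one scale.

**Markov clustering.** The column-stochastic weight matrix (self-loops at
each node's maximum incident weight) is iterated through expansion (matrix
squaring) and inflation (elementwise power 1.5, the conventional
granularity for ortholog groups), pruning entries below 1e-5 and stopping
when the maximum entry change falls below 1e-6 or after 100 iterations.
Clusters are connected components of the symmetrized limit matrix; MCL can
only split, never join, connected components, so unrelated proteins cannot
be merged. Cluster ids are assigned by descending size then smallest member
id, making outputs diffable. Isolated proteins become singleton COGs, so the
output is always a partition of the input.

**Representatives.** Each COG's alignment yields a position-specific
profile: per-column log-odds (base 2) against a uniform background with
add-one pseudocounts; columns more than half gaps are insert columns,
excluded from scoring. The pool sequence with the best profile-to-sequence
global alignment becomes the representative and donates its annotation;
it may lie outside the COG, which is logged. Gap penalties for this
alignment are open 4.0 / extend 0.5 *in log-odds units* — BLOSUM-scale
penalties would be meaningless against log-odds columns; the chosen values
keep gaps rare relative to typical per-column scores (≈ 2–4 bits at
conserved columns).

## Alignment, distances, trees

**Progressive alignment.** Guide tree from fractional-common-3-mer
distances (1 − shared/min) by UPGMA; profile–profile global alignment at
each internal node with BLOSUM62 mean-of-pairs column scores and affine
gaps 11/1. Ids are sorted before anything else and children are visited in
sorted-id order, so the alignment is independent of input order. For two
sequences the result is an optimal global pairwise alignment (co-optimal
tracebacks may differ from another implementation's; the score is optimal).

**Distances.** Pairwise deletion (sites with a gap in either row are
excluded); p-distance or the Poisson correction −ln(1 − p). p is capped at
0.95 before the log so saturated pairs stay finite (cap distance ≈ 3.0
substitutions/site). A pair with zero comparable sites is an error naming
the pair.

**Neighbor joining.** Canonical Saitou–Nei NJ with the Studier–Keppler
Q-criterion. Ties in Q are broken by the smallest (row id, column id) pair.
Negative branch-length estimates are clamped to zero with the deficit moved
to the sister branch. On additive matrices NJ is exact; the acceptance
suite verifies exact topology and branch-length recovery on random additive
matrices up to 12 taxa.

## The exclusive-clade screen

A "group-specific clade" is formalized as an **exclusive bipartition** of
the unrooted gene tree: an edge whose removal yields a leaf side whose
genomes (i) are all group members and (ii) include every group member at
least once. This is rooting-invariant — the natural reading of a terminal
node on an NJ tree, whose rooting is arbitrary. Extra paralogs of group
genomes elsewhere in the tree do not disqualify a clade; a group equal to
the entire leaf set (one leaf per genome) can never be exclusive, since no
edge separates it.

Eligibility: a COG is screened when it has ≥ 3 sequences and every group
genome is represented; others are skipped with a logged reason. Support is
computed only for first-round positives (bootstrap is the expensive step):
columns are resampled with replacement, distances and NJ are rebuilt per
replicate, and support is the fraction of replicates in which the exclusive
bipartition recurs. A replicate whose resampled columns leave some pair
with no comparable sites cannot produce a tree and counts as
non-supporting. Defaults follow the screen's published conventions:
1000 replicates, retention at support ≥ 0.80 (inclusive). All seeds are
explicit and echoed to the run manifest.

**Locus assignment.** Retained hits are anchored on a reference genome
(default: the first group member; smallest-ordinal gene if the genome has
paralogs in the COG). Anchors on one contig with at most 5 intervening
genes between consecutive members share a locus; multi-gene loci get
letters by descending size then leftmost coordinate, singletons are "lone".
The 5-gene threshold is a package choice — published locus figures show
tight clustering but no explicit rule — and is configurable and logged.

## Gene content

Counts are COG counts, not gene counts: paralogs collapse to one presence
bit. Pairwise "unique" counts are computed against the pair only,
regardless of other genomes, which makes shared + unique_A equal to A's
row sum — an identity the tests exercise on random matrices.
Group-exclusive COGs are those present in every in-group genome and absent
from every out-group genome, other genomes ignored.

The mobile-element scan matches annotation keywords (default plasmid, par,
phage, replication) as whole tokens, also allowing gene-name style tokens
with one trailing capital (parA, ParB) so that "preparation" never matches
"par". A contig is flagged putative-mobile when at least half its genes
match; contigs under 60 kb are additionally listed for review regardless of
fraction, replacing the manual inspection step of the original protocol
with an explicit, configurable rule. A third strategy used in that
protocol — BLASTn against relatives' plasmids — requires external sequence
collections and is out of scope.

## APNI

Whole-genome identity follows the fragment-based ANIb convention rather
than maximal-match whole-genome alignment: 1020-bp non-overlapping
fragments per contig (terminal remainders ≥ half length kept, shorter
dropped), each fragment placed in the other genome by exact 15-mer seeds on
both strands and aligned to a padded candidate window by infix
edit-distance alignment (edlib); identity is 1 − edits/alignment-length.
Fragments are retained at ≥ 30% identity over ≥ 70% of their length; each
direction's ANI is the mean retained identity, and APNI is the mean of the
two directions, in percent, with 95% as the same-species benchmark. The
unit-cost scoring is a deliberate simplification: for substitution-style
divergence it yields the same identities as an affine scheme, and the
divergence range that matters for species delineation (≥ 85% identity) is
far from the regime where gap-cost choices move the value. A pair in which
no fragment aligns in some direction is reported "no alignment", never
APNI = 0. Self-comparisons give exactly 100.0. Expected deviation from
maximal-match implementations is a few tenths of a point, so external
comparisons should carry a ±0.5-point tolerance.

## Synthetic data and what validation shows

The generator draws a random species tree (sequential uniform edge
attachment — uniform over labelled topologies — with exponential branch
lengths, mean 0.1 substitutions/site), samples per-family presence
(default 0.85 per genome), evolves 300-residue proteins down each family's
gene tree (each site substitutes along a branch of length l with
probability 1 − e^(−rate·l), replacement uniform over the other 19
residues; rate 1.0), back-translates with uniform synonymous codon choice,
and assembles contigs with 200-bp random spacers. A fraction f = 0.1 of
families is *planted*: the in-group is detached and re-grafted as a single
clade on a fresh stem of length s = 0.5. Planting by re-grafting, rather
than simulating an explicit transfer process, gives exact ground truth
without inventing transfer rates. Planted genes of in-group genomes are
placed consecutively so genuine loci exist; 5% of families carry
mobile-element keyword annotations; one genome pair at 5% nucleotide
divergence is emitted for APNI checks.

Two constraints keep the truth table exact. The species tree is redrawn
(seeded, bounded) until the in-group is *not* monophyletic in it, so null
families genuinely lack the signal. And a null family whose sampled
presence pattern would leave the in-group exclusive in the pruned species
tree (every interleaving taxon absent by chance) has its presence resampled
— otherwise the "false positive" would be a correctly detected, genuinely
monophyletic family, and the planted flag would no longer equal realized
monophyly.

Default validation conditions: 8 genomes, 3 in-group, 200 families,
f = 0.1, s = 0.5, protein length 300, seed 11, 100 bootstrap replicates
(the screen's 1000-replicate default is for real runs; 100 suffices to
separate support ~1.0 planted families from chance positives at these
conditions). Under these conditions the full orthology → screen pipeline
achieves sensitivity ≥ 0.9 and false-positive rate ≤ 0.05 against truth
(observed: 1.0 and ≤ 0.01 across seeds), and APNI recovers planted
divergence within 0.5 points on megabase pairs.

What this does **not** show: the generator has no indels, no rate
heterogeneity, no codon bias, no rearrangements, and plants a clean,
strong signal (s = 0.5 on branches of mean 0.1). Real screens face
alignment error, saturated families, incomplete lineage sorting and partial
transfers; passing tests demonstrate that the machinery is correct and the
decision rule behaves as specified, not that the screen's error rates on
real genomes match these numbers. Full-scale replication of a published
screen additionally depends on the exact genome panel and on
alignment-statistic choices (the E-value cutoff and coverage filter ahead
of clustering are rarely reported), so COG counts can drift between stacks.

## Numerical and degenerate-input choices

* −log10(0) capped at 300; all graph weights finite and ≥ 0.
* Profile columns use add-one pseudocounts; uniform 1/20 background.
* Alignment-traceback state matching uses a 1e-6 tolerance with a fixed
  preference order (match, then gap-in-B, then gap-in-A) for co-optimal
  paths.
* NJ final three-taxon star solved in closed form; clamping as above.
* Trees with fewer than 3 leaves are never built (such COGs are skipped).
* Empty inputs (FASTA without entries, empty alignment, empty pool,
  zero-replicate bootstrap) are errors, not silent no-ops; a genome that
  contributes no protein to any COG is an error in matrix construction.
* Dataset emission refuses a non-empty output directory without an
  explicit overwrite flag; reruns with one config and seed are
  byte-identical.

## Second-round validation

The screen validates first-round hits by NJ bootstrap rather than
maximum-likelihood tree building. ML inference is out of scope here; the
quantity the pipeline is judged on is planted-signal recovery, and the
bootstrap over the same distance/NJ construction measures exactly the
stability of the clade that the first round found. Users who want ML
validation can export the per-hit alignments and trees (aligned FASTA and
newick are both written) to an external tool.
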