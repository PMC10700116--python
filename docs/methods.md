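# Methods

This note documents the models and procedures implemented in `kleptoscreen`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic study does and does not establish.

## Alien Index screening

For one query protein with hit set H (best HSP kept per subject; bitscore
ties broken by lower e-value, then lexicographic subject id), the normalized
bitscore of a hit is nbs = min(1, bitscore / self_bitscore), where the self
bitscore comes from the query's own self-alignment row, identified by
subject id equal to query id or an explicit flag. The Alien Index is
AI = nbsO − nbsM with nbsO the maximum nbs over hits whose lineage excludes
the recipient clade (Metazoa) and nbsM the maximum over hits inside the
recipient clade, skipping the query's own sublineage (Placobranchoidea) on
*both* sides — close kleptoplastic relatives can neither vouch for vertical
inheritance nor count as donors. Conventions chosen here:

* a side with no qualifying hit contributes nbs = 0, so lineage-restricted
  genes get AI = nbsO and metazoan-only genes get AI = −nbsM;
* nbs is clamped at 1 so AI stays in [−1, 1] even when an HSP out-scores the
  self alignment;
* "total database hits" for the candidate filter counts post-collapse
  subjects, including the self subject (the alternative — counting HSPs —
  differs only when a subject aligns in several pieces, and subjects is the
  quantity the per-subject collapse makes well defined).

Contig flagging uses two rules verbatim: a contig is bacterial contamination
iff min AI over its genes > 0, or the fraction of genes with AI > 0.1 is
≥ 1/2. Note the first rule flags a single-gene contig with 0 < AI ≤ 0.1 —
aggressive, but applied as stated. HGT candidacy is AI > 0.1 (strict),
≥ 50 hits, and a non-flagged contig. Organelle flagging requires ≥ 2 hits at
e ≤ 1e−5 to one organelle's protein set; when a contig qualifies for both
organelles, the one with more qualifying hits wins (tie: smaller minimum
e-value).

## Gene-model curation

Coordinates are 1-based inclusive; the overlap of [s1,e1] and [s2,e2] is
max(0, min(e1,e2) − max(s1,s2) + 1), and "intersect" means ≥ 1 bp on either
strand (the default semantics of interval intersection tools). An unmasked
model is rescued iff (1) zero-bp overlap with every masked gene span on its
contig, (2) best BLASTp e-value < 1e−3 against model-animal proteomes,
(3) zero-bp overlap between its exons and classified repeats, and (4) no
single exon with > 50% of its length covered by the union of simple-repeat
intervals. The 50% rule is applied per exon (read distributively); coverage
is computed on the merged union so overlapping repeat annotations are not
double-counted. Gene length in summaries is the genomic span including
introns; the median of an even-sized list is the mean of the central pair;
percentages are half-up rounded to two decimals via decimal arithmetic (not
binary-float rounding). The expression-evidence threshold is mean
length-scaled TPM ≥ 1 in ≥ 1 stage; the comparator is configurable (≥ or >)
because the two appear interchangeably in practice — ≥ is the default, being
the definition attached to summary tables. Orthology evidence excludes
orthogroups private to the focal species.

## Expression analysis

**Length-scaled TPM.** TPM_gs = (c_gs/L_gs) / Σ_g (c_gs/L_gs) · 1e6 with
L_gs the per-sample effective length; each gene is then re-weighted by its
average length over samples and columns re-normalized. On the count scale
the same matrix is rescaled so each column sums to the observed library
size. All-zero columns stay all-zero.

**TMM.** The reference sample is the column whose upper quartile of nonzero
library-scaled counts is closest to the mean upper quartile. Per sample,
genes zero in it or the reference are dropped; M = log2 ratio and A = mean
log2 abundance are doubly trimmed (30% from each M tail, 5% from each A
tail, rank-based); the factor is the exponentiated inverse-variance-weighted
mean M using the delta-method binomial variance, and factors are rescaled to
geometric mean 1.

**Exact test.** Effective library sizes (library size × TMM factor) are
equalized by deterministic rescaling of counts to their geometric mean —
a simplification of the quantile-based adjustment used in the canonical
implementation; the rescaled group sums are rounded to integers. Given the
total t, the group sums follow the conditional distribution of two negative
binomials with per-library null mean t/(n_A+n_B) and sizes n/φ; at φ = 0
this is exactly Binomial(t, n_A/(n_A+n_B)). The default double-tail p-value
is min(1, 2·min(lower, upper)) with the observed outcome in both tails; a
summed-small-probabilities variant (`tail="smallp"`) is provided since
"double tail" is also read that way.

**Dispersion.** Method of moments: within each replicate group,
var = μ + φμ² is inverted and pooled over genes with degrees-of-freedom
weights, φ̂ = Σ df·(v−m) / Σ df·m², floored at 0. Dispersion is estimated
within developmental stages (not the two contrast groups) so stage
differences are not absorbed into noise. Trended mode estimates φ in 10
equal-occupancy log2-abundance bins and interpolates linearly per gene.

**DEG calling.** Genes failing the stage-mean TPM filter are excluded before
testing; the contrast pools egg+veliger+larva as one unfed group (3 vs 9
replicates) against juveniles. Reported log2FC uses TMM-normalized group
means with a 0.5 pseudo-count — reporting only, never inside the test. A DEG
requires log2FC > 2 and BH FDR < 0.01.

## Comparative candidates

Pattern classes partition orthogroups given declared species roles:
conserved_all (all five species), klepto_specific (all four kleptoplastic,
outgroup absent), singleton (one species), other. Candidates per class are
the focal-species members intersected with the DEG set — a deterministic
step, so recovery against planted truth is exact by construction.
Enrichment is the upper-tail hypergeometric P(X ≥ k) per term, BH-adjusted
across tested terms; terms with k = 0 are not tested. The background is the
tested universe (genes passing the expression filter) by default and is
configurable, since the appropriate universe (all genes, expressed genes,
annotated genes) is a genuine modelling choice; terms are used as given,
with no ontology-graph ancestor propagation. Domain-span extraction returns
[min start, max end] over the hits of all required profiles, kept only at
350–650 aa.

## Tree post-processing

Supports are parsed from internal node labels. Midpoint rooting places the
root halfway along the longest leaf-to-leaf path (two-leaf trees are rooted
directly at the path midpoint; ties resolve deterministically through the
underlying traversal order; a midpoint falling on a zero-length edge
resolves to its child node). Collapsing contracts every internal edge with
support below the threshold (default 95); unlabeled edges are kept, since
absent support is not evidence against a branch, and the operation is
idempotent. The automated HGT placement check walks from the query to the
smallest proper clade with ≥ 2 leaves and declares support iff that clade
contains ≥ 1 donor-class leaf and 0 recipient-class leaves, ignoring
skip-class leaves. This formalizes what is otherwise a manual inspection;
reports label it as an automated rule, not a curator's judgement.

## Synthetic study

The generator emulates the data *shapes* of a slug genome project, not
sequence evolution: contig sequences are i.i.d. random DNA, homology hits
are drawn directly as normalized-bitscore fractions against a fixed 3-level
toy taxonomy (with explicit Metazoa and Placobranchoidea labels so the skip
rule is exercised verbatim, and a self-hit in every gene's table), and
counts are drawn from the NB model itself — there is no read simulation or
mapping noise. Defaults are the study design: 4 stages × 3 replicates, 40
nuclear contigs of 3–7 genes, 3 contaminant contigs (bacterial best hits
with nbs 0.88–0.99), 1 HGT gene (donor nbs 0.85, metazoan nbs ≤ 0.3, > 50
subjects, planted on a multi-gene nuclear contig, with a donor-clade tree),
2 organelle contigs, 50 DEGs spiked at log2FC 3 into the juvenile stage,
NB dispersion 0.1, and a mean library of 200,000 counts per sample — a
desk-scale library that keeps per-gene totals in the realistic hundreds-to-
thousands range for the conditional exact test. Ordinary genes' metazoan
best hits dominate their out-lineage hits by construction, so nuclear
contigs are never flaggable; this makes contamination recall a clean test of
the rules rather than of hit-simulation noise. One integer seed determines
every file byte-for-byte; substreams per component are derived by fixed
offsets.

Because ~21% of simulated genes are spiked DEGs (a far higher fraction than
a real transcriptome), TMM's trimmed mean absorbs some of the composition
shift and measured fold changes shrink below the true 8×; sensitivity in the
90% range with zero observed false discoveries is therefore the expected
behaviour of a correct implementation under these conditions, not a ceiling
of the method. Passing recovery tests demonstrates the pipeline's logic and
statistics on data matching its assumptions; it does not establish
performance on real libraries with mapping ambiguity, length biases or
batch effects.

## Known limitations

* The exact test's deterministic library equalization diverges (slightly)
  from the quantile adjustment of the canonical count-based DE package;
  p-values are not expected to replicate it digit-for-digit.
* Moment-based dispersion is less efficient than likelihood-based empirical
  Bayes shrinkage; with 3 replicates per stage its trended estimates are
  noisy and are deliberately pooled across many genes.
* The HGT placement rule is one defensible formalization of a manual
  criterion; borderline placements (query sister to a mixed clade) are
  conservatively called unsupported.
* GFF3 handling covers the gene/exon subset these analyses exchange, not
  the full feature grammar.
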