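# Methods

This note documents the models, rules and numerical choices implemented in
`stressgenome`, and what the synthetic-data experiments do and do not
demonstrate.

## Genome content accounting

Internal coordinates are 0-based half-open throughout; GFF3 and
RepeatMasker-style inputs (1-based inclusive) are converted at the I/O
boundary, BED is consumed as-is. Composition uses the **union rule**:
exonic bases are the union of all exon intervals over all transcripts of
all genes; intronic bases are the union of gene spans minus that exonic
union; everything else — including assembly gaps — is intergenic. The
three classes therefore partition the genome exactly in integer
arithmetic, which the tests assert against a per-base labelling oracle.
Overlapping and nested genes need no special casing under the union rule.
Strand is parsed but ignored: occupancy fractions are strand-agnostic.

Per-gene statistics (exons per gene, intron length) are properties of a
single gene structure, so each gene is represented by the transcript with
the longest summed exon length; introns are the gaps between its
consecutive exons, single-exon genes contribute none, and the mean intron
length averages over introns, not genes. An annotation in which no gene
has an intron reports mean 0.0 with an explicit `no_introns` flag rather
than NaN.

GC content is (G+C)/(A+C+G+T) with N and other ambiguity codes excluded
from the denominator; the input convention of published assembly GC
figures is rarely stated, and excluding ambiguous bases makes the
statistic independent of gap content.

## Scaffold decontamination

Two independent homology-based rules, both config-overridable:

* **Mitochondrial**: scaffold length ≤ 15,822 bp (the brine-shrimp
  mitochondrial genome), at least one gene, and *every* gene on the
  scaffold has a hit labelled `mitochondrial-gene` with bit score ≥ 50.
  Gene-less scaffolds are never mito-flagged — the rule is gene-based.
* **Alien**: at least one hit; every hit at ≥ 70% identity is
  non-invertebrate; no invertebrate hit exists at any identity; and no
  stretch of the scaffold longer than 5 kb lacks a qualifying alien hit.
  A scaffold with no hits is retained: "100% non-invertebrate" cannot be
  established from nothing.

The 5 kb clause of the alien rule is genuinely ambiguous in prose form
("a maximum length of 5 kb without alien hits"). We implement the
windowed reading — no alien-free gap over 5 kb, measured between
consecutive alien-hit intervals and the scaffold ends — as the most
conservative interpretation that still removes only well-supported
contaminants; the alternative "only scaffolds ≤ 5 kb are eligible"
reading is selectable via `alien_rule_is_max_scaffold_len`. Taxon
grouping is precomputed into a column of the hit table rather than
resolved against a live taxonomy service, keeping the pipeline fully
offline-testable.

Monotonicity holds by construction: adding an invertebrate hit can only
move a scaffold from flagged to retained.

## Orthogroup calling

With focal count N_x and comparator count N_y, and defaults min_focal = 5,
ratio = 3: expanded iff N_x ≥ 5 and N_x ≥ 3·N_y; contracted iff N_x ≥ 5
and 3·N_x ≤ N_y. Because ratio > 1 the two calls are mutually exclusive
(asserted). A comparator count of zero with a qualifying focal count is
called expanded — the literal rule, and how presence/absence families
behave; `zero_comparator_as_unique` routes such calls to a separate
`focal_unique` status instead. Since the aggregation across comparators
behind a single "expanded" label is not fully specified in such analyses,
pairwise calls are always reported alongside a consensus status
(`expanded_vs_all` / `contracted_vs_all` / `mixed` / `none`), and
summaries default to the strict vs-all consensus.

Venn partitions define presence as count > 0 and assign each orthogroup to
exactly one of the 2^k − 1 regions, so region counts always sum to the
union size. Shared-unique detection is plain presence algebra
(present in every must-have species, absent from every must-lack species).

## Term enrichment

The 2×2 table per term compares the test set against an effective
reference R′ = reference ∖ test — the **asymmetric** contract: shared
genes are deleted from the reference only. This biases the test toward
the test set and legitimately yields zero annotated reference genes; when
test and reference are disjoint the asymmetry is inert and the procedure
is the ordinary one-sided Fisher exact test (asserted on fixtures). The
p-value is the upper hypergeometric tail P(X ≥ a); under-representation
is available behind a flag but over-representation is the default.

Gene→term annotations are closed upward under the is_a relation
(true-path rule) by default, which is correct for GO-style DAGs; flat
pathway maps should disable propagation. Test genes absent from the term
map stay in the table margins as unannotated rather than being dropped.
BH adjustment is the standard step-up (sort, p·m/i, enforce monotonicity
from the largest rank down, cap at 1); it is implemented directly — eight
lines — so that it agrees *exactly* with the brute-force oracle in the
tests. "Most specific" reduction keeps a significant term iff none of its
descendants is significant; a pure leaf filter would discard significant
interior terms whose children are all non-significant, which seems wrong,
but the significance-aware rule is a design choice, not a forced one.

## Differential expression

Counts are modelled as NB(μ, φ) with Var = μ + φμ², log link, and offsets
log(library size × TMM factor). The salinity design has nine fixed
columns — intercept, batch 2, high salinity, time 30/45/60, and the
salinity×time interactions — with batch 1 / low salinity / 15 min as
reference levels. The anoxia design is intercept + anoxia (no batch term
is present in that experiment).

**Sample layout.** The emulated salinity experiment has 16 libraries:
2 salinities × 4 time points × 2 replicates per condition, replicate
batches ordered (2, 1) within every condition so batch is balanced
against every contrast. (The study's sample table and its "over 14 out of
16 samples" filter rule imply different replicate counts; the 16-sample
reading is the one every downstream threshold is anchored to, so the
generator follows it and keeps the table's replicate-batch ordering.)

**Filtering**: a gene is removed iff its CPM (count·10⁶/library size, no
prior count) is below 3 in *strictly more than* 14 of 16 samples
(salinity) or 3 of 6 (anoxia) — the literal "over".

**TMM**: the reference library is the one whose CPM upper quartile is
closest to the mean upper quartile; per library, M and A values against
the reference are computed over genes with nonzero counts in both, the
top and bottom 30% of M and 5% of A are trimmed, and the factor is 2 to
the precision-weighted mean of surviving M values, rescaled to geometric
mean 1. This follows the reference implementation closely enough that the
tests verify agreement with edgeR's `calcNormFactors` to ~1e-6.

**Fitting**: per-gene IRLS with working weights μ/(1+φμ), batched across
genes (all genes share the design, so each iteration is one stacked
normal-equation solve), with step-halving on likelihood decreases, an
active set that drops converged genes, and convergence at relative
log-likelihood change < 1e-10. Coefficients match an independent IRLS
route (statsmodels' NB GLM) to ~1e-6. Linear predictors are clipped to
±60 and μ floored at 1e-10 for numerical safety; genes that fail to
converge within 60 iterations are flagged, logged and excluded from
testing. Coefficients are natural-log internally and reported in log2.

**Dispersion**: the Cox–Reid adjusted profile likelihood
APL(φ) = ℓ(φ; β̂(φ)) − ½·log det(XᵀWX) corrects the downward bias of
profile ML. A common dispersion maximizes the summed APL (on ≤ 1,000
evenly-strided genes — one shared parameter does not need more); per-gene
estimates maximize df·APL_g(φ) + prior_df·(mean APL over genes)(φ) on a
15-point log grid spanning 2^±6 around the common value with quadratic
refinement. prior_df defaults to 10 pseudo-degrees-of-freedom: per-gene
estimates from 7 residual df are noisy, and this weight roughly balances
per-gene evidence against the ensemble. The scheme is validated by
parameter recovery (the common estimate lands on the generating value;
shrinkage demonstrably tightens the estimate distribution), not by
matching any particular package's internals.

**Testing**: the omnibus screen is a likelihood-ratio test of
β_S = β_S:T30 = β_S:T45 = β_S:T60 = 0 against χ²(4) at the gene's fixed
dispersion (a quasi-likelihood F would be a different published method;
the LRT is fully self-contained). BH over omnibus p gives padjScreen;
genes with padjScreen < 0.05 are screened. Confirmation then tests the
five contrasts of interest — the salinity effect at each time point
(β_S, β_S+β_S:T30, β_S+β_S:T45, β_S+β_S:T60) and the equally-weighted
average effect β_S + (β_S:T30+β_S:T45+β_S:T60)/4 — by Wald tests, within
screened genes only, Holm-corrected over the five contrasts at the family
level equal to the largest raw omnibus p that BH rejected (the
screening-adjusted FWER recipe of stage-wise testing frameworks). The DE
direction is the sign of the average effect. The anoxia analysis is a
single-coefficient LRT with BH adjustment; whether significance should be
on raw or adjusted p is ambiguous in the source analysis, so both are
config options with *adjusted* as the default.

## Synthetic data

Generators are pure functions of their seed (identical seed ⇒ identical
bytes). Counts are drawn NB with constant dispersion 0.1 by default (a
log-normal gene-wise option exists for robustness checks), baseline
abundances log-normal around 30 CPM, library sizes log-uniform in
0.5–2 × 10⁶ — desk-scale, far below real sequencing depth. 10% of genes
get planted DE effects of ±2 log2 units on the main salinity effect, one
random interaction, or both; gene-wise batch shifts are N(0, 0.1 log2),
emulating a library-prep composition shift; a random 10% of genes carry
mild time trends. Orthogroup, scaffold and term-map generators plant
structures that satisfy the corresponding calling rule with margin
(e.g. planted enriched terms annotate the test set at ≥ 4× the background
rate) while backgrounds violate it by construction.

What passing tests show: the implementations compute the stated rules and
models correctly, with calibrated type-I error and honest power under NB
sampling at the stated conditions. What they do not show: robustness to
real-data pathologies the generators omit — read-level artefacts, GC
bias, mapping multi-hits, gene-wise dispersion trends with abundance,
correlated samples, annotation errors.

## Problem sizes used

Test and acceptance runs use desk-scale sizes chosen to exercise every
code path with tight Monte-Carlo bounds: 2,000 genes × 16 samples for
coefficient-recovery checks, 100 replicate null datasets of 2,000 genes
(common-dispersion fast path) for screening calibration, 5,000 null genes
for omnibus-p uniformity, 500 orthogroups, 30 scaffolds, 60 terms. The
exhaustive hypergeometric oracle covers all 2×2 tables with margins ≤ 12.

## Known limitations

* The NB GLM reports Wald confirmation p-values; profile-likelihood
  intervals would be more accurate at very low counts.
* The stage-wise confirmation controls within-gene FWER at the
  screening-adjusted level; it does not propagate a closed-form FDR
  guarantee to individual confirmed contrasts.
* TMM's reference-library choice makes factors discontinuous in rare
  edge cases where two libraries tie for the reference. The rank-based
  trim also degenerates when many genes share byte-identical M values
  (e.g. one library an exact copy of another except for a planted shift):
  whole tie groups receive one average rank and can fall outside the trim
  window together. Real libraries carry independent sampling noise, which
  breaks such ties; the simulated shift fixtures therefore sample both
  libraries independently around their planted means.
* Reported log2 fold-changes are unshrunken MLEs: a gene observed as all
  zeros in one condition cell gets an extreme estimate (with a
  correspondingly enormous standard error). Robust summaries of planted
  effect recovery use medians for this reason; a prior-count option would
  be the natural extension.
* The term-map generator plants annotation rates, not DAG-coherent
  biology: a planted enriched term's ancestors become enriched through
  propagation, which is correct behaviour but inflates the count of
  significant terms relative to the planted count; the most-specific
  reduction removes them.
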