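# Methods

This note records the models, conventions and numerical choices behind
`famvar`, and what the synthetic-data-backed tests do and do not establish.

## Variant representation

Coordinates are 1-based VCF convention; every interval test is inclusive at
both ends. At ingestion each allele pair is reduced to its minimal anchored
representation: shared trailing bases are trimmed first, then shared leading
bases (advancing the position), always retaining one base per allele. This
makes equivalent spellings of the same indel compare equal (e.g.
`CAAAT>CT` and `CAAA>C` at the same anchor). Full repeat-aware
left-alignment would require the reference sequence, which is deliberately
not an input of the loaders; within a single jointly processed dataset the
anchored-minimal form is sufficient for matching, and the indel
reconciliation step flags any comparison-set indel within 10 bp whose
representation still differs, for manual review, rather than guessing.

Missing genotypes are first-class (`None`) and never imputed. Half-missing
calls such as `./1` are treated as missing — the conservative reading, since
published counts imply complete genotypes in the members that matter.
Multiallelic sites are split into biallelic records at load time.

## Filter cascade

Filters 1–5 are pure per-variant predicates, so their application order
cannot change the stage-6 input set (tested by permutation); stage 6
(segregation) is family-relative and runs last. Numeric conventions: the
rarity thresholds are strict (`< 0.01`), the CADD threshold inclusive
(`≥ 10`), the splice window `≤ 2 bp`, frameshift status
`|len(alt) − len(ref)| mod 3 ≠ 0`. An absent score never counts as damaging:
a variant must present positive evidence from CADD *and* one concordant
protein-level predictor. PolyPhen-2 is consumed as its textual categories.

Attrition accounting: the per-family column at each stage counts surviving
variants carried by at least one of that family's sequenced definite cases;
the stage-6 cell counts variants fully segregating in that family, and the
stage-6 "All" cell is the size of the union over families (a cross-family
variant is counted once). Tiers A and B and the visual-inspection status are
annotations; the pipeline never auto-removes a candidate for them.

Two non-equivalent readings of "not found in unaffected individuals"
coexist in the published tables; both are exposed:
`SegregationResult.absent_in_unaffected` is evaluated against the family's
own screened unaffecteds, while `unaffected_carrier_count` counts carriers
cohort-wide (the candidate table's `Unaff` column). Neither is asserted to
be "the" published semantics.

## Pedigree LOD engine

The two-point likelihood treats each individual's latent state as an ordered
pair of two-locus haplotypes (disease allele ∈ {d, D} × marker allele ∈
{1..k}). Founder haplotypes follow linkage-equilibrium priors with disease
allele frequency q = 0.01 and uniform marker allele frequencies (1/k by
default, overridable); transmission picks a parental strand with probability
½ and recombines marker against disease with probability θ; penetrance is
(f0, f1, f2) = (0, 1, 1) — dominant, fully penetrant, no phenocopies — with
affecteds-only coding: definite cases and obligate carriers are coded
affected (for obligates this encodes "carries the disease allele" exactly,
since f1 = f2 = 1 and f0 = 0), everyone else phenotype-unknown.

Summation is by variable elimination on the pedigree's factor graph,
contracting one individual at a time in reverse topological order through
`einsum` (children before parents keeps factor scopes small on
tree-structured pedigrees); each contraction is renormalized and the log
scale accumulated, so likelihoods far below float range are handled.
Mendelian-inconsistent marker data yield −∞ at the requested θ; data
impossible even at θ = ½ raise an error.

**Maximum possible LOD.** Each family's ceiling is the LOD at θ = 0 of a
deterministically constructed fully informative marker: founders carry
unique allele pairs and the disease haplotype is gene-dropped from the
single ancestral founder covering the most definite/obligate members, with
observations restricted to those included members. The construction fixes
the disease–marker phase of the introducing founder, and the likelihood is
evaluated with that phase known — that is what "simulating a marker that
co-segregates with the disease allele" means, and it makes each informative
meiosis contribute log10 2 (the parent-plus-two-affected-children pedigree
gives 2·log10 2 ≈ 0.602 in the q → 0 limit; at q = 0.01 the value is 0.591,
the residual being the marginalized possibility, present only in the θ = ½
denominator, that an untyped spouse carries the disease allele). Ordinary
markers are scored with phase marginalized, the standard two-point
behaviour. The deterministic construction was chosen over a Monte Carlo
expectation: it is reproducible and is the quantity the within-maximum
comparison needs.

The engine is verified against an independent full-joint enumeration (tensor
product over every individual's genotype simultaneously, no peeling) to
1e−8. Enumeration memory grows as (2k)^(2n), so the oracle runs on
pedigrees of up to 6 members with k = 2 marker alleles — already covering
founders, three-generation transmission, recombination at several θ and
untyped members; larger pedigrees are covered by closed-form cases
(LOD(θ=½) ≡ 0, the trio value, the dominance of the fully informative
marker over 100 random markers).

**Window annotation.** "Within a 10 Mb window centered on the variant" is
implemented as half-width 5 Mb, inclusive (configurable). The
within-maximum flag uses `family_max − window_lod ≤ 0.01 + 1e−9`; the 1e−9
guard avoids floating-point false negatives at the printed precision. For
the packaged candidate table the family maxima are the per-family maxima of
the printed window-LOD column except family F, whose reported maximum
possible LOD (1.12) exceeds all its printed window LODs (best 0.83) — the
documented reason no family-F candidate is flagged. Published-region
overlap uses 1-based inclusive intervals (a BED conversion helper is
provided): 1p34.3–36.13 as chr1:16,200,000–40,100,000 and 11q24–25 as
chr11:120,700,000–135,006,516 (hg19).

## Expression triage

CPM filtering keeps genes at ≥ 1 CPM in at least `min_samples` samples,
defaulting to the smallest group size; the boundary is inclusive and the
rule is scale-invariant by construction. TMM factors are computed against
the sample whose upper-quartile CPM is closest to the mean, trimming 30% of
M and 5% of A on each side and averaging with inverse delta-method variance
weights; factors are scaled to geometric mean 1.

The NB GLM engine is a batched IRLS (log link, per-sample log offsets
`log(library × factor)`, fixed per-gene dispersion) vectorized across genes;
convergence is declared when the last β step is < 1e−4 with a finite
likelihood, and non-converged genes are reported with absent p-values and
excluded from the BH adjustment. It matches statsmodels' Poisson GLM at
φ → 0 and its NB GLM at fixed α to 1e−5 in the tests — statsmodels is the
cross-check, never the fitting path, because the dispersion profile below
requires thousands of whole-transcriptome refits.

Cox–Reid dispersion: for a candidate φ, the adjusted profile log-likelihood
per gene is `ll(β̂(φ)) − ½ log det(XᵀWX)`. The common dispersion maximizes
the pooled APL on a 40-point log2 grid over φ ∈ [2⁻²⁰, 2⁶] with parabolic
refinement; tagwise estimates maximize
`APL_g(φ) + (prior_df / residual_df) · mean_g APL(φ)` — weighted-likelihood
empirical-Bayes shrinkage toward the common value whose strength is
prior_df (default 10) in effective extra degrees of freedom, with tagwise →
common as prior_df → ∞. Exact numerical equivalence with any particular
reference implementation is not a contract; the calibration properties are:
type-I error of the LRT at nominal 5% within ±1% on 20,000 null genes, and
logFC recovery bias below 0.1 at 30 + 30 samples.

Design: intercept, group (aneurysm = 1), standardized age, sex
(female = 1), and rupture as a single indicator (ruptured = 1, all controls
and unruptured 0) — rupture is nested within group, so a full factor would
be collinear; non-full-rank designs are rejected with the offending columns
named. logFC is the group coefficient in log2 units, positive = higher in
aneurysm tissue. (The published candidate table prints the headline
differentially expressed gene with a negative sign while the accompanying
text calls it overexpressed; this package fixes the aneurysm-over-control
convention and the packaged fixture keeps the printed value, as a
transcription.)

## Synthetic cohorts

The generator's defaults mirror the study conditions: 7 three-generation
families; dominant founder variant with penetrance 1 and phenocopy rate 0;
unaffected members labeled screened only at age ≥ 45 (the younger
generation is left unknown); obligate carriers identified structurally
(unaffected members with an affected ancestor and an affected descendant);
sequencing covers affected members, obligates and screened unaffecteds; and
a 44 aneurysm vs 16 control count matrix at dispersion φ = 0.1 with
log-uniform library sizes of 5–20 million. Background variants draw each
filter's pass state independently at marginal rates (0.98, 0.30, 0.27,
0.82, 0.47 for filters 1–5) chosen to mirror exome-wide attrition
proportions, which gives the product-of-marginals null used in the
calibration test. The causal variant's annotation profile passes filters
2–5 by construction so that recovery tests isolate segregation logic, and
the phenocopy dial exists precisely because phenocopies (affected
non-carriers) are the documented failure mode of the strict segregation
criterion — a masked or phenocopy-broken family loses its variant under the
default strict missing-genotype policy, and the tests assert both
directions.

What the synthetic data do *not* emulate: linkage disequilibrium and
realistic marker maps, sequencing error and coverage structure, relatedness
between background-variant genotypes and annotation scores, and batch or
library-preparation artifacts in counts. Passing tests therefore
demonstrate correctness of the algorithms under their stated model, not
robustness to those real-data complications.

## Problem sizes

The acceptance script and test suite run at sizes chosen to exercise each
property with comfortable statistical margin on a single CPU: 200 simulated
families for recovery, 20,000 genes for null calibration (binomial SE of
the rejection rate ≈ 0.0015), 2,000 genes / 50 planted for logFC recovery,
36 engine-vs-enumeration LOD comparisons across three pedigree shapes and
three θ values, and 10,000 background variants for the marginal-product
check (3-SD binomial band).
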