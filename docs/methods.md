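# Methods

## Decay-cluster model

All classification operates on stage-aggregated log expression
E(s) = log₂(mean FPKM(s) + c) with pseudocount c = 1, so E ≥ 0 and a unit
difference in E is a 2-fold change of pseudocounted expression. Replicates
within a stage are combined by the arithmetic mean of FPKM *before* the
transform — the analysis targets one expression profile per stage, and
averaging on the linear scale keeps the maternal-selection threshold
(mean GV FPKM strictly > 2) and the log-margin rules operating on the same
quantity.

The four cluster predicates (README table) use margin m = 1 with the strict
and non-strict inequalities exactly as written, so boundary genes classify
deterministically. Their mutual exclusivity is provable pairwise: I and III
split on E(zyg) ≤ E(8c)+m versus >, II and IV likewise, and {I, III} versus
{II, IV} split on E(GV) > E(zyg)+m versus ≤. The predicates are *not*
exhaustive — genes whose expression rises more than 2-fold from GV to zygote
satisfy none of them — so an UNCLASSIFIED label is carried explicitly,
preserving the accounting identity
|I|+|II|+|III|+|IV|+|UNCLASSIFIED| = |selected maternal genes|.

The morula extension applies the identical 2-fold rule to Cluster IV genes
only: degraded iff E(8-cell) > E(morula) + m. With no morula stage in the
matrix the flag is `not_applicable` rather than silently false.

### ZGA-dependence calling

The α-amanitin contrast compares a control and a transcription-blocked
matrix over the zygote and a post-ZGA stage. The post-ZGA stage defaults to
the 8-cell stage — the human major-ZGA stage, and the stage to which the
inhibited embryos are cultured — although it is configurable, as is the
orientation of the pre-selection ratio. Pre-selection keeps Cluster II/III
genes whose control pseudocounted FPKM(post)/FPKM(zygote) < 0.5; among
these, "stabilized by transcription block" is not a published numeric rule,
so the package defines it as the same 2-fold convention used everywhere
else: dependent iff the treated drop E(zyg) − E(post) < 1 while the control
drop is ≥ 1. Both thresholds sit in `ClassifierConfig`
(`decay_ratio_threshold`, `stabilization_margin`).

## 3′-UTR features

Motif scanning is exact string matching in the DNA alphabet after U→T
normalization, counting **every matching start position**: overlapping
occurrences each count, and a position matching two motif variants would
count once per variant (the CPE and PAS variant pairs cannot actually
co-match at one position). Overlap counting is a deliberate choice — the
alternative non-overlapping scan cannot be distinguished from published
figure values — and is pinned by an independent sliding-window oracle in the
tests. Scanning is strand-specific by construction; minus-strand BED
intervals are reverse-complemented at load time so every sequence reads
5′→3′ of the transcript. When a gene carries several annotated UTRs the
longest is kept. Zero-length UTRs and genes without UTR annotation are
excluded from comparisons and counted in the returned report.

Class comparisons use the two-tailed pooled-variance Student's *t*-test
(Welch behind a flag), with box-plot summaries (median, quartiles, 2.5/97.5
percentile whiskers, mean ± SEM).

## Embryo QC and defect calling

Correlation and PCA operate on log₂(FPKM+1). PCA follows R `prcomp`
semantics: embryos are observations, genes are features, centered per gene,
unscaled, coordinates from SVD. For reproducibility each component is
oriented so its largest-magnitude loading is positive — a deterministic
convention replacing the arbitrary SVD sign.

Set-overlap significance uses the upper-tail hypergeometric probability
P(X ≥ |A∩B|) (one-sided Fisher model). A *t*-test on a set overlap is not
well defined, so no attempt is made to reproduce one; the hypergeometric
choice is recorded in each result object.

The M-decay caller takes a marker panel (six maternal transcripts in the
default design) measured in ≥3 replicates per group. A marker is
*accumulated* when its test/control mean fold change exceeds 1 **and** a
one-way ANOVA across the groups is significant at α = 0.05; the defect
requires ≥4 of the 6 detected markers. With fewer than six detected markers
the threshold scales proportionally (⌈4·detected/6⌉); with fewer than four
detected the call is INDETERMINATE. The accumulation fold threshold is a
parameter (`fold_threshold`): the default 1.0 leans on the significance
requirement rather than a fixed effect size, matching a "significant
accumulation" criterion; a stricter 2-fold convention is one argument away.
The ANOVA is computed from sums of squares directly so the degenerate
noise-free cases are well defined: all-identical data give F = 0, p = 1;
zero within-group variance with a real between-group difference gives
F = ∞, p = 0.

The Z-decay caller partitions genes by Group A (degraded > 2-fold
zygote→8-cell in normal embryos, E_arr(8c) ≥ E_norm(zyg) − 1 in the arrested
embryo) and Group B (zygotically increased > 2-fold normally, not in the
arrested embryo); the two groups are disjoint by construction. The defect
flag tests whether normally-degraded transcripts are enriched among the
embryo's *accumulated* transcripts — genes above normal 8-cell levels by
more than the margin (E_arr(8c) > E_norm(8c) + 1) — via the hypergeometric
upper tail. Defining the enrichment's B-set relative to normal 8-cell
embryos rather than to the zygote keeps the test informative: "not below
zygote level" is also true of every stably expressed gene, which would make
the draw coextensive with the universe and the p-value identically 1.

Cohort concordance screening (`concordant_subset`) greedily removes the
embryo with the lowest mean correlation to the rest until the subset's mean
pairwise r reaches `r_min` (default 0.7). This is an explicit heuristic for
an informally described practice; it is deterministic and recorded, not an
inference procedure. No multiple-testing correction is applied across genes
by default; Benjamini–Hochberg is available (`benjamini_hochberg`).

## qPCR model

Relative level = 2^(Ct_ref − Ct_gene): one cycle earlier ≈ 2-fold more
template. The literal exponent order 2^(Ct_gene − Ct_ref) would invert
abundance (an abundant transcript has a *low* Ct) but is kept available as
`convention="literal"` for exact comparison against analyses that used it.
Technical triplicates are averaged on the Ct scale (geometric on the linear
scale, matching amplification physics); biological replicates are averaged
on the linear scale. Undetermined Ct values are an error by default, with
optional ceiling imputation at Ct = 40, the detection limit of a 40-cycle
run. No amplification-efficiency correction is attempted.

## Synthetic-data model

The generator emulates the study's input conditions:

* **Baseline.** GV log₂-FPKM ~ Normal(5, 1.5) — a typical detected-gene
  FPKM distribution centered near 32. Maternal-class baselines are floored
  at 1.05·d²/(d−2) (≈8.4 at decay fold d = 4) so that, at noise 0, both
  transitions of a Cluster III gene clear the 2-fold margin and every
  maternal gene clears FPKM > 2; non-maternal genes draw uniformly below
  the selection threshold. The floor truncates roughly the bottom decile of
  the log-normal — accepted as the price of an exactly recoverable truth.
* **Decay.** Deterministic fold drops of d = 4 (one margin beyond the
  2-fold rule) at each planted transition; class proportions default to the
  published cluster sizes 2372:2259:1109:1531; 176/1531 of Cluster IV genes
  additionally lose their transcript by the morula stage.
* **Noise.** Multiplicative log-normal on FPKM — additive Gaussian with
  σ = 0.25 on the log₂ scale — applied independently per sample, with two
  replicate samples per stage. This reproduces the scatter the log-scale
  analysis sees but not real RNA-seq features such as length/GC bias,
  dropout at low expression, or library-size variation: passing recovery
  tests demonstrates correctness of the decision rules under calibrated
  noise, not robustness to every artifact of single-embryo libraries.
* **α-amanitin pair.** 90% of Cluster II/III genes are planted
  ZGA-dependent (human Z-decay is predominantly transcription-dependent);
  dependent genes keep their zygote level through the 8-cell stage in the
  treated matrix.
* **UTRs.** Uniform-ACGT background; Poisson-planted CPE/PAS copies at
  non-overlapping recorded positions. Z-decay UTRs are twice as long
  (mean 1000 vs 500 nt) with twice the planted motif rate (2 vs 1 expected
  copies per UTR), so background matches — which the truth absorbs by
  recording the post-hoc scanned count as authoritative — preserve the 2×
  rate ratio.
* **Arrested cohorts.** Defective embryos stabilize the planted M- (or Z-)
  decay target set at 4-fold above control and down-shift the
  decay-machinery genes (BTG4/CNOT7/CNOT6L-like) 4-fold; marker tables
  carry three test and three control replicates.
* **Ct tables.** Ct = ref_ct − log₂(level) (+ optional Gaussian noise);
  exact inverse of the 2^ΔCt transform at noise 0.

All generators take a mandatory seed, use one `numpy.random.Generator`, and
share no global state.

## Problem sizes and numerical choices

The test-suite and acceptance-script problem sizes are chosen to make the
statistical claims sharp while keeping a full run near interactive speed:
10⁵ fuzz triples for rule exclusivity, 10⁴ genes for recovery rates, 10⁴
random sequences against the motif oracle, complete enumeration of every
universe up to size 12 for the hypergeometric check, 200 embryos for
defect-caller operating characteristics, and 2000 UTRs per class for the
motif-rate ratio (3-standard-error band). Equality tolerances: identities
expected exact in floating point (ANOVA F = t², Ct round-trip,
hypergeometric vs enumeration) are asserted at ≤1e−10 relative or ≤1e−12
absolute; planted-truth recovery thresholds (100% at noise 0, ≥95%
clustering / ≥90% detection at σ = 0.25, ≤5% false positives) are fixed
properties of the stated noise conditions.

## Known limitations

* FPKM is consumed as given; no re-normalization, no count-level modeling.
* The classifier is threshold-based by design — no spline/mixture temporal
  clustering — so genes near a margin flip under noise; replicates and the
  4-fold planted effects in simulation quantify that sensitivity.
* Motif scanning is exact-match only (no PWM or degenerate consensus).
* The concordance screen and the Z-decay enrichment flag are the package's
  own formalizations of informally described procedures and are documented
  as such above.
* Annotation genome build is a configuration value (`source_genome_id`);
  the package does not reconcile mixed-build inputs.
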