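# Methods

This note documents the statistical model behind each pipeline stage, the
tunable parameters and their defaults, what the synthetic cohorts do and
do not emulate, and the numerical/design choices made where the protocol
left room.

## Measurement model

Two technologies feed the pipeline, both reduced to a feature-by-sample
matrix (`ExpressionMatrix`) tagged with its scale:

* **NGS counts.** Read counts per miRNA per serum sample, with per-sample
  library-size (depth) variation and heavy sparsity: most annotated miRNAs
  are undetected in most serum samples.
* **qPCR Ct.** Cycle-threshold values, normalized against an exogenous
  spike-in (cel-miR-2-3p, added at fixed copy number before extraction):
  ΔCt = Ct(spike) − Ct(miRNA). One PCR cycle is one doubling, so ΔCt is a
  log2-scale abundance; higher ΔCt means more abundant. Fold changes
  between groups are therefore `2**|mean ΔCt difference|` and group shifts
  planted by the simulator are additive on the ΔCt scale.

## Discovery stage

**Prevalence filters.** A miRNA is removed when its zero-count fraction is
*strictly* greater than the threshold; the cascade runs at 0.50 and then
0.45. The second filter mathematically subsumes the first (asserted as a
test property); both are run so the audit log reports the same two-step
funnel a study protocol would.

**Normalization.** CPM (counts per million by total column count) plus a
pseudocount (default 1.0). Total-count normalization is a deliberate,
documented substitution for TMM: the contribution being implemented is the
filter/test cascade, not a particular normalization. *Known limitation:*
total-count normalization is sensitive to composition — a very abundant,
strongly shifted feature inflates its group's library sizes and biases the
apparent fold change of every other feature. With thousands of features
and moderate effects this bias is negligible; in tiny artificial matrices
it is not (the test suite uses feature-rich cohorts for exactly this
reason).

**Exact conditional negative-binomial test.** For one feature with group
counts summing to s₁ and s₂ (s = s₁ + s₂), the test conditions on s and
asks whether s₁ is surprising under equal expression proportions:

* dispersion φ = 0 (Poisson limit): s₁ | s ~ Binomial(s, L₁/(L₁+L₂)),
  with L the summed library sizes.
* φ > 0: counts are first scaled to the geometric-mean library size; each
  group sum is then negative binomial with mean nᵢμ and size nᵢ/φ (μ the
  common per-sample mean under the null), and the conditional law follows
  by convolution: P(K = k | s) ∝ NB(k; n₁μ, φ/n₁) · NB(s−k; n₂μ, φ/n₂).

Two-sided p-value: twice the smaller tail including the observed point,
capped at 1 — simple, conventional, and stated. A feature with zero counts
everywhere returns p = 1 with a `flat` flag rather than an error. For
totals above 200 000 the conditional law is effectively Gaussian and a
normal approximation with continuity correction is used (mean s·n₁/(n₁+n₂),
variance v₁v₂/(v₁+v₂)); the switch point is far above where the
approximation becomes accurate to a few percent.

**Dispersion.** Method of moments on library-size-scaled counts:
φ̂ = max(0, (s² − m̄)/m̄²) per feature; the common dispersion is the median
across features, estimated within each contrast group and pooled with
degree-of-freedom weights so planted group shifts do not inflate it. This
is a deliberately simple estimator; it recovers a true common dispersion
to about ±0.1 at realistic sizes (tested) and is biased upward by zero
inflation, which makes the exact test conservative rather than
anticonservative on sparse features.

**Rank-sum arm.** Mann–Whitney U on log2-CPM (rank-equivalent to CPM
itself; the log is for display symmetry only). Exact enumeration when
n₁+n₂ ≤ 12 with no ties, otherwise the normal approximation with tie and
continuity corrections (delegated to scipy, which implements exactly this
contract; the test suite checks the exact branch against full permutation
enumeration).

**Candidate selection.** `members = (exact-test hits ∩ rank-sum hits)
− stage-inconsistent + literature`. Hit thresholds: p < 0.05 for both
tests and |log2 FC| > 2.0 for the exact-test arm, all strict and compared
on unrounded values. The stage-consistency rule removes intersection
members whose all-stages-pooled-vs-benign rank-sum p is ≥ 0.05; a config
switch (`stage_rule="per_stage"`) instead requires every individual stage
to pass, since the protocol wording does not disambiguate the two
readings. Literature markers (default miR-497-5p, miR-21-5p, miR-205-5p)
are configuration data, not logic; one absent from the expression universe
is included with a warning.

## Validation stage

Spike-in normalization requires a complete spike row (an undetermined
spike reaction invalidates the sample's normalization, so it is an error,
not a missing value). A candidate validates when rank-sum p < 0.05 **and**
linear fold change ≥ 1.5. The fold-change gate is *inclusive*: published
candidate lists retain markers whose printed fold change sits exactly at
1.5, implying the comparison was made on unrounded values; an inclusive
comparison reproduces that behaviour for effects planted exactly at the
gate. A marker missing in more than 50% of either group is reported
`undetermined` and excluded from the validated set (the threshold is this
package's rule; qPCR practice shows the phenomenon but no standard
cutoff). Per-marker ROCs are oriented so the case group's mean scores
high (orientation recorded; the raw unoriented AUC is kept alongside).

## UDR and panel optimization

The UDR of a sample is the mean linear expression of the panel's
up-regulated members divided by that of its down-regulated members.
Two choices required a decision:

* **Scale.** "Expression level" in the score's definition is taken as
  linear relative expression — `2**ΔCt` for qPCR, CPM + pseudocount for
  NGS — because ΔCt can be negative and would break the ratio. A
  `udr_log_scale` switch computes the log-UDR (difference of mean log2
  expression, i.e. the geometric-mean ratio) for sensitivity analysis;
  for independent log2-normal members this variant has the closed-form
  population AUC Φ(Δ/√(2(1/N+1/M))), which the test suite uses as an
  analytic oracle.
* **Missingness.** A sample missing any panel member is skipped and
  logged, never imputed (an opt-in mean-of-available-members fallback
  exists but is off by default). The ratio-of-means construction makes the
  score fairly robust to a missing member, but silently changing a panel's
  effective membership per sample would blur what was evaluated.

Directions are fixed per marker from the validation contrast before any
search; the search explores subsets only, never direction flips.
Exhaustive enumeration of all (2^N − 1)(2^M − 1) panels is used when that
space has at most 4096 panels (the 6-marker space of interest has 31);
sequential backward elimination — repeatedly removing the member whose
removal most improves the AUC, stopping when no removal strictly improves
it — is used for larger spaces and is always available explicitly. AUC
ties between removals are broken by removing the lexicographically
smallest feature ID, making the path deterministic. Greedy elimination
can never beat the exhaustive search; this dominance is property-tested.

**Parsimony.** Among the evaluated panels, those within
`parsimony_epsilon` (default 0.02 AUC) of the best are kept and sorted by
size ascending, then AUC descending. The 0.02 default is this package's
choice: it is the slack that prefers a 3- or 4-marker panel over a
6-marker panel whose AUC is a few points lower, matching how a compact
clinical panel would be chosen in practice.

## ROC, AUC and confidence intervals

AUC is the tie-adjusted rank statistic (concordant + half the tied pairs,
over n₁n₂), identical to the trapezoidal area under the empirical ROC;
curve points come from scikit-learn. The 95% CI is a seeded, stratified
(cases and controls resampled separately) bootstrap percentile interval
with 2000 resamples by default — the CI method of the original analysis
software is unknown, so a standard, fully specified one is used instead.
Exact agreement with any particular software dialect's p-values or CIs is
not claimed.

## Cohort summary

Counts and percentages (one decimal) for the whole cohort and per group;
stage and histology tabulated within the cancer group only. Between-group
tests: chi-squared with continuity correction for 2×2 categorical tables,
Fisher's exact test when any expected cell is below 5, and a two-sided
rank-sum test for age (the original age test is unnamed; the choice is
flagged in the output's `test` column). Degenerate cohorts (one group
absent) report percentages without p-values.

## Synthetic cohorts

`SyntheticDesign` is a blueprint: group sizes, per-feature generative
parameters, technology settings, a seed. Every feature draws from an
independent RNG substream keyed by (seed, hash of feature ID), so adding
or removing a feature never perturbs the others — fixtures stay stable.

* qPCR: ΔCt(f, s) = baseline + effect·1[case stage] + Normal(0, σ);
  Ct = spike Ct − ΔCt; optional per-feature missing-reaction probability
  plants undetermined markers. Effects may differ by stage (early-only
  effects exercise the stage-consistency rule).
* NGS: count = 0 with the structural-zero probability, else negative
  binomial with mean libsize·proportion·2^effect and the feature's
  dispersion; library sizes uniform over a range.

Calibration links connect planted shifts to reported quantities:
√2·σ·Φ⁻¹(AUC) for a target AUC, and the inverse of the expected rank-sum
z for a target p-value at given group sizes (both tested by round-trip
simulation).

The **study-condition designs** encode the published cohorts. Validation:
35 benign / 10 per stage I–IV; the 15 candidate markers planted at their
published early-stage fold changes, each marker's within-group σ solved so
the *expected* rank-sum p equals its published p (this single calibration
also reproduces the published per-marker AUC range, because the rank-sum z
and the AUC are two views of the same statistic); late-stage shifts
attenuated to 60% of early-stage, reflecting the early-stage focus of the
filtering; the qPCR-undetermined marker planted with 70% missing
reactions. Discovery: 16 benign / 19-8-12-21 across stages; the 21
published discovery hits planted at their |log2 FC| (two with stage-I-only
effects), in a 2656-feature long-tailed background with tiered
structural-zero probabilities so the prevalence cascade removes roughly
the published fractions. The within-group σ values and the zero-inflation
tiers are free parameters of the emulation (the source cohorts report no
variance components); they are stated here and in the design code and
fixed once.

What the generator does **not** emulate: inter-marker correlation
(miRNAs are drawn independently; real co-regulated miRNAs are not),
amplification-efficiency differences between qPCR assays, hemolysis and
other pre-analytic artifacts, batch effects, and any linkage between
demographics and expression. Passing tests therefore show that the
*pipeline machinery* behaves correctly under a faithful marginal model of
the data, not that the selected markers would generalize clinically.

## Problem sizes and determinism

The test suite and the benchmark script run at desk scale by design:
calibration recoveries use 5000 cases / 5000 controls (single-marker AUC
reproduced to ±0.01); planted-recovery and noise-elimination properties
use 100 seeded replicates at 35/20 or 200/200; null calibration of the
exact count test uses 1000 features; pipeline smoke tests use cohorts of
several hundred to 2656 features. All randomness flows from explicit
seeds (design seeds for generation, `RunConfig.seed` for bootstrap CIs),
so two runs with identical inputs and configuration produce byte-identical
report bundles.

## Known limitations

* Total-count (CPM) normalization instead of TMM: composition bias under
  extreme, abundant effects (see Discovery). The differential-test
  interface isolates the count test so a different backend could be
  swapped in.
* The method-of-moments dispersion conflates biological dispersion with
  zero inflation, making the exact test conservative on sparse features.
* Markers whose true fold change sits exactly at a filter boundary
  (|log2 FC| = 2.0 in discovery, FC = 1.5 in validation) are retained in
  roughly half of replicate cohorts — an intrinsic property of thresholding
  a noisy estimate at its own expectation, visible in replicate simulations
  at the published group sizes.
* With very strong planted effects at small cohort sizes the panel AUC
  saturates at 1.0, and backward elimination (strict-improvement stopping)
  then has no gradient to act on: it stops at the full panel. Noise-member
  elimination is identifiable only in non-saturated regimes.
* No cross-validation or train/test machinery: discovery and validation
  cohorts are evaluated separately, mirroring the study design, and panel
  AUCs evaluated on the same cohort used to select the panel are
  optimistically biased.
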