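# Methods

## Data model

A study is two genotype-count triplets — cases and controls, each
(T1T1, T1T2, T2T2) — plus optional design metadata. Counts are kept in the
column order of the source tables; the package never infers which allele is
"variant" from observed frequencies, because silent relabeling is the
classic way meta-analyses of genotype tables go wrong. A dataset is an
ordered list of studies of one SNP; order affects report layout only, and a
test asserts every statistic is permutation-invariant.

The interchange CSV (`study_id,year,case_11,...,ctrl_22` plus optional
metadata columns) is comma-separated UTF-8 with a required header; tabs are
accepted via a flag, `#` lines are comments. Metadata enums parse
case-insensitively from fixed tokens so quality scoring is deterministic.

## Effect measures

Each of the four genetic models (homozygote T2T2 vs T1T1, heterozygote
T1T2 vs T1T1, dominant T1T2+T2T2 vs T1T1, recessive T2T2 vs T1T1+T1T2)
collapses a study to a 2×2 table. The per-study effect is the sample odds
ratio with the Woolf standard error on the log scale; CIs use
z = 1.959964 rather than 1.96, matching the output conventions of the
legacy software whose tables the bundled data come from (the difference is
invisible at 2 decimals but keeping it explicit makes oracle comparisons
well defined). Two-sided p-values come from the normal distribution of
log OR / SE and are reported at full precision; rendering ("<0.001") is a
report-layer concern.

Continuity correction: the default adds 0.5 to all four cells only when
some cell is zero ("halves-when-zero"); `none` and `halves-always` are
available. The bundled tables never hit a zero cell, so the policy only
matters for user or simulated data. A table with an empty margin (e.g. no
exposed subjects in either arm) is refused even with correction — the odds
ratio is genuinely undefined there, and fabricating one from correction
constants would only launder noise.

## Pooling and heterogeneity

Cochran's Q is computed about the inverse-variance fixed pooled log OR with
weights 1/SE²; I² = max(0,(Q−df)/Q); τ² is the DerSimonian–Laird moment
estimator truncated at zero (so τ² = 0 whenever Q ≤ df, and random-effects
results then coincide with inverse-variance fixed results; note
statsmodels leaves τ² negative in that regime, which the oracle tests
account for).

Fixed-effects pooling defaults to Mantel–Haenszel on the raw cell counts
with the Robins–Breslow–Greenland variance for log OR_MH; inverse-variance
weighting is a config option. The source analysis named no estimator; MH
is the convention of the software it used, and on these homogeneous data
the two agree within 0.01 on every contrast (asserted by tests). Q is
always computed from the inverse-variance fixed centre even when MH
pooling is selected: deterministic, standard, and indistinguishable at the
2-decimal precision of interest. (The published per-contrast heterogeneity
p-values agree with ours to ≈0.03; they are treated as descriptive and not
asserted beyond the non-significance flag.)

Model selection follows the heterogeneity gate: DerSimonian–Laird random
effects iff Q's p-value < alpha (default 0.05, strict inequality; 0.10 is
a common alternative and available in config), otherwise the configured
fixed method. All contrasts of all three bundled SNPs select fixed
effects.

Leave-one-out sensitivity re-runs the gated pipeline k times, each
omitting one study (k ≥ 3 required so every reduced set still pools).

## Hardy–Weinberg and quality scoring

HWE in controls uses the Pearson χ² with expected counts from the sample
allele frequency (1 df, no continuity correction, alpha 0.05); an exact
test is out of scope since only the equilibrium flag feeds downstream. A
monomorphic arm returns "in equilibrium" with a flag instead of raising —
the test is vacuous, not failed.

The quality rubric awards 0–3 points in five categories (case source,
control source, genotyping specimen, HWE in controls, total sample size
with bands ≥1000/≥500/≥200); totals of 10+ are "high quality". Applying
the rubric literally to the Webb study gives 11 (mixed cases 2 +
volunteer controls 2 + mixed specimens 1 + HWE 3 + size 3), one point
below the score its original reviewers reported; the package keeps the
literal 11 and stores the reported 12 alongside for comparison. Sample
size for scoring is the article-level enrolment, which can exceed a
per-SNP genotype-row total when not every subject was genotyped at every
SNP — dataset validation surfaces that as an informational finding rather
than an error.

## Publication-bias diagnostics

Egger's test is the OLS regression of the standardised effect θᵢ/SEᵢ on
precision 1/SEᵢ, t-testing the intercept on k−2 df. Begg's test is
Kendall's τ (tau-b for ties) between the variance-standardised deviates
from the fixed pooled estimate and the sampling variances; p is the exact
permutation tail for k ≤ 8 (cheap and exact at these sizes), else the
normal approximation on the Kendall score with continuity correction.
Both require k ≥ 3: for a two-study dataset the report marks them "not
estimable" instead of silently emitting a meaningless number (Egger has 0
residual df at k = 2). Funnel output is coordinates only (points, pooled
reference line, 95% pseudo-CI wedge over an SE grid); rendering is left to
the caller.

## Synthetic data

The generator emulates the structure of the bundled tables: control
genotypes are multinomial draws from Hardy–Weinberg proportions at variant
allele frequency q; case probabilities are the control probabilities
tilted by (1, OR_het, OR_hom) and renormalised. Between-study
heterogeneity, when requested, adds one Normal(0, τ²) shift per study to
both log ORs before normalisation — on the same scale as the
random-effects model being tested. Each study draws from a generator
spawned from the master seed with the study index as spawn key, so counts
depend only on (seed, index), never on generation order.

Defaults are the package's reference study conditions: q = 0.3 (a common
variant, matching the 0.30–0.37 control frequencies of the bundled data),
OR_het = 1, OR_hom = 0.7, 1,000 subjects per arm, k = 50, τ = 0. With
OR_het = 1 the homozygote- and recessive-contrast population ORs both
equal OR_hom exactly, which is what makes the recovery experiment sharp.

What the generator does not emulate: linkage disequilibrium, covariates,
population stratification, genotyping error, or selective publication.
Passing simulation tests therefore show the estimators are correct under
the stated sampling model, not that real literatures are free of
confounding or selection.

## Problem sizes and numerical checks

The stochastic test battery uses 500 replicates of the k = 50 recovery
design (mean pooled OR within [0.68, 0.72], CI coverage within
[0.92, 0.97]) and 1,000 null replicates of a k = 10 design for Egger's
type-I error (within [0.03, 0.08]); HWE p-uniformity uses 2,000 arms of
n = 1,000. Reproduction of the published tables compares values rounded
half-up to 2 decimals with tolerance 0.01, absorbing the source's own
rounding. Ties and degenerate inputs: identical precisions make Egger's
regressor constant (raised as an error); identical effects give Q = 0,
I² = 0; duplicated studies pool to the single-study estimate.

## Known limitations

No allelic/trend contrast, meta-regression, subgroup synthesis, Peto
method, REML/profile-likelihood τ², trim-and-fill, or figure rendering.
Per-study p-values in the bundled reference are 2-decimal printings and
are not asserted beyond the OR/CI cells.
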