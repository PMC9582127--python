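# Methods

## Scope and data model

`credmeta` synthesizes case–control genetic-association evidence at the
level of study × variant × disease genotype-count records.  One input row
carries the six genotype counts (three per arm), the study's publication
year, and an ethnicity label drawn from {Asian, Caucasian, African,
Other}.  Upstream curation — deduplication of overlapping populations,
selection of the most recent/most complete dataset per population — is
assumed already applied to the input table.  Within each (variant,
disease) group the earliest publication year marks the first-published
study; ties break lexicographically on `study_id` so the flag is
deterministic.

Analyses are keyed by (variant, disease, stratum, genetic model).  The
Overall stratum pools all rows of the group, including any "Other"
category; each ethnicity with at least `min_datasets` rows is analysed as
its own stratum.

## Allele orientation

The effect allele is the minor allele of the *pooled* controls of the
group, decided once and applied to every record.  Orienting per study
would let sampling noise near MAF 0.5 flip the effect direction of
individual studies inside one pooled analysis; orienting by the pooled
frequency makes the derived 2×2 tables invariant to how the input file
happened to label the alleles (a property-tested guarantee).  At a pooled
MAF of exactly 0.5 the orientation is genuinely ambiguous and the input
labeling is kept.

## Effect estimation and pooling

Per-study log odds ratios use the Woolf estimator with SE
√(Σ 1/cell).  When any of the four cells is zero, 0.5 is added to all four
cells of that study (the convention of the classic Stata `metan` routine);
a study with an empty exposure margin in both arms carries no information
about the OR and is dropped with a logged warning rather than an error.
An association is pooled only when at least three informative datasets
remain — below that the result is a skip marker with its reason.

The primary fixed-effect estimator is Mantel–Haenszel on the (continuity-
corrected) counts with the Robins–Breslow–Greenland variance; the
inverse-variance estimator is retained as a cross-check and the two agree
within 2% on dense homogeneous tables (tested).  Cochran's Q is always
computed with inverse-variance weights about the inverse-variance fixed
mean (the Higgins convention), I² = max(0, 100·(Q−df)/Q), and a single
study gives Q = 0, df = 0, p = 1 by convention.  The DerSimonian–Laird
τ² is the method-of-moments value max(0, (Q−df)/(Σw − Σw²/Σw)); at τ² = 0
random-effects pooling reduces exactly to fixed inverse-variance pooling
(tested, and cross-checked against R's `metafor`).  The random-effects
model is *selected* iff the Q test's p < 0.1 — the boundary p = 0.1 keeps
the fixed model — and its CI uses plain normal theory (no Knapp–Hartung),
matching the software era of the synthesized literature.  Both fits are
always computed and logged; the report shows the selected one.
Throughout, the 95% CI uses z = 1.959964 and two-sided p-values come from
the standard normal.

## Bias diagnostics

*Egger*: OLS of the standardized effect (lnOR/SE) on precision (1/SE);
two-sided t-test on the intercept with k−2 df.  The literature sometimes
cites "modified" Egger variants without specifying them; the package
implements classic Egger as primary and exposes the Harbord score test
(Z/√V regressed on √V from the 2×2 counts) behind the `egger_method`
config switch.  *Begg*: Kendall rank correlation between
variance-standardized deviations from the pooled fixed estimate and the
variances, with tie-corrected variance and the (|S|−1) continuity
correction; the normal approximation is used, which is adequate from
k ≈ 30 (the null-uniformity property is tested there) and conservative
below.  *Excess significance*: observed count of studies individually
significant at 0.05 versus the sum of their powers to detect the pooled
effect; χ² goodness-of-fit on the two bins, exact binomial tail below
k = 10; flagged only when observed > expected.  This test is disabled by
default (most genotype-count literatures cannot support it) and excluded
from verdicts unless enabled.  All diagnostics require k ≥ 3 and are
recorded as absent otherwise; "bias detected" means any available test
p < 0.1.

## Sensitivity analyses

For each significant association: leave-one-out re-pooling (absent when
k−1 would fall below the three-dataset minimum), exclusion of studies
whose controls fail the Hardy–Weinberg χ² test at α = 0.05 (plain Pearson,
1 df, no continuity correction; monomorphic controls pass trivially), and
exclusion of the first-published study.  Each re-analysis re-applies the
full procedure including fixed/random re-selection, but inherits the full
analysis' allele orientation.  "Robust" is operationalized as: every
available re-analysis preserves the effect direction and nominal
significance (p < 0.05).  The qualitative "did not alter the summary OR"
criterion used in narrative synopses needs some testable rule; this one is
declared, not inferred.  HWE screening is applied only inside this
sensitivity battery — the primary pass keeps all studies.

## Credibility grading

Amount of evidence counts subjects (alleles under the allelic model) in
the least-common exposure group summed over cases and controls — the
original Venice recommendation — gradable instead on total sample size via
`amount_basis="total"`.  Boundaries: exactly 100 or 1000 → B.
Replication grades I² at A ≤ 25 < B < 50 ≤ C.  Protection from bias is C
when a bias test fires, a sensitivity check fails, or the pooled OR lies
in (0.87, 1.15) without an explicit genome-wide-confirmed flag (supplied
per association in the config; default false); B when the bias or
sensitivity inputs are unavailable; A otherwise.

FPRP uses the observed two-sided p of the selected pooled model as α and
the normal-approximation power to detect OR 1.5 (protective estimates:
1/1.5) at that α, with prior 0.05.  Published FPRP columns in some
synopses track the printed p-values so closely that they imply an
effective prior near 0.5; the package implements the formula with the
prior as an explicit parameter and makes no attempt to reproduce such
columns digit-for-digit.  Grades: strong < 0.05 ≤ moderate ≤ 0.2 < weak
(noteworthiness is strict < 0.2).  The final verdict takes the Venice
class (AAA strong / any-C weak / else moderate), upgraded one level by a
strong FPRP and downgraded one by a weak FPRP, clamped to [Weak, Strong].
In grading-only mode (pre-pooled summary rows), α is recovered from the
printed OR and CI via SE = ln(CI_hi/CI_lo)/(2·1.959964).

## Synthetic data

The generator draws, per study, a log OR from Normal(ln ψ, τ²); control
genotypes multinomially at HWE proportions (q², 2q(1−q), (1−q)²); and case
genotypes with probabilities proportional to the control probabilities
times (1, ψᵢ, ψᵢ²).  Under this multiplicative model the allelic OR
target equals ψ, making parameter recovery well defined, while dominant
and recessive ORs follow deterministically from ψ and the MAF (and exceed
ψ for risk alleles, as the worked example shows).  HWE violation is an
inbreeding-like heterozygote deficit (a configurable fraction of
heterozygote mass moved to the homozygotes, default 0.3); publication
censoring retains a non-significant study (allelic p ≥ 0.05) only with
probability `censor_nonsignificant`.  Defaults — k = 4, ψ = 1.5,
MAF 0.3, 1000/1000 per study, τ² = 0, no censoring, no HWE violation —
mirror a typical stratum of the synthesized candidate-gene literature
(3–14 datasets, on the order of 10³ cases and controls).

What the generator does *not* emulate: linkage disequilibrium between
variants, covariate confounding (smoking in particular), genotyping error
beyond the HWE distortion, and overlapping control series.  Passing
recovery and calibration tests therefore certify the statistical machinery
under the model's own assumptions, not robustness to those real-data
complications.

## Numerical and testing choices

Simulation sizes in the test suite are deliberately modest: calibration
checks (type-I error of the pooled test and of Egger's test at their
nominal levels, judged against 99% binomial bands over 1,000 replicates)
run at k = 10 with per-study n = 500, and parameter-recovery/coverage
checks at k = 20, n = 1000 over 200 replicates — large enough for the
binomial bands to be meaningful, small enough that the full suite runs in
well under a minute.  Power-style checks (publication censoring inflating
Egger's flag rate; retained-significant-only sets inflating the
excess-significance flag rate) are sized so the effect being detected is
actually present in the simulated design — e.g. censoring is imposed on
under-powered studies of a modest true effect (ψ = 1.2), since two-sided
censoring of a pure null retains both tails and produces no funnel
asymmetry at all.

Known limitations: no Peto or exact conditional estimators; no
meta-regression; no trim-and-fill or selection-model corrections; the
normal-theory CIs can undercover for very sparse recessive tables, where
the continuity correction dominates; X-chromosome and multi-allelic
variants are out of scope.
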