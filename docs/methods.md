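# Methods

## Phase contrasts and candidate selection

The six differentiation stages are treated as ordered groups: phase A
compares the stem spheroid SR1 (baseline) with the progenitor spheroid
SR2; phase B compares the pooled spheroids {SR1, SR2} with the early
adherent progeny {AD1, AD2}; phase C compares {AD1, AD2} with the late
progeny {AD3, AD4}. For a gene g and contrast (B, C):

* Δβ(g) = mean_C β(g) − mean_B β(g), an unweighted mean of stage values
  per group (groups of one stage are that stage's value; no variance
  filter is applied — the contrasts are thresholded point estimates, not
  tests);
* FC(g) = mean_C E(g) / mean_B E(g) on the linear intensity scale.

A gene is a differentially methylated region (DMR) when |Δβ| ≥ 0.10 and
a differentially expressed gene (DEG) when FC ≥ 1.5 or FC ≤ 1/1.5. Both
thresholds are closed; a tolerance of 10⁻⁹ absorbs floating-point
rounding at exact boundaries (e.g. group means of 0.60 − 0.50).
Candidates are the discordant intersections only: hypomethylated + up
(Δβ ≤ −0.10 ∧ FC ≥ 1.5) or hypermethylated + down. Concordant pairs and
single-omic hits are discarded. The pooled candidate count tallies
distinct (gene, phase) pairs, so a gene recurring in two phases counts
twice — consistent with summing per-phase tallies.

Promoter windows are the 2 kb span ±1 kb around the TSS, 0-based
half-open (BED convention), clipped at coordinate 0, strand-independent.
Sample QC retains samples with a uniquely-mapped read fraction ≥ 0.40
(boundary inclusive).

## Recurrent risk score

Per gene and cohort, five dichotomisation thresholds are the sample
quantiles at p ∈ {0.25, 1/3, 0.50, 2/3, 0.75} (linear interpolation
between order statistics — numpy's default — pinned for
reproducibility; at least 10 analysable patients are required, and a
constant value vector is flagged degenerate). Ties at a threshold go to
the low arm. Three endpoints administratively censor follow-up at 18
months, 36 months, and not at all.

Each of the 15 cutoff × endpoint conditions runs a two-group log-rank
test: at each distinct event time t, with n at risk (n₁ in the low arm)
and d events (d₁ low), the statistic accumulates O₁ = Σd₁,
E₁ = Σ d·n₁/n and the hypergeometric variance
V = Σ d·(n₁/n)(1−n₁/n)(n−d)/(n−1); χ² = (O₁−E₁)²/V on 1 df. The test is
implemented in-package because the vote needs the direction (sign of
O₁−E₁, the arm with more observed than expected events is "inferior")
alongside the p-value; it is cross-checked in the test suite against a
brute-force per-event-time 2×2 oracle and against lifelines. Two-sided
p-values with the direction read post hoc are used; α = 0.05 by default
and exposed as a parameter. No multiple-testing correction is applied
inside the grid or across genes — the dual-cohort concordance
requirement is the de facto error control (a Benjamini–Hochberg option
across genes could be layered on by callers; it is deliberately not a
default).

Votes: +1 if p < α and the low arm is inferior; −1 if p < α and the
high arm is inferior; 0 otherwise, including degenerate conditions
(empty arm, no events, zero variance), which keeps the 15-vote total
defined for every gene. The RRS total is the signed sum, an integer in
[−15, 15].

Dual-cohort selection follows the stricter reading — both totals > +1
(i.e. ≥ 2) for hypomethylation risk, both < −1 for hypermethylation
risk; the looser sign-only reading (both > 0 / both < 0) is available
via `mode="sign"`.

## Signature coding and survival evaluation

Each signature gene carries a risk direction and a cutoff. A gene counts
toward a patient's risk tally when its value is ≤ cutoff
(low-value-at-risk; ties at the cutoff count as at risk) or > cutoff
(high-value-at-risk). Risk groups are 0–1 / 2 / ≥3 genes at risk;
patients missing any signature gene are excluded complete-case (no
imputation rule is defined for this analysis).

When a signature is derived from RRS selections, the direction follows
the RRS sign (positive totals → low values at risk) and the per-gene
cutoff is the grid threshold with the smallest overall-endpoint log-rank
p in the reference cohort (ties break toward the lower cutoff; the
median is the configurable fallback). The source data do not pin which
cutoff dichotomises each signature gene, so this choice — consistent
with the RRS machinery itself — is a declared design decision.

Kaplan–Meier estimation, the k-sample log-rank test and Cox
proportional-hazards fits are delegated to lifelines. Censoring ties at
an event time are processed after the event (standard product-limit
convention); Cox ties use the Efron approximation, with Wald CIs and
p-values. Categorical covariates are dummy-coded against fixed reference
levels: risk group "0–1", stage "early", grade "G1", debulk "optimal";
reference rows are reported with HR fixed at 1. A warning is issued
below 10 events per parameter; non-finite estimates are flagged
non-estimable rather than raised. `survival_at` evaluates the KM step
function right-continuously (post-step value at an event time, last step
value beyond follow-up).

## Immune context

Correlation between a gene's level and an infiltration score is Pearson
by default (the scatter relationship of interest is linear on the log
scale), with Spearman available for bounded methylation betas. Joint
strata split both axes at their medians (ties to the low arm; cutpoints
exposed as parameters), yield four strata, and compare survival with the
k-group log-rank test; empty strata are reported with n = 0 and excluded
(df reduced). The worst stratum is the one with the lowest 60-month
survival, ties broken by the final step value and then by the fixed
stratum order high/high, high/low, low/high, low/low.

## Synthetic-data generator

The generator emulates the study conditions end to end.

**Stage omics.** Defaults: 6000 genes; planted per-phase counts at the
published tallies (A: 95 hypo-up / 184 hyper-down; B: 32/1; C: 3/21);
baseline betas uniform on [0.2, 0.8] (away from the unit-interval edges
so planted shifts never clip, and wide enough that all five quantile
cutoffs are distinct downstream); expression log-normal around 100.
A planted gene realises exactly ±Δβ (default 0.25) and FC (default 2.0,
required > 1.5) in its own phase contrast at zero noise and is flat in
the other two contrasts; planted sets are pairwise disjoint by
construction. Per-stage Gaussian beta noise (default sd 0.01) and
log-normal expression noise (default sd 0.05) are small enough that a
null gene crosses the 0.10 delta threshold with probability < 10⁻⁶
(enforced at configuration time via the worst-case single-stage
contrast); effect magnitudes are chosen for clean separation since the
source data report only candidate counts, not effect sizes.

**Survival cohorts.** Two independent cohorts (default 300 patients
each, emulating the two validation databases) with per-gene betas
uniform on [0.2, 0.8]. Event times are exponential with hazard
h = h₀ · Π HRᵢ^{at-riskᵢ} · Π covariate multipliers, h₀ = 0.02/month;
a risk gene's multiplier applies when the patient's beta is on the risk
side of the cohort median (below for hypomethylation risk). The
exponential proportional-hazards form is the simplest model consistent
with Cox evaluation and makes hazard ratios exactly recoverable.
Censoring is exponential (0.005/month) plus administrative truncation at
120 months of follow-up. Clinical covariates (stage 30/70 early/late,
grade 15/35/50 G1/G2/G3, debulk 60/40 optimal/suboptimal) are drawn
independently and are hazard-linked only when `covariate_hrs` is set —
off by default so signature-recovery tests are unconfounded; the
multivariate Cox tests switch it on. Default risk genes are the five
signature genes at HR 2.5 each, hypomethylation direction.

**Immune profiles.** Scores are standard normal; a planted
(gene, cell, sign) link adds the standardised log-expression of the gene
so that the marginal correlation is sign·ρ with ρ = 0.5 (comfortably
above the 0.3 recovery bar at the default cohort size). A separate
scenario generator plants a hazard multiplier on the joint
gene-high × infiltrate-high stratum for testing the four-way survival
comparison.

What the generator does *not* emulate: read-level sequencing, probe
effects, copy-number or mutation layers, correlated gene-gene structure,
non-proportional hazards, informative censoring, and batch effects.
Passing tests therefore demonstrate correctness of the analytic chain
under its stated model, not robustness to those real-data features.

## Problem sizes and numerics

The bundled checks run the integration at the full 6000-gene scale
(sub-second) and size the Monte-Carlo suites at 200 replicates for null
calibration (n = 100/cohort), 40 replicates for risk-gene recovery
(n = 300/cohort), 30 replicates for joint-strata identification
(n = 400) and single 2000-patient cohorts for Cox recovery — large
enough for stable pass/fail margins at the stated bounds. All
randomness flows through numpy `SeedSequence` streams derived from the
user seed; identical configurations reproduce byte-identical outputs.

## Known limitations

* Endpoint handling uses administrative censoring at 18/36 months; a
  landmark binary analysis is a plausible alternative reading and is not
  implemented.
* The published clinical hazard ratios and 60-month survival
  probabilities depend on proprietary patient cohorts and are treated as
  structural references only; the package reproduces the machinery and
  its planted-truth behaviour, not those numbers.
* The log-rank direction is read post hoc from a two-sided test;
  one-sided variants are not offered.
* Cox models assume proportional hazards throughout; no time-dependent
  covariates or competing risks.
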