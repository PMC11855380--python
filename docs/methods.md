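# Methods

## Model

Patients are assumed to fall into k latent molecular subgroups. After
feature selection and per-feature standardization, the joint stacked
matrix X ∈ ℝ^{n×d} is modelled as a mixture of k Gaussians with diagonal
covariances:

p(xᵢ) = Σ_c w_c · N(xᵢ; μ_c, diag σ²_c),  Σ_c w_c = 1.

Diagonal covariances are a deliberate restriction: after stacking several
omics blocks, d routinely exceeds n, and full covariance estimates would be
singular. A variance floor of 1e-6 (in standardized units) keeps every
component density proper, so no E-step can encounter a singular component;
the degenerate n = k case saturates at the floor by design.

Subtype validity is judged by survival separation, not by an information
criterion: the hard assignment (per-row argmax of the posterior
responsibilities, ties to the lowest component index) is tested with the
multi-group log-rank statistic. This matches the use case — a subtyping is
useful insofar as the groups differ clinically.

## Cox screening (FSbyCox)

Each feature is standardized (so β is per SD) and fit univariately by
Newton–Raphson on the Breslow-tie partial likelihood; convergence is a
Newton step below 1e-9 within 50 iterations, with step-halving on any
likelihood decrease. Standard errors come from the observed information;
p-values from the normal approximation of β̂/se. Degenerate inputs —
constant features, cohorts with no observed events, monotone likelihoods
(|β̂| beyond 50 per SD) — are flagged non-converged with p = 1 and excluded
from selection rather than raised: real omics matrices contain such columns
routinely. Breslow rather than Efron tie handling is used for its
simplicity; with continuous synthetic survival times ties never occur, and
with real data the difference is second-order at the screening stage.

The default threshold p < 0.05 (strict inequality) is exposed as a flag, as
is an optional cap keeping only the smallest-p features.

A screening limitation worth knowing: a feature that isolates a
*middle*-hazard group (high values ↔ intermediate survival) has a weak
*marginal* hazard association, because the pooled remaining groups average
to a similar hazard. Such features can be missed by any univariate
monotone-hazard screen; with three or more survival-ordered groups the
selected set therefore under-represents features contrasting the middle
group.

## EM and EM*

Classical EM alternates the exact E-step (responsibilities via log-sum-exp)
and M-step (weighted moments; empty components — total responsibility below
1e-12 — are re-seeded at the currently worst-explained sample and logged).
Convergence: relative log-likelihood gain below 1e-6, at most 200
iterations. The log-likelihood trace is non-decreasing (asserted in tests
with 1e-8 slack for floating-point).

EM* accelerates this by structure-based data segregation. After each
E-step over the active set, every active sample is pushed into the max-heap
of its best-matching component, keyed by its log density under that
component; the root thus holds the best-explained member. The top
`settle_quantile` fraction of each heap (default 0.5; floor rounding, so a
singleton heap never settles) is frozen — its responsibilities and
log-likelihood contribution stop being recomputed — and only the remaining
active samples are re-scored. Every `recheck_every` iterations (default 5)
all settled samples are re-scored once and reactivated if their
best-matching component changed. The M-step always uses all n rows: frozen
responsibilities for settled samples, fresh ones for active. A final full
pass over all samples produces the reported log-likelihood and assignment.

Convergence of EM* uses the objective with frozen settled contributions:
since settled terms are constants between rechecks, the objective changes
only through the active samples, and iteration stops when its relative
change drops below the same 1e-6. Two properties anchor this
reconstruction, since the original active/settled policy is described only
qualitatively:

* **EM limit.** As `settle_quantile` → 0 nothing ever settles and the EM*
  iteration is *exactly* classical EM — identical trace to 1e-10 at the
  same seed (tested).
* **Agreement.** On well-separated mixtures the two solvers reach the same
  partition (ARI ≥ 0.95) with final log-likelihoods within 1% (tested).

Cost is measured in per-sample per-component density evaluations — a
hardware-independent counter incremented by every E-step, recheck and the
final pass. On separated data the active set halves per iteration, so EM*'s
total is ≈ 2n·k plus recheck/final overhead versus EM's (iterations)·n·k.

Initialization: `random` draws k distinct samples as means; `kmeanspp`
uses D²-proportional sampling. Weights start uniform, variances at the
per-feature global variance. Because initialization is the dominant source
of run-to-run variability, the fitting entry point runs 10 restarts
(seeds `seed+i`) by default and keeps the highest final log-likelihood.

## Survival statistics

The Kaplan–Meier estimator and the g-group log-rank test are implemented
directly (and cross-checked against lifelines in the test suite).
Conventions: censoring tied with an event time counts the censored sample
at risk for that event ("event first"); the log-rank statistic uses the
full hypergeometric variance–covariance of (O−E) over the first g−1 groups
— exact for any g, unlike the sum-of-marginals shortcut — and p-values are
reported at full precision with no lower clipping. An all-censored cohort
yields the empty step set (S ≡ 1) and log-rank p = 1 with a warning.

## Differential expression

Effect size is log2(mean+1) differences between tumor-subtype and
reference samples (pseudocount 1; computed as a difference of logs so a
group swap negates it exactly). The test is Welch's two-sample t on
log2(x+1) values. The call rule is |log2FC| ≥ 3.5 (inclusive) AND raw
p < 0.05 (strict); Benjamini–Hochberg adjusted p-values are reported for
transparency but deliberately do not gate the call — the rule is the raw-p
fold-change gate, and the top-N ranking (default 50) orders significant
hits by |log2FC|, ties by smaller p. This plain two-sample screen does not
include empirical-Bayes variance moderation; with the small per-feature
sample sizes of typical subtype-vs-normal contrasts, moderated tests would
be more powerful for borderline features.

## Synthetic cohorts

The generator emulates exactly the structure the pipeline assumes: k latent
groups drawn from the mixing weights; per-omics *signal* features with
group means on a regular simplex (feature j uses simplex coordinate
j mod k, so every signal feature is informative) scaled so group centroids
sit `separation` per-feature SDs apart within each k-feature block, unit
SD; *noise* features standard normal for all groups; survival exponential
with group-specific mean (`hazard_scales`, days — defaults spread
geometrically from one year); right-censoring with probability
`censor_rate` at a uniform time strictly before the event, which is valid
censoring by construction. Exponential survival was chosen over Weibull
because it satisfies proportional hazards exactly and has closed-form
means for tests. Everything is reproducible bit-for-bit from the seed.

Deliberately absent: bounded methylation beta distributions, count noise,
batch effects, informative censoring, and omics-specific feature
correlation. Passing tests therefore demonstrate the statistical machinery
under its own model assumptions, not robustness to real-data pathologies.

## Problem sizes

Tests and the reproduction script use cohorts of 150–500 patients with
tens to ~1000 stacked features — comfortably beyond the regime where the
estimators' asymptotics apply, while keeping the full suite under a
minute of compute. Calibration rates use 400–1000 Monte-Carlo replicates
(Cox type-I error 500, log-rank 1000, DE null 2000 features), matching the
precision of the acceptance bands.

## File formats

Matrices are TSV/CSV (auto-detected), first row feature IDs, first column
sample IDs. Cells empty or `NA` are median-imputed per feature; features
with > 20% missing are dropped, both logged. Clinical tables are
`sample_id / time / event` (days; event 1 = death observed). Sample
alignment takes the intersection across all inputs in lexicographic order
— determinism is the requirement, the order itself is arbitrary.
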