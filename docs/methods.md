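# Methods

## The integrated measure

A dexterity trial yields two outcomes on different scales: a completion
time (continuous, seconds) and an error count (small non-negative
integer). The integrated measure puts them on a common footing by ranking
all `N` pooled trials of a study on each channel and summing the two
percent deviations from the mean rank `R̄ = (N+1)/2`:

    im = (R_t − R̄)/R̄ + (R_e − R̄)/R̄ .

Design choices that are load-bearing:

* **Pooling.** Ranks are computed over all trials of a study jointly — 80
  for the 20×4 crossover, 22 for the 11×2 retest — not within arms. Each
  subject therefore carries one score per condition/session, and arm-level
  summaries are means over those per-subject scores.
* **Midranks for ties.** Error counts are small integers, so ties are
  common. Midranks keep the rank total at `N(N+1)/2` exactly, which makes
  the study's scores sum to zero in exact arithmetic (checked to ≤1e−9 in
  floating point). Any other tie rule would break the zero-sum property.
* **Denominator.** Deviations are expressed relative to the *mean rank*.
  This bounds each channel's contribution to `±(N−1)/(N+1)` and the sum to
  roughly ±2, and gives arm means of a few tenths for realistic designs.
* **Sign convention.** Slower times and more errors get higher ranks, so a
  positive score is poorer-than-average performance. Figure-style output
  multiplies by 100 and reports "percent from the study mean".

The measure is a pure function of the two rank vectors, hence invariant to
any strictly increasing transform of either raw channel and antisymmetric
under reversing the performance order of a tie-free study. Times are
stored at millisecond precision; transform invariance accordingly holds
for maps that keep millisecond-separated times distinct.

## Statistical analyses

**Test–retest.** Per-subject (day 1, day 2) score pairs are compared with
the Pearson product-moment correlation, with the two-sided p from the
exact t transform on n−2 df (n = 11 is small; a normal approximation would
be sloppy). A paired t-test on the same pairs screens for a systematic
session difference such as a learning effect, and Shapiro–Wilk (Royston
approximation) checks each session's scores for normality. All p-values
in the package are two-sided.

**Construct validity.** The scored crossover is pivoted into a complete
`n × k` within-subject matrix (an incomplete crossover is an error naming
the subject and arm). Mauchly's W is the determinant/trace ratio of the
covariance of the k−1 orthonormal within-subject contrasts,

    W = det(S) / (tr(S)/(k−1))^(k−1),

referred to χ² with `k(k−1)/2 − 1` df through the standard small-sample
multiplier `(n−1)·[1 − (2p² + p + 2)/(6p(n−1))]` with `p = k−1`. The
one-way repeated-measures ANOVA uses the within-subjects decomposition
`SS_total = SS_subjects + SS_conditions + SS_error`,
`F = MS_conditions/MS_error` on `(k−1, (n−1)(k−1))` df, with **no
sphericity correction by default** (the analysis is designed for data that
pass Mauchly's test; Greenhouse–Geisser/Huynh–Feldt epsilons are out of
scope). Post-hoc, all `C = k(k−1)/2` unordered pairs are compared with
paired t (least significant difference) tests; the corrected p is
`min(1, C·p_lsd)` — all possible pairs count, not only the
baseline-versus-intervention ones — and confidence intervals are
Bonferroni-adjusted to family-wise 95% (per-comparison `1 − α/C`) by
default, with an unadjusted option, since reporting conventions differ.
Pair differences are reported first-minus-second in the canonical
condition order (baseline, fatigue, stress, fatigue+stress), so
baseline-versus-intervention differences are negative when interventions
impair performance. These engines are implemented from their definitions
and cross-checked in the tests against pingouin (Mauchly, RM-ANOVA),
closed-form algebra (r, paired t) and R's `shapiro.test` (Shapiro–Wilk).

## Workload interference score

The stress intervention (identifying playing cards while tracing) is
justified by Wickens-style multiple-resources reasoning. The package
scores the interference of two concurrent tasks on a 0–8 scale as

    score = demand(a) + demand(b) + |resources(a) ∩ resources(b)|

with demand ∈ {automatic = 0, simple = 1, difficult = 2} and resources
drawn from the 3-D+1 set {perception, cognition, response,
visual_channel}. This demand-plus-conflict decomposition is a
reconstruction: it is the minimal scheme consistent with the two anchors
the design uses (the card dual task, two simple tasks sharing perception
and cognition, scores 4; the scale tops out at 8 for two difficult tasks
in full conflict). How a given total splits between demand and conflict
is not otherwise constrained.

## Synthetic data generator

The generator emulates the joint structure the analyses assume, not any
particular subject pool. Completion times are lognormal,

    time_ij = exp(log T0 + u_i + β_c + ε_ij),

with `T0 = base_median_time_s = 180 s`, subject effect SD 0.25 (log
scale), residual SD 0.10, and condition effects β of 0 (baseline), 0.18
(fatigue), 0.18 (stress) and 0.25 (combined) applied to both channels.
Error counts are negative binomial with mean `12·exp(v_i + β_c)` and
variance `mean·(1 + 0.15)`; the subject rate effect v has SD 0.35 and
correlates with u at `skill_correlation = 0.9` (a dexterous subject is
both fast and accurate — without this coupling a composite of the two
channels could not be highly reliable). The linear (NB1-style)
overdispersion was chosen over a quadratic one because at a base rate of
12 errors a quadratic term would drown the between-subject signal and cap
the achievable test–retest reliability well below what a usable
instrument exhibits.

Counts are realized through a Gaussian-copula quantile: the trial's count
is the negative-binomial quantile at Φ(w) of a standard-normal latent w.
In the retest study *all* subject-level latents — u, v and w — correlate
across the two sessions at `retest_stability = 0.9`, while the time
residual ε stays independent. Treating the count realization (not just
the underlying rate) as a stable subject trait is a modeling choice: it
makes the stability parameter meaningful for a count channel whose
Poisson-level noise would otherwise put a hard ceiling (≈0.65) on the
achievable reliability, and it makes the perfect-stability limit exact —
at stability 1 with zero time residual, session two reproduces session
one verbatim. Under these defaults the simulated 11-subject retest
correlation has median ≈ 0.83 (1000 replicates), and the crossover's
baseline-versus-intervention differences in mean integrated measure come
out at roughly 0.4–0.7.

What the generator does **not** emulate: period/carry-over effects of the
crossover (conditions act identically at every position), learning across
sessions, speed–accuracy *trade-offs* (the subject coupling is positive;
real populations may contain slow-but-careful subjects, which would shrink
within-arm SDs of the composite), and any biomechanical or cognitive
mechanism behind the fatigue and stress effects — interventions act purely
as log-scale shifts. Passing tests therefore demonstrate that the
pipeline recovers the structure this family of models injects, not that
the star-track test behaves this way in humans.

One master seed drives everything through derived streams (schedule,
subject effects, residuals), so identical configuration and seed give
byte-identical pipeline artifacts.

## Numerical and interface choices

* Times are stored in seconds at millisecond precision; trials CSV and
  STARTRACK v1 event-log writes are byte-stable and round-trip exactly.
* An arm with a single trial reports SD as NaN (undefined) rather than 0.
* Degenerate inputs fail loudly: all-identical studies (zero error
  variance), singular contrast covariances, constant non-zero paired
  differences and undefined correlations raise errors instead of
  returning NaNs.
* Mauchly's p uses the plain χ² upper tail; pingouin adds a higher-order
  correction term, so p-values agree closely but not to machine precision
  (W and χ² do).
* Analysis scripts and the default pipeline use simple randomization
  (independent uniform permutations per subject); a balanced Williams
  Latin-square allocation is available behind a flag for designs that
  must balance position effects.

## Problem sizes

The simulation-based checks use the study's own design sizes (20×4 and
11×2): 2000 null replicates for the ANOVA type-I calibration, 1000
replicates for reliability parameter recovery, 100 random instances per
oracle-equivalence check.

## Known limitations

* The sphericity-corrected ANOVA variants are deliberately absent; data
  that fail Mauchly's test need a different tool.
* The workload score collapses Wickens' dimensional conflict matrix to a
  shared-resource count; it ranks task pairings coarsely and is not a
  fitted cognitive model.
* The generator's parameters are a calibration, not estimates from any
  dataset; conclusions drawn from synthetic runs are properties of the
  generator.
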