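# Methods

## Statistical model

The analysis treats each (metric, tract) pair as one two-sample problem: per
subject a single scalar — the tract-mean of the metric — and a group label
(athlete/control). All group comparisons are two-sided Mann–Whitney *U* tests
computed from midranks. Significance is strict, p < α. Medians and IQRs use
linear interpolation between order statistics. Subjects are excluded listwise
per metric (a subject either contributes a full tract set for a metric or is
dropped for that metric); no imputation is performed.

Whether per-tract values entering the tests are tract-mean scalars or
profile-resolved values along the tract is a genuinely open design choice in
tractometry; this package assumes tract-mean scalars, which is also what the
single-WM-ROI summary (the subject mean over all 72 tracts, i.e. the tract
sum divided by 72) presupposes.

### Mann–Whitney modes

* **asymptotic** — U from midranks, tie-corrected null variance
  n₁n₂/12·[(N+1) − Σ(t³−t)/(N(N−1))], continuity correction 0.5, two-sided
  normal p. Degenerate input (all values identical) returns p = 1 with a flag.
* **exact** — the full permutation distribution of U over all C(N, n₁) label
  assignments; without ties via a cached dynamic program over rank sums, with
  ties by enumeration (feasible to N ≈ 16). Two-sided p is twice the smaller
  tail, capped at 1.
* **auto** — exact when N ≤ 12, asymptotic otherwise. The threshold keeps the
  permutation engine fast and is configurable. At the study's group sizes
  (~20 per group) auto always selects the asymptotic test, so the omnibus
  engine uses the asymptotic path for observed and permuted labels alike —
  the comparison is internally consistent by construction.

## Permutation omnibus

The multiplicity device is not per-test correction (deliberately absent, as
in the exploratory design this mirrors) but an omnibus statistic: T = the
number of tracts significant at per-tract α ∈ {0.05, 0.01}. Group labels are
reshuffled uniformly over assignments preserving group sizes (full label
permutation, not sign-flipping); all per-tract tests are recomputed per
permutation. Ranks are computed once per tract — a permutation only
re-selects which rows enter the group-1 rank sum — so B permutations reduce
to one (B×n)·(n×T) matrix product per metric.

Two p-value rules are provided:

* `strict_greater` — the fraction of null counts strictly above T_obs. This
  is the literal description of the procedure being reproduced but can return
  exactly 0.
* `ge_plus_one` (default) — (1 + #{null ≥ T_obs})/(B + 1), a valid
  Monte-Carlo p with floor 1/(B+1). Reported values such as 10⁻⁴ at B = 10⁴
  correspond to this floor.

The null 95th percentile q95 uses the empirical-CDF (inverted-CDF) quantile:
the smallest integer q with ≥95% of null counts ≤ q. It is interpreted as the
largest number of false-positive tracts expected under exchangeability. A
metric is flagged as exceeding its null when T_obs > q95 and the omnibus
p < 0.05.

For a fixed seed the same permutation sequence drives every metric whose
retained subject roster has the same size and ordering; per-metric omnibus
p-values are therefore comparable but mutually dependent (a documented,
deliberate property).

Under independent tracts (ρ = 0) the null count is Binomial(72, α̂) with α̂
the achieved size of the discrete U test (≈0.048 at n = 20/21 with continuity
correction), and the simulated q95 reproduces the Binomial(72, 0.05) 95th
percentile (7). Under realistic inter-tract correlation the null count is
much more dispersed — q95 of 15–22 at ρ ≈ 0.5 — which is exactly why the
independence-based expectation cannot be used as the threshold.

## Effect sizes and the null bound

Cohen's *d* with pooled SD ((n₁+n₂−2)-denominator), athlete minus control, so
positive d for DKI FA means higher anisotropy in athletes. The significance
threshold for |d| is the half-width of its null (1−α) interval:

* `normal` (default): z_{1−α/2}·√((n₁+n₂)/(n₁n₂)) — 0.6359 ≈ **0.64** for
  n₁ = n₂ = 19 at α = 0.05, matching the threshold in use for those group
  sizes. Rank-based effect sizes do not reproduce this value, which is why
  the pooled-SD d was adopted.
* `t`: the same with the central t quantile at n₁+n₂−2 df. This additionally
  absorbs the sampling variability of the pooled SD (0.658 at 19/19) and is
  strictly larger than the normal bound at any finite df.
* `montecarlo`: the empirical (1−α) quantile of the absolute standardized
  group-mean difference over ≥10⁵ null normal simulations with the population
  scale treated as known. This converges to the normal bound and serves as
  its stochastic check. (Simulating d with the *estimated* pooled SD instead
  would converge to the t bound — the distinction is exactly the known- vs
  estimated-scale choice, and the normal reading is the one consistent with
  the 0.64 value.)

Cross-metric "average" effect summaries for DTI and DKI are taken over the
four sub-metrics both modalities share (FA, MD, AD, RD) only.

## Correlations and deficits

Spearman r_s is the Pearson correlation of midranks after pairwise deletion;
p from the t-transform with n−2 df, or exact enumeration over all n!
orderings for n ≤ 8. Correlations of single-WM-ROI metrics with outcomes are
computed within the injured group only (CSF was sampled in athletes only in
the emulated design; an `athletes_only=False` flag enables exploratory
all-subject grids). Each cell reports its own n, so differing per-modality
missingness shows up per cell rather than collapsing the grid.

Cognitive raw scores are standardized against published norms,
z = (raw − mean)/SD, sign-flipped where a higher raw score is worse, so
negative z is always worse-than-norm. A deficit is z ≤ −1.5 (boundary
inclusive), the lowest Φ(−1.5) ≈ 6.7% of a normative population.

## Synthetic cohort generator

The generator emulates the *statistical structure* of a two-group concussion
tractometry study, not diffusion physics: no images, no tensor fits, no
spatial structure beyond a single equicorrelation ρ across tracts.

A scalar latent injury factor L (athletes |N(1, 0.25)|, controls 0) drives
every group difference: affected tracts shift by sign·δ·L in units of the
metric's scale; NfL = 150 + 70·L + N(0, 25²) ng/L floored at zero; cognitive
raws decline (or inventories rise) with L; SCAT5 severity and symptom counts
rise with L, clamped to their instrument ceilings (132 / 22). GFAP is
independent of L. Missingness drops whole subjects per modality (DTI 7%,
DKI 11%, neuropsychology 11%; 27% of athletes without CSF), reproducing the
differing per-modality n of real cohorts.

Calibration choices (fixed once, all defaults):

* Baseline centers are healthy-control single-ROI medians per metric; the
  tract-level noise SD is IQR/1.349 (normal-theory conversion) from the
  corresponding control IQRs.
* Inter-tract correlation ρ = 0.5 by default: it reproduces null q95 values
  in the 15–22 range observed in practice. Equicorrelation is the simplest
  structure with one testable knob; block structure would be a configuration
  extension, not the default.
* Effect deltas per metric are set so that affected-tract shifts reproduce
  the observed athlete-vs-control single-ROI median differences and roughly
  the observed per-metric significant-tract counts: DKI FA +3.1 SD on 52
  tracts, DKI RD −1.15 on 36, DKI AK +1.6 on 35, DKI RK −1.65 on 29, DKI MD
  −1.7 on 19, DKI MK −0.8 on 6, mild −1.0 shifts on 12–18 tracts for the DTI
  diffusivities, and no injected effect for DTI FA or DKI AD. Affected tracts
  are the first k indices (the analysis is index-blind, so the choice is
  immaterial).
* NfL coupling (70 ng/L per latent unit, residual SD 25) matches the athlete
  median (~220 ng/L) and an NfL–DKI-FA Spearman correlation of ~0.6. Under a
  single Gaussian factor these two targets and the NfL IQR cannot all be
  matched; the level and the correlation are the quantities the analysis
  actually tests, so they take precedence and the simulated NfL spread is
  narrower than real CSF panels.

What passing tests on this generator do **not** show: robustness to
heavy-tailed or heteroscedastic metrics, block-structured or
distance-decaying tract correlation, site/scanner effects, informative
missingness, or outcome couplings beyond a single factor. The nonparametric
tests make the calibration of marginals largely irrelevant to validity, but
power statements are specific to the equicorrelated Gaussian world.

## Numerical and design notes

* Quantile conventions: linear interpolation for medians/IQRs; inverted CDF
  for the integer q95.
* Exact-test enumeration guards: DP for tie-free exact U (any n), explicit
  enumeration otherwise, with automatic fallback to asymptotic (and a logged
  warning) beyond N = 16 with ties.
* Report percentages round half away from zero; raw fractions are always
  retained alongside.
* Determinism: every stochastic component takes an explicit seed; identical
  config + seed reproduces cohorts and permutation results byte-identically.
  Pipeline outputs embed the seed, thresholds and package version in a
  manifest sufficient to reproduce every numeric output.
* Problem sizes used by the test suite and the acceptance script (chosen as
  desk-scale defaults): B = 1500–10⁴ permutations; 500 null cohorts for
  type-I calibration; 40 preset seeds for signal recovery; 10⁵ draws for
  Monte-Carlo bounds and normative prevalence.

## Known limitations

* The omnibus engine is asymptotic-only inside permutations; at very small n
  (≲6 per group) its discrete size is conservative and the exact per-tract
  mode should be used for the observed comparisons instead.
* The strict_greater omnibus p can be exactly zero; use the default
  ge_plus_one rule whenever a valid p is needed.
* The generator's latent factor couples *all* affected modalities; it cannot
  represent dissociations (e.g. imaging changes without biomarker changes).
* No brain-surface or slice rendering: all outputs are tabular.
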