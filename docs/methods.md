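# Methods

This note documents the models, defaults and numerical choices behind
`painmap`, and what the synthetic generators do and do not emulate.

## Forward-model activation mapping

**Model.** Two groups of animals, each described by an M-vector of
region-wise FOS⁺ cell counts. Counts are standardized per region to
z-scores (pooled across both groups, mean 0, sample SD with ddof = 1).
A soft-margin linear SVM (libsvm, `C` default 1.0, deterministic at a
fixed seed) fitted on the z-scores gives the backward model
ŝ = Wᵀx + b, with K = 1 for a two-class problem. The forward model
x = Aŝ + ε re-expresses the discriminant in data space via

A = Σx W Σŝ⁻¹ with Σŝ = Wᵀ Σx W,

where the noise term ε is the residual and carries no stored parameter.
Positive Aₘ means higher z-scored activity in the alphabetically later
group label (e.g. MA over CON); the class order is exposed on the fitted
model so the sign convention is always explicit.

**Assumptions.** The pattern A is interpretable as "signal per region"
under the standard linear forward-model assumptions: the discriminative
signal is linear in the features and the covariance estimate is a
reasonable stand-in for the true Σx. With tiny cohorts the second
assumption is the binding one, hence shrinkage (below).

**Covariance shrinkage.** With N animals ≪ M regions the sample
covariance S is singular and Σŝ = WᵀSW can be degenerate. We use a
diagonal-target estimator Σ̂ = (1−s)·S + s·diag(S). The analytic
intensity (`shrinkage="auto"`) follows the variance-of-covariances rule:
s* = Σ_{i≠j} V̂ar(S_ij) / Σ_{i≠j} S_ij², clipped to [0, 1], where the
estimation variance of each off-diagonal entry is computed from the
per-animal outer products. Under near-independent features and small N
this drives s → 1 (diagonal covariance), which is the correct limit; with
strong real correlations and large N it vanishes. A singular Σŝ after
shrinkage raises an error that asks for more shrinkage rather than
silently pseudo-inverting.

**Scale behaviour.** A is equivariant, not invariant, to rescaling the
weights: replacing W by cW maps A to A/c (the numerator is linear in c
while Σŝ absorbs c²). The pattern *direction* — which determines every
ranking, contribution curve and sign readout — is invariant, and the
tests pin both the direction invariance and the exact 1/c law.

**Ranking and contribution.** Regions are ordered by descending |Aₘ|,
ties broken alphabetically by region name for determinism. The
cumulative contribution is the running sum of |A| over that order,
normalized by Σ|A|; the last value is clamped to exactly 1 to absorb
rounding. Degenerate (zero-variance) count columns are z-scored to 0 and
flagged rather than rejected, keeping wide atlas tables usable.

**Cross-validation.** Leave-one-out or stratified k-fold held-out
accuracy is offered as a descriptive sanity check; with 3 animals per
group no CV scheme has meaningful power, and the package does not
present these numbers as inference.

## Ethology

Ethograms are ordered, non-overlapping labeled bouts over a fixed action
alphabet (default: the 10-action repertoire running, trotting, stepping,
walking, rearing, hunching, right turning, curling-up, sniffing,
self-grooming). Analytics:

- **Proportions** are time-weighted by default (summed bout duration per
  label over total time); bout-weighted proportions are an option. Both
  sum to 1 exactly.
- **Transitions** are counted at the bout level between consecutive
  bouts, self-transitions included — consecutive same-label bouts are
  legal and counted, since sticky repertoires are themselves a phenotype.
  An optional pseudocount (default 0 for unbiased estimation, 0.5
  suggested for sparse chains) is added to every cell before row
  normalization. Labels with no observed outgoing transition produce an
  all-zero row with an explicit flag, never a silent uniform row.
- **Clustering** of repertoire vectors is agglomerative (Ward linkage,
  Euclidean distance) cut at k = 2 by default, matching the two-phenotype
  design.
- **Embedding** uses t-SNE with PCA initialization at a fixed seed;
  perplexity defaults to min(5, ⌊(N−1)/3⌋) for small cohorts. The linear
  SVM boundary fitted in the 2-D plane and its training accuracy are
  descriptive only — a 2-D embedding of a small cohort can always be
  partially separated, and the API documents the accuracy as such.
- **Differential actions** run the shared test selector per action and
  adjust p values across the action family with Benjamini–Hochberg.

## Classical assays

- **von Frey.** The ladder is the six-filament specification series
  1.65, 2.36, 2.44, 2.83, 3.22, 3.61 with 10 trials per filament. The
  threshold is the smallest filament with strictly more than 60 % positive
  trials (more than six of ten). Never-responding animals return a
  censored marker `"> max_filament"` with the ladder maximum as a numeric
  sentinel so rank-based group statistics remain usable. Filament values
  are ordinal scores as printed; no gram-force conversion is applied.
- **Open field.** 50 × 50 cm arena; the center zone is a concentric
  square whose side is `center_fraction` (default 0.5) of the arena side.
  Zone time counts samples inside divided by the sample rate; an entry is
  a strict outside→inside transition with a session starting inside
  counted as one entry; each path segment is attributed to the zone of
  its start point. No hysteresis band is applied by default. The center
  dimensions and entry rule are conventions of tracking software, not
  physical constants, so both are configuration-exposed.
- **Elevated plus maze.** Open arms 30 × 5 cm along ±x, closed arms
  30 × 5 cm along ±y, 5 × 5 cm center platform centered at the origin.
  Per-sample zone assignment partitions the session; zone metrics follow
  the open-field rules per zone class.

## Physiology

- **ΔF/F.** The isosbestic 410-nm channel is regressed onto the 470-nm
  signal channel by affine least squares over the whole recording; the
  fitted trace is F₀ and ΔF/F = (F470 − fit)/fit. This removes shared
  motion/bleaching artifacts and is invariant to a common gain on both
  channels. A zero-variance control falls back to a percentile baseline
  (default 10th) of the signal channel with a warning.
- **Peri-event analysis.** Segments are aligned at event times and
  baseline-subtracted by the mean of the pre-window, making the constant
  trace exactly zero. Events whose window leaves the recording are
  dropped and logged. AUC is the trapezoidal integral over (0, post]
  by default (window configurable), in ΔF/F·s.
- **Paired-pulse ratio** is peak2/peak1 on amplitude magnitudes of
  evoked currents (50/100/200 ms interstimulus intervals by convention);
  peak extraction from raw sweeps is out of scope.

## Statistics policy

Two-group comparisons use a recorded decision tree: Shapiro–Wilk per
sample and Levene across samples, both gated at p < 0.05 (the gate is a
documented default). Both normal and homoscedastic → pooled t; normal
but heteroscedastic → Welch t; otherwise two-sided Mann–Whitney U.
Samples too small for Shapiro–Wilk (n < 3) pass the normality gate;
constant samples are routed to the nonparametric branch. Family-wise
multiplicity uses Benjamini–Hochberg. Repeated-measures designs are out
of scope. Calibration is verified by simulation: empirical type-I error
on Gaussian and log-normal nulls and family FDP on full-null action
tables sit at the nominal 5 % within Monte-Carlo error (1000 reps).

## Synthetic data: what it emulates, and what it does not

Generators are seeded (`numpy` Generator; identical spec + seed is
bit-identical) and always return the ground truth alongside the data.

- **Region counts**: negative binomial per region, mean/dispersion
  parameterization (variance μ + μ²/θ, default μ = 200, θ = 10 —
  overdispersion typical of cell counts; magnitudes are free parameters,
  not calibrated to any published table). Group effects multiply chosen
  regions' second-group mean by exp(effect_log_fold). Not emulated:
  inter-region count correlations, imaging/registration artifacts.
- **Ethograms**: first-order Markov chains with exponential bout
  durations truncated at the session end (default 10-minute sessions).
  Not emulated: duration–transition coupling, non-stationarity within a
  session, observation noise in action labels.
- **Trajectories**: reflected random walk with an outward radial drift
  scaled by `center_avoidance`; step scale ties to `speed_scale` so zero
  speed is exactly stationary. Plus-maze walks reject moves leaving the
  maze polygon. Not emulated: thigmotaxis dynamics, bout-structured
  locomotion, body orientation.
- **Photometry**: shared baseline + linear drift + white Gaussian noise
  on both channels; the signal channel multiplies the baseline by
  (1 + ΔF/F transient), transients decaying exponentially (τ default
  1 s) at the event times. Not emulated: hemodynamic crosstalk,
  photobleaching nonlinearity, movement artifacts beyond the shared
  component.
- **von Frey**: binomial positives under a logistic psychometric curve
  centered on the true threshold.

Because these generators omit the artifacts listed, passing recovery
tests demonstrates correctness of the computations, not robustness of
the upstream measurements on real recordings.

## Problem sizes and numerical choices

Simulation-based checks run at: 100 random instances for the dense
Haufe oracle (tolerance 1e-10); 50 Gaussian cohorts of n = 200/group at
M = 10 for forward-model consistency; 100 planted-effect cohorts at
M = 129, n = 20/group, pooled Cohen's d = 3 (the matching negative-
binomial log-fold is solved numerically) for region recovery; ~1e5 bouts
for the Markov round trip (per-row total-variation bound 0.05); 1000
null replicates for type-I/FDP calibration and 200 for power; 100 random
paths for the zone-metric state-machine comparison. Null peri-event AUC
centering is assessed across 20 independent recordings of 100 trials
each, using the between-recording standard error, because trials within
one recording share the control fit and are weakly correlated. The
end-to-end run uses the full study scale (6 animals × 129 regions,
17 ten-minute ethograms) and completes in seconds on one CPU.

## Known limitations

- The activation pattern inherits all caveats of linear discriminant
  interpretation; with 3 animals/group it is a descriptive ranking, not
  a localization test.
- Auto shrinkage targets the diagonal; strongly correlated region blocks
  at tiny N will be over-regularized toward independence.
- Transition probabilities are bout-level; frame-level (duration-
  weighted) transition analysis would weight sticky actions differently.
- The embedding accuracy is training accuracy in a 2-D t-SNE plane and
  must not be read as generalization performance.
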