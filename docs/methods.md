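# Methods

This note records the package's modelling conventions, the design of the
synthetic-data generator, the calibration procedure behind the day-5
feedback simulation, and the numerical choices a maintainer would need to
reason about the results.

## Network metrics

**Clustering.** Watts–Strogatz node-averaged clustering: per node,
realized neighbor–neighbor links over possible ones; nodes of degree < 2
contribute 0.  **Path length.** Mean shortest-path length over ordered
node pairs at *finite* distance: disconnected pairs are excluded from
numerator and denominator.  Thresholded graphs are occasionally
disconnected, and this rule — applied identically to source graphs and
null graphs — keeps λ well defined and comparable without arbitrary
infinite-distance substitutes.

**Null model.** Maslov–Sneppen double-edge swaps: two edges (a,b),(c,d)
are replaced by (a,d),(c,b) when no self-loop or duplicate arises, with a
random orientation flip so edge directionality cannot bias the walk.  The
degree sequence is preserved exactly.  Defaults: 30 nulls per graph, ≥ 10
successful swaps per edge (a saturation warning reports the achieved
count if the proposal budget of 100·edges is exhausted — in practice only
reachable on pathological graphs).  Connectivity of nulls is *not*
enforced.  γ and λ normalize by the ensemble mean (not median).

**Thresholding.** Edges are the top `floor(s·n(n−1)/2)` node pairs by
|Z| (absolute-value ranking; floor so the requested sparsity is never
exceeded).  Ties at the cut break deterministically by ascending
(row, column) index, making graphs bit-reproducible.  |r| is clamped to
1−10⁻⁷ before the Fisher transform so duplicated channels stay finite.

## The feedback engine

Per block: the 15 s baseline span yields a σ sequence (trailing
128-sample windows), whose mean and sample SD define the score map
`score = 50(σᵢ + 3SD − σ_base)/(3SD)` clamped to [0, 100].  The 2 s
stimulus gap between baseline and regulation enters neither statistic.
A baseline with fewer than two windows or zero spread is refused — the
score map would be undefined.

Each block resets its own baseline (the protocol's block structure); a
session-level baseline is available via direct use of
`baseline_stats`/`feedback_score` but is not the default.  The
learning-curve statistic is the session mean regulation score minus 50:
reported group curves are of order ±3 points, i.e. baseline-relative,
which reconciles the 0–100 score range with learning-curve values near
zero.

The online refresh is nominally 3 Hz; at 25.6 Hz sampling the step is 8
samples (3.2 Hz), the closest integer stepping.  Scaled simulations
(cohort-level tests and the reproduction script) evaluate every 4th
update (step 32) with 10 nulls per update; window length, thresholding
and the score map are unchanged.

## The signal generator

Channels are zero-mean multivariate normal with covariance
`I + c·A`, where `A` is the latent adjacency and `c` the coupling
strength (default 1.2); eigenvalues are clipped at 10⁻⁶ to restore
positive definiteness.  Structured components are added on top:
sinusoids at 1.2 Hz (cardiac), 0.25 Hz (respiratory) and 0.1 Hz (Mayer)
with per-channel random phases; 1/f pink noise; white sensor noise;
per-channel linear drift; and Poisson spike artifacts with 0.3 s
exponential decay.  All amplitudes are configurable;
`SignalGenConfig.clean()` returns the coupling-only variant.

Two facts about this construction worth knowing:

* A positive-semidefiniteness constraint caps uniform edge correlations
  at ~1/|λ_min(A)| (≈ 0.2 for a degree-10 graph), so for realistic
  couplings the eigenvalue clipping reshapes the covariance and
  single-window graph recovery is inherently noisy (per-window σ
  fluctuates with SD ≈ 0.03–0.06).  This is a feature for studying the
  engine under estimation noise, but it means no coupling value yields
  exact per-window recovery of the latent graph.
* The latent covariance-to-graph map is one simple choice among many; it
  makes connected pairs more correlated, which is all the downstream
  analyses require.

**Training cohorts.**  A subject-day is 120 s rest plus 18 blocks of
(15 s baseline, 2 s stimulus, 25 s regulation) at 25.6 Hz; the 2 s gap is
floor-rounded to 51 samples.  One latent graph `G ~ WS(35, k, p_base)` is
drawn per subject-day and shared by the rest, baseline and gap spans;
during regulation the covariance interpolates linearly between `G` and an
anchor — the ring lattice for effective rewiring p below baseline (UP
direction), an independently drawn fully rewired graph above it (DOWN).
The per-day effective p schedule defaults to a slowly descending UP curve
and a weakly rising DOWN curve; per-subject p offsets (SD 0.0005, fixed
across days so schedules stay monotone per subject) add between-subject
heterogeneity.  Cohort graphs use k = 12 rather than the k = 10 of the
generic Watts–Strogatz default: with 210 latent edges against the
178-edge budget of sparsity 0.3, threshold-boundary flips exchange
lattice-like edges instead of injecting random shortcuts, which
measurably stabilizes the windowed σ estimate (and drops spurious-edge
counts from ~25 to ~3 per window).  Baseline p_base = 0.15 places the
measured network in a clearly small-world regime (σ ≈ 1.9 at sparsity
0.3).

**Behavior.**  The generator works at the level of per-subject condition
means (the statistics of interest are subject-level summaries), with
trial-level expansion to 18 blocks × 5 trials: RT noise (SD 100 ms)
around the condition mean and Bernoulli correctness at the subject's
accuracy.  Pretest anchors: Stroop effect 80 ± 40 ms, neutral RT
600 ± 60 ms, accuracy 85 ± 4%.  Post-minus-pre changes are drawn
per-subject from the configured group (mean, SD): UP posttest ΔStroop
(−60, 45) ms, DOWN (9, 77) ms, UP follow-up ΔACC (2.48, 4.69)%, neutral
RT practice drift (−30, 35) ms per later test day; the remaining cells
(not constrained by group-level summaries) carry plausible defaults of
the same order.  Accuracies truncate to [0, 100]%; with the 85% pretest
anchor the truncation bias on ΔACC is below 0.1% (the post distribution
sits ≈ 2 SD under the ceiling), keeping the Monte-Carlo recovery of the
configured means unbiased.  A speeded color–word task with a 1.1 s
response window sits naturally in this accuracy range.

The behavioral and network drifts are *independent* streams: the
generator makes no attempt to couple a subject's ΔStroop to their
network change, so brain–behavior correlations are null by construction
and only exercise the analysis machinery.

## Day-5 calibration

The day-5 UP simulation targets a group-mean session statistic (default
2.813 baseline-relative points).  Because the statistic divides by the
per-block baseline SD — largely estimation noise — no closed form links
the latent drift to the expected score; calibration is therefore closed
loop, exploiting that the response is proportional to the covariance
mixing weight near the origin:

1. a 144-block probe at mixing weight 0.06 estimates the response slope;
2. a 1044-block pilot at the weight projected to yield ≈ 5 points
   refines it (larger operating points have smaller relative error;
   5 points stays within the near-linear range);
3. proportional inversion gives the calibrated weight, hence the
   effective day-5 rewiring probability.

Pilot streams are seeded independently of the final cohort.  The
engine's intrinsic noise should be kept in mind when interpreting single
runs: one block's statistic has an SD of ≈ 12 points (17 regulation and
9 baseline σ values per block, overlap-correlated, behind a ratio
statistic with clamping), so the mean over a 17-subject × 18-block
cohort carries an SE of ≈ 0.6–0.7 points, and the calibration transfers
a further ~5% relative uncertainty.  Single-cohort results therefore
scatter around the target by several tenths of a point.

## Preprocessing

Standard five-step chain.  OD is referenced to the recording-mean
intensity, so concentrations are changes relative to that reference (a
generate → preprocess round trip is exact after mean-centering).
Motion detection flags samples whose trailing-window (0.5 s) excursion
exceeds 0.5 OD or whose rolling SD exceeds 50× the channel's median
windowed SD; flags are padded by 1 s and merged.  These thresholds are
conventional defaults, exposed in `PreprocessConfig`.  Spline correction
replaces a flagged interval by its residual around an LSQ cubic-spline
trend (knots every 0.5 s), linearly re-anchored to the neighboring
samples; unflagged samples are untouched, boundary-touching intervals
anchor one-sided with a warning.  The band pass is a 5th-order
Butterworth (0.01–0.2 Hz), zero-phase offline and causal single-pass
online.  MBLL inversion uses wavelengths 780/805/830 nm, DPF 6.0 each,
3 cm separation, and a pinned published-style extinction table
(mM⁻¹cm⁻¹): 780 nm (0.710, 1.075), 805 nm (0.830, 0.780), 830 nm
(0.974, 0.693) for (HbO₂, HbR) — replaceable via config; concentrations
are in µM-equivalent arbitrary units, and only relative fluctuations
matter downstream.

The scaled cohort simulations run the online window/threshold/null/score
chain directly on generated concentrations; the Eq.-2 statistic is
self-normalizing, so the causal band pass would rescale its noise but
not its calibrated mean, and the filter stages are exercised by their
own tests and the offline analyses instead.

## Statistics

Two-sample t tests pool variances by default (matching common
point-and-click practice); Welch is available.  The mixed RM-ANOVA
assumes sphericity (ε = 1).  The a-priori sample size searches total N
(equal groups) for the within-between interaction with noncentrality
λ = f²·N·m·ε/(1−ρ), dfs ((g−1)(m−1)ε, (N−g)(m−1)ε); with f = 0.25,
α = 0.05, power 0.8, 2 groups, 3 measurements, ρ = 0.5, ε = 1 the search
returns N = 28 (achieved power 0.812; 26 gives 0.778).  Edge-wise
contrasts operate on per-subject mean Fisher-z values (not binary edge
presence) — they carry more information and keep the t test well
defined — with p < 0.01 selection and optional BH adjustment.  Zero
variance with zero effect returns p = 1 with a warning rather than NaN.

## Rewiring-continuum placement

`infer_rewiring_p` simulates C(p) and L(p) for the reference family
(n = 35, k = 10 — matching the channel count and the edge budget of the
working sparsity) on a log-spaced grid (100 seeds per point), scores
grid points by squared distance in units of the family SD per metric,
and refines once around the minimum.  The uncertainty interval collects
fine-grid points within one distance unit of the optimum; observations
outside the family envelope snap to the boundary and are flagged.
Placements to be *compared* (UP vs DOWN) should share the simulation
seed so both use the same reference curves.

## Problem sizes

Simulation-heavy checks are scaled to single-CPU runtimes: cohort-level
tests use 3–8 subjects per group, the day-5 reproduction uses the full
17 subjects × 18 blocks with every-4th-update refresh and 10 nulls, the
behavioral recoveries use 500 cohorts, and oracle equivalence tests for
C and L enumerate graphs with n ≤ 8.

## Limitations

* No hemodynamic response modelling (no HRF convolution, no balloon
  model), no scalp/short-channel physiology separation, no
  task-evoked activation structure: signals are stationary within spans.
* Graph recovery from 5 s windows is intrinsically noisy (see the PSD
  cap above); analyses that depend on single-window graphs inherit that
  noise by design.
* Behavioral effects are injected at the subject level; trial-level
  sequential structure (post-error slowing, fatigue) is absent.
* The generator's group effects are point configurations, not fits to
  any dataset; passing recovery tests shows the pipeline is unbiased and
  correctly scaled, not that the underlying physiology is realistic.
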