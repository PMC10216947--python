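# Methods

This note documents the models, estimators and synthetic-data generators in
`edukin`, the assumptions behind them, and the choices made where several
defensible designs existed.

## The cumulative-labeling model

A thymidine analog such as EdU is incorporated only by cells in S-phase.
In a population where a fraction GF (the *growth fraction*, percent) cycles
with period `Tc` hours, spending `Ts` hours in S, continuous exposure
produces a labeling index (percent of labeled nuclei)

```
LI(t) = GF · (t + Ts) / Tc    for t ≤ Tc − Ts
LI(t) = GF                    for t ≥ Tc − Ts
```

Writing the rising segment as `y = a + b·t` gives the identities used
throughout the package: `a = GF·Ts/Tc` (the instantaneous S-phase
fraction, also the expected LI of a vanishingly short pulse),
`b = GF/Tc` (the rate of S-phase entry), a breakpoint at `Tc − Ts`, and the
inversions `Ts = a/b`, `Tc = GF/b = breakpoint + Ts`.

**Assumptions.** The linear form is exact only for a *steady-state renewal
population*: constant size, uniform cell-cycle age distribution, no cell
death, no entry into or exit from the cycle during the experiment, and
identical (Tc, Ts) for every cycling cell.  An exponentially growing
population has an excess of young cells and a slightly convex cumulative
curve; the package implements the stated linear equations and mirrors their
premise in the simulator's default `renewal` division mode.  Heterogeneous
tissue (sub-populations with distinct kinetics) can be emulated by
composing simulated populations but is not modeled in closed form.

**Units.** LI and GF are carried as percent (0–100) and all times in hours
everywhere — the units in which such measurements are conventionally
reported.  `g1_fraction` (default 0.5) fixes where S sits inside the cycle;
the cumulative curve is invariant to it, only division timing in
pulse-chase simulations depends on it.

## Fitting the broken line with plateau

`fit_cumulative` minimizes weighted squared error of the two-phase curve.
For a breakpoint lying between two adjacent distinct sampling times the
problem decouples exactly — an ordinary weighted line through the
pre-breakpoint points and the weighted mean of the post-breakpoint points —
so the global landscape is explored by scanning every placement of the
breakpoint between adjacent sampling times.  A placement is
*self-consistent* when the breakpoint implied by its own line and plateau
((GF − a)/b) falls back inside the generating interval, strictly inside the
sampled time range.

**Selection rule (a genuinely open design choice).**  When several
placements are self-consistent the fitter selects the *earliest* breakpoint
(equivalently the smallest Tc), not the smallest SSE.  The raw SSE
criterion is degenerate here: a plateau supported by a single late point
fits that point exactly, so late placements absorb the final observation's
measurement error into the model and win SSE comparisons while inflating
Tc — on one of the packaged published series the raw-SSE optimum reads a
29-percentage-point rise between the last two samples as part of the
"plateau-free" line and nearly doubles Tc.  Reading the curve as saturating
at the earliest time compatible with the two-phase geometry is the
conservative interpretation (it never claims a longer cycle than the data
force) and matches standard practice in cumulative-labeling analysis.
Nonlinear least-squares tooling started from a mid-range breakpoint
converges to the same solution; `selection="sse"` restores the raw global
criterion for comparison.  Ties (identical breakpoints) break toward
smaller Tc.

If no interior placement is self-consistent, breakpoints pinned at interior
sampling times are tried (a constrained linear fit in `min(t, B)`); if none
improves on a single straight line the fit is flagged non-identifiable and
only a lower bound on GF (the largest observed LI) is reported.  A plateau
supported by a single point is allowed but is weakly identified: GF then
equals that point's value.

**Uncertainty.** `bootstrap_ci` provides case-resampling percentile
intervals, resampling whole specimens when specimen identifiers are given
(respecting the longitudinal correlation of repeated measurements within a
specimen) and single points otherwise.  *Known limitation:* with very few
specimens (the suite exercises six) percentile intervals undercover — the
coverage test observes roughly 75–90% for nominal 95% intervals — which is
the familiar small-cluster behavior of the percentile bootstrap, not an
implementation artifact; treat intervals from ≤ 6 specimens as optimistic.

## The labeling simulator

`simulate` is the package's synthetic-data generator: a structure-of-arrays
agent population in which exactly `round(n·GF/100)` cells cycle
(stratified assignment — GF is a population constant of the model, so it is
not given Bernoulli sampling noise; a consequence is that plateau-phase
counts in cumulative designs are noise-free while pre-plateau counts carry
full binomial noise).  Cycling ages are i.i.d. Uniform[0, Tc), the
stationary renewal distribution; an `exponential_growth` age option
(density ∝ 2^(−a/Tc)) is provided for growing-tissue scenarios.

Advancement is event-driven and exact rather than time-stepped: for each
cell the number of divisions in a span and the overlap of its recurring
S-interval with the exposure window are computed in closed form, so
simulator-vs-model discrepancies are pure sampling noise.  Labeling sets
intensity 1 at the cell's last in-S moment inside the exposure window; each
subsequent division halves intensity (label shared between daughters);
cells are scored positive above a detection threshold, default 1/16,
i.e. a label survives four rounds of dilution — a plausible reading of
labels becoming "diluted" after repeated division, and exposed as a
protocol parameter.  In `renewal` mode (default) a division replaces the
parent by one daughter, keeping size and age distribution stationary;
`growth` mode keeps both daughters (synchronized clones, materialized as
copies).  No cell death, migration, or cycle entry/exit is simulated — no
rates are available to calibrate them — so simulated data are *cleaner*
than real specimen counts: passing recovery tests demonstrates estimator
correctness under the model's own assumptions, not robustness to
biological heterogeneity.

Experiments use one independent population per specimen with per-specimen
random substreams spawned from a master seed (`SeedSequence.spawn`), so
results are reproducible and order-independent.  Default experiment sizes
(6 specimens × 2000 cells, sampling at 0.25/5/10/24/48 h) mirror a
realistic cumulative design: a few thousand nuclei per counted volume, a
handful of specimens per time point, samples from 15 minutes to two days.

## Group statistics

Stage-wise summaries are mean ± SEM (sample SD / √n, flagged NaN for
n = 1).  Inference is nonparametric, as appropriate for 4–16 specimens per
stage: Kruskal–Wallis omnibus (tie-corrected H) followed by pairwise
Mann–Whitney tests.  For pooled n ≤ 10 the Kruskal–Wallis p is an exact
full-enumeration permutation p (in-package enumeration; the limit keeps
enumeration sub-second); Mann–Whitney uses the exact U distribution for
tie-free samples with n₁+n₂ ≤ 12, otherwise the tie-corrected normal
approximation with continuity correction.  Pairwise flags default to raw
p ≤ 0.005 — a stringent threshold in lieu of multiplicity correction;
Bonferroni and Holm adjustments are available but off by default.

## Synthetic stacks and counting

`imaging` replaces interactive spot counting with a reproducible pipeline.
Synthetic stacks default to 45 planes at 1.5 µm axial step with 0.5 µm
lateral sampling; nuclei (default diameter 6 µm) are placed by dart
throwing at ≥ 1.5 diameters separation with a half-diameter border margin
and rendered as 3-D Gaussian blobs (σ = diameter/2.355 per axis, peak
amplitudes jittered ±20% to mimic staining heterogeneity); exactly
`round(n·labeled_fraction)` nuclei appear in the label channel; additive
Gaussian noise is clipped at zero.  What the generator does *not* emulate:
touching/overlapping nuclei, intensity gradients with depth, anisotropic
PSF tails, autofluorescence and structured background — so detection scores
on these stacks are an upper bound on real-data performance, and the
counting tests validate the pipeline's logic, not its field accuracy.

Detection is difference-of-Gaussians band-pass at the expected diameter
(σ = d/4 and 2·d/4 per axis, scaled by voxel size), local-maximum
extraction over an ellipsoidal half-diameter footprint, and a relative
threshold (default 0.25 × band-passed maximum) standing in for the manual
threshold adjustment of interactive workflows.  The labeling index matches
label-channel detections to nuclear detections by greedy nearest-neighbor
pairing within half a diameter; unmatched label detections are discarded
(clamped with a warning when they exceed nuclear counts).  Manual
region-of-interest drawing is inherently interactive and is out of scope;
counting applies to the whole stack.

## Numerical notes

* Breakpoint-interval consistency uses closed intervals between adjacent
  sampling times and a strict interior requirement on the full range, so a
  noiseless point exactly at the breakpoint belongs to either side without
  changing the fit.
* `params_from_line` rejects zero intercepts (they imply Ts = 0) and
  plateaus not exceeding the intercept; the fitter skips such candidate
  placements rather than clamping them.
* Division counting in the simulator uses floor arithmetic on exact phase
  references; with `g1_fraction = 1` (S ending exactly at division) the
  division coinciding with the labeling instant is counted as at-or-before
  labeling, so the label is not halved for it.
* Detection thresholds compare against powers of two (1/16 by default),
  which are exact in binary floating point; no epsilon is applied.

## Problem sizes used in the checks

Deterministic fits run on the two packaged published series (5 and 4 time
points).  Stochastic checks use: 20 000 cells for simulator-vs-model
agreement (3 binomial SE); 50 replicates of 6 specimens × 2000 cells for
parameter recovery (median relative error ≤ 10%); 40 replicates × 200
resamples for bootstrap calibration; 10 stacks of 300 nuclei at peak SNR 5
for detection precision/recall (≥ 0.95) and end-to-end LI error (≤ 3
percentage points).  These sizes were chosen to make sampling noise small
relative to the tested tolerances while keeping the full suite fast enough
to run habitually.
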