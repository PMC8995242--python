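# Methods

This note documents the models, numerical choices and known limitations of
`blochkwic`. Everything quantitative stated here is computed by the test
suite or the worked example in the README; nothing is quoted from external
measurements.

## Signal model

The sequence is a spin-lock-prepared, RF-spoiled radial gradient echo. One
preparation cycle is modelled with longitudinal magnetization only:

1. recovery over `t_rec`:  `Mz ← M0 + (Mz − M0)·exp(−t_rec/T1)`
2. balanced spin-lock preparation:  `Mz ← Mz·exp(−t_SL/T1ρ(f_SL))`
3. readout train, k = 1…NR:  emit `S_k = Mz·sin α`, then
   `Mz ← M0 + (Mz·cos α − M0)·exp(−TR/T1)`

Assumptions: ideal spoiling (no transverse coherence between pulses), an
ideal balanced spin-lock module (B0/B1 imperfections, T2ρ and
off-resonance effects during the lock are neglected — the balanced
preparation is designed to suppress them), and TE/T2\* decay treated as a
constant factor absorbed into `M0`. The spin-lock amplitude enters only
through the linear dispersion model `T1ρ(f_SL) = T1ρ⁰ + m1ρ·f_SL` (slope
in ms/kHz, amplitude in kHz inside the model).

The chronological timeline runs the weighting blocks in ascending-`t_SL`
order by default (`weighting_order` is configurable because the
acquisition order of the blocks is a free protocol choice), with
`n_dummy = 2` lead-in cycles using the first block's parameters.

Exact steady-state properties used as test oracles: with `t_SL = 0` and
α = 90° the steady-state signal is saturation recovery over the full
cycle, `M0·(1 − exp(−(t_rec+TR)/T1))`; with `t_rec ≫ T1` the
first-readout signal ratio between two spin-lock times is
`exp(−Δt_SL/T1ρ)`.

## Flip-angle optimization

`optimal_flip_norelax` maximizes the relaxation-free train signal
`Σ_k sin α · cos^(k−1) α` (43.51° for NR = 4; 90° for NR = 1; 60° for
NR = 2, where the optimum solves `2cos²α + cosα − 1 = 0`).

`optimal_flip_bloch` maximizes the *steady-state* signal averaged over
all spin-lock times and readouts. Each weighting block is simulated
independently to steady state (60 settle cycles — far beyond the
geometric convergence of the recursion for realistic timings) and the NR
readouts of the settled cycle are averaged. For TR = 5 ms,
t_rec = 1500 ms, t_SL = 4…60 ms, NR = 4, T1 = 1400 ms, T1ρ = 40 ms this
gives 39.35°. Averaging the raw chronological timeline instead (which
mixes in the transients at block boundaries) shifts the optimum by less
than 0.1°; the steady-state definition is used because it is the
per-weighting signal level the protocol actually delivers. Both
optimizers are deterministic grid searches (default step 0.01°), so
results are bit-reproducible.

The relaxation-free optimum is a single-train property: it is recovered
from the steady-state simulator in the limit `t_rec ≫ T1` (complete
recovery each cycle) with `TR ≪ T1`, not for `T1 → ∞`, where repeated
trains simply consume the magnetization.

## Bloch sorting

Spokes are ranked by predicted signal (descending); rank N receives
projection angle `φ = N·360°/(1+√5)` (N starts at 1, so the familiar
sequence 111.25°, 222.49°, 333.74°, … is reproduced at full precision —
the two-decimal shorthand 222.50°/333.75° differs in the second decimal).
Ties — the common case, since each weighting repeats 13 identical
preparations — are broken chronologically, making the sort stable and the
golden-index order within each plateau equal to acquisition order.

Gap structure: consecutive full-circle golden-angle indices cover the
circle with at most three distinct azimuthal gaps (three-distance
theorem); exactly two distinct gaps occur at the convergent denominators
of the rotation number — 3, 13, 55, 233 — which includes the 13-spoke
k-space centre. The intermediate Fibonacci counts used by outer annuli
(21, 34, 89, 144) have three gap sizes; the Nyquist factor margin covers
this mild nonuniformity.

`sorting_deviation` quantifies how far a measured, golden-index-ordered
signal sequence is from monotone non-increasing: the mean over spokes of
`max(0, s_i − min(s_1..s_{i−1}))/s_i`. It is exactly 0 for noiseless
Bloch-sorted data.

## KWIC filter

One filter per weighting, built from annuli in k-space:

- The innermost annulus is exactly the `n_prep` (13) first-readout spokes
  of the target weighting; outer radius `r = n_phi/(π·f_nyq)` with
  `f_nyq = 1.1` by default. This annulus alone fixes the low-frequency
  contrast of the reconstructed image.
- Each outer annulus takes the smallest Fibonacci spoke count satisfying
  the azimuthal Nyquist condition `n_phi > π·r·f_nyq` at its outer
  radius, expanding the spoke set symmetrically in golden-index space
  around the centre block (which equals predicted-signal adjacency after
  Bloch sorting). At the index bounds the remainder is taken from the
  open side. Annuli are half-open `[r_prev, r_max)`; the outermost
  annulus is extended to cover the k-space edge at `matrix/2`.
- If no admissible Fibonacci count ≤ the total spoke count covers the
  edge, the design is rejected with the minimal required count in the
  message.

Under serial sorting the same index rule applies to the chronological
indices, reproducing conventional view-sharing behaviour (the centre set
is then not index-contiguous; outer annuli are contiguous intervals
spanning it).

## Forward model and reconstruction

The phantom is rasterized on the reconstruction grid; each spoke's
samples are the sum over tissue regions of the region-mask NUFFT times
that tissue's Bloch signal at the spoke's (window, readout) position.
Complex Gaussian noise (std `noise_sigma` per channel) is added in
k-space only (single coil), reproducibly under a fixed seed. For the
128-matrix BSA phantom, `noise_sigma = 1.0` (k-space units where M0 = 1)
is used in the matched-noise comparisons; at that level the background
standard deviation of the reconstructions is dominated by residual
view-sharing artifacts rather than thermal noise, which mirrors the
artifact-limited regime the sorting comparison is about.

**Readout sampling.** Spokes carry samples at spacing Δk = 0.5 cycles/FOV
(2× readout oversampling), spanning |k| ≤ matrix/2. This is deliberate:
the four-tube phantom occupies the square FOV corners, so its diagonal
Radon projections are longer than the FOV and Δk = 1 sampling aliases
along the spoke direction (mirror ghosts of ~0.6 relative amplitude in
experiments with Δk = 1). Two-fold readout oversampling is also the
near-universal scanner default for radial acquisitions.

**NUFFT.** Kaiser–Bessel gridding with oversampling 2 and kernel width 6
(Beatty shape parameter), with analytic deapodization. Width 6 keeps the
operator error near 1e−5 relative RMS against the exact direct-summation
DFT (width 4 hovered at the 1e−3 contract boundary). The direct NDFT is
retained as the independent test oracle for matrices ≤ 64.

**Density compensation.** The analytic weighting is a per-annulus radial
ramp: area element `π·|k|·Δk/n_phi` per sample, with the k = 0 sample
given the central-disk area `π·Δk²/4` split over the spokes that carry
it. By default the reconstruction refines this ramp with 10 Pipe–Menon
iterations (divide by the gridding-kernel convolution of the weights,
evaluated at the samples), rescaled to the ramp's total weight so the
image scale stays consistent across filters. The refinement lowers the
low-frequency quadrature error of the view-shared trajectory and with it
the haze floor; per-tube noiseless T1ρ biases tighten from
(−2.6…+4.2)% to (−0.9…+3.6)%. `dcf="ramp"` restores the plain ramp.

Magnitude images are returned by default; complex output is available.

## Quantification

Per-pixel two-parameter fit `S = S0·exp(−t_SL/T1ρ)` on magnitude images:
log-linear initialization, then damped Gauss–Newton (vectorized over
pixels, ≤50 iterations). Pixels below 5% of the shortest-`t_SL` image
maximum, or with non-finite/non-positive samples, are masked; constant
pixels end up flagged out rather than producing negative rates. For
noiseless exponential data the fit is exact to machine precision (the
two-point case reduces to `T1ρ = Δt/ln(a/b)` exactly). Unweighted least
squares is used and no Rician bias correction is applied — at the
simulated SNRs the rectified-noise floor is negligible against the
view-sharing haze, and the reference analysis this mirrors also fit
magnitude data.

Dispersion: per-pixel OLS of T1ρ against f_SL in kHz, only where every
input map is valid; noiseless linear inputs are recovered to 1e−6 and the
fit R² is 1 to 1e−9.

Metrics: `snr_metric` = mean over pooled signal masks / std over a
disjoint noise mask (zero-variance noise regions are rejected);
`delta_q` = per-pixel `100·(test − ref)/ref` summarized as mean ± std
over an ROI.

## Study conditions of the simulated experiments

- Phantom protocol: TR = 5 ms, TE = 2 ms, t_rec = 5000 ms, α = 40°,
  NR = 4, t_SL = 4…102 ms (8, linear), f_SL = 1500 Hz (dispersion:
  750…2500 Hz, 8 linear), 128×128, FOV 38.4 mm.
- BSA phantom: four 17 mm tubes at (±9.6, ±9.6) mm (quadratic array; the
  exact tube placement is not published — chosen to keep the tubes
  separated and inside the square FOV), dispersion parameters per tube
  from the reference measurement (10%: 82.60 ms, 12.81 ms/kHz; 15%:
  51.51, 8.42; 20%: 36.11, 5.73; 25%: 27.00, 4.59), T1 = 1400 ms for all
  tubes (tube T1 values are not published).
- Cardiac ring phantom: myocardial annulus T1ρ⁰ = 32.73 ms,
  m1ρ = 4.76 ms/kHz, T1 = 1400 ms around a blood disk T1ρ⁰ = 48.72 ms,
  m1ρ = 21.57 ms/kHz, FOV 32 mm.
- Sorting prior for the BSA experiments: T1 = 1400 ms, T1ρ⁰ = 49.3 ms,
  m1ρ = 7.9 ms/kHz (the across-tube mean — the prior only needs to rank
  signal levels, not match any tube exactly).

## What the simulations do and do not show

The phantom simulator exercises the full chain — Bloch prediction,
sorting, view-shared sampling, gridding, fitting — under controlled
conditions, so accuracy statements isolate the method itself. It does
not model cardiac or respiratory motion, flow, B0/B1 inhomogeneity,
coil sensitivity, trigger-delay physiology, or Rician noise statistics
of multi-channel magnitude images. Passing tests therefore validate the
sampling/reconstruction/quantification logic, not in vivo robustness.

Known systematic behaviour: KWIC view sharing slightly underestimates
long T1ρ and overestimates short T1ρ (the shared periphery mixes
neighbouring signal levels, and for the extreme weightings the sharing
is one-sided). In the noiseless 128-matrix BSA simulation the per-tube
mean errors are −0.9%, +1.0%, +2.2%, +3.6% (pooled ≈ +1.5%); the
positive tail on the shortest-T1ρ tube comes from magnitude
rectification of residual sidelobe haze under the deep signal decay at
t_SL = 102 ms.

## Problem sizes

Default test and acceptance runs use the full 104-preparation, 416-spoke,
128×128 protocol for the end-to-end checks (seconds per map on one CPU),
matrix ≤ 64 for exact-oracle comparisons, and a 26-preparation, 16×16
toy protocol for I/O and linearity tests.
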