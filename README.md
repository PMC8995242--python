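# blochkwic

Fast quantitative T1ρ and T1ρ-dispersion mapping for preclinical cardiac
MRI, built around three ideas: a high-flip-angle spin-lock-prepared radial
gradient-echo readout, a Bloch-simulation-optimized assignment of
golden-angle projections ("Bloch sorting"), and a KWIC (k-space weighted
image contrast) view-sharing reconstruction. A digital-phantom forward
simulator makes every stage testable without scanner data.

## The problem

T1ρ — spin-lattice relaxation in the rotating frame — is probed by a
spin-lock (SL) pulse of duration t_SL and amplitude f_SL applied before
each acquisition. Mapping T1ρ requires several images with different t_SL;
mapping its *dispersion* (the dependence of T1ρ on f_SL, a candidate
contrast-agent-free fibrosis marker) multiplies that by several SL
amplitudes. In mice, where the diastolic acquisition window is ~20 ms and
the magnetization must recover over a full respiratory cycle between
preparations, the naive protocol takes hours. This package implements an
accelerated scheme: after each preparation only NR = 4 radial spokes are
read out, 13 preparations are spent per weighting (13 × 8 = 104
preparations, 416 spokes per map — a 32:13 ≈ 2.5× acceleration over a
fully sampled Cartesian reference), and the eight weighted images are
recovered by KWIC view sharing.

## The method

**Flip-angle optimization.** With spoiled gradient-echo readouts the k-th
pulse of a train sees magnetization ∝ cos(α)^(k−1), so ignoring
relaxation the mean train signal S̄(α) = Σ_{k=1..NR} sin α · cos^{k−1} α
peaks at α = 43.51° for NR = 4. Including T1 recovery (TR = 5 ms,
t_rec = 1500 ms, T1 = 1400 ms) and spin-lock decay (T1ρ = 40 ms,
t_SL = 4…60 ms) in a longitudinal Bloch recursion shifts the optimum to
α = 39.35°.

**Bloch sorting.** High flip angles make the per-spoke signal vary
strongly within and between preparations. The package predicts every
spoke's signal by solving the longitudinal Bloch recursion for the whole
acquisition, ranks the spokes by predicted signal, and assigns the N-th
rank the golden-angle projection φ = N · 360°/(1+√5) ≈ N · 111.25°.
Adjacent projection angles then carry adjacent signal levels, so the
contrast varies smoothly across k-space instead of oscillating — the
artifact level drops and SNR rises relative to chronological ("serial")
golden-angle ordering.

**KWIC reconstruction.** For each weighting, the k-space centre (up to
radius n_φ/(π·f_nyq) with n_φ = 13 and Nyquist factor f_nyq = 1.1) uses
*only* the 13 first readouts acquired directly after that weighting's
preparation, so the low-frequency contrast is exact. Peripheral annuli
admit growing, Fibonacci-sized sets of signal-adjacent spokes (21, 34,
55, 89, 144, 233), each satisfying the azimuthal Nyquist condition
n_φ > π·r·f_nyq. Gridding uses a Kaiser–Bessel NUFFT (oversampling 2,
width 6) with per-annulus ramp density compensation refined by Pipe–Menon
iterations.

**Quantification.** Pixel-wise mono-exponential fits
S(t_SL) = S0·exp(−t_SL/T1ρ) give T1ρ and R² maps; ordinary least squares
of T1ρ against f_SL (in kHz) gives the linear dispersion model
T1ρ(f_SL) = T1ρ⁰ + m1ρ·f_SL with the offset in ms and the slope in
ms/kHz.

## Worked example

Flip-angle optimization for the murine myocardial protocol:

```text
$ blochkwic optimize-flip
closed-form optimum (NR=4): 43.51 deg
Bloch-simulated optimum:          39.35 deg
parameters: TR=5.0 ms, t_rec=1500.0 ms, NR=4, t_SL=[4.0, 12.0, 20.0, 28.0,
36.0, 44.0, 52.0, 60.0] ms, T1=1400.0 ms, T1rho=40.0 ms
```

Noiseless end-to-end simulation of the four-tube protein-solution (BSA)
phantom (128×128, FOV 38.4 mm, t_SL = 4…102 ms, f_SL = 1500 Hz, Bloch
sorting; tube T1ρ⁰/m1ρ values from the reference dispersion measurement):

```python
import numpy as np, blochkwic as bk
from scipy.ndimage import binary_erosion

seq = bk.SequenceParams(TR=5, t_rec=5000, alpha=40, NR=4,
                        t_SL_list=np.linspace(4, 102, 8),
                        f_SL_list=(1500.0,), matrix=128, fov=38.4)
ph = bk.make_bsa_phantom()
prior = bk.TissueParams(T1=1400, T1rho0=49.3, m1rho=7.9)
pat = bk.build_pattern(seq, prior, 1500.0, mode="bloch")
ks = bk.simulate_kspace(ph, pat, seq, 1500.0)
filters = bk.design_kwic(pat, matrix=128, f_nyq=1.1)
series = bk.reconstruct_series(ks, filters, matrix=128, t_SL_list=seq.t_SL_list)
m = bk.fit_t1rho(series)
for shape, mask in zip(ph.shapes, ph.region_masks()):
    roi = binary_erosion(mask, iterations=2) & m.mask
    rep = bk.delta_q(m.t1rho, np.full_like(m.t1rho, shape.tissue.t1rho(1500.0)),
                     roi, label=shape.tissue.label)
    print(f"{rep.label}: T1rho = {rep.mean:6.2f} +/- {rep.std:4.2f} ms   "
          f"dQ = {rep.delta_q_mean:+5.2f} +/- {rep.delta_q_std:4.2f} %")
```

prints

```text
10%: T1rho = 100.87 +/- 5.91 ms   dQ = -0.93 +/- 5.80 %
15%: T1rho =  64.76 +/- 3.57 ms   dQ = +0.96 +/- 5.57 %
20%: T1rho =  45.69 +/- 3.03 ms   dQ = +2.20 +/- 6.77 %
25%: T1rho =  35.12 +/- 3.03 ms   dQ = +3.64 +/- 8.95 %
```

i.e. the fitted tube T1ρ values recover the effective ground truth
(T1ρ⁰ + m1ρ·1.5 kHz) with per-tube mean errors of a few percent; long
relaxation times are slightly under-, short ones slightly over-estimated,
which is the characteristic residual of KWIC view sharing.

The full pipeline (simulate → sort → k-space → reconstruct → fit →
dispersion) is also scriptable: `blochkwic pipeline --config cfg.yaml`
writes schedules, k-space bundles (HDF5), weighted images and parameter
maps (NIfTI), and a run manifest.

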