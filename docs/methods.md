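# Methods

This note records the model, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Sequence timing

All MOLLI intervals are defined in heartbeats. A trigger series (R-wave
instants, ms, t = 0 at the first trigger) plus a scheme label — `5(3)3`
(acquisition counts outside parentheses, recovery pauses inside) or `5(0)3` —
compiles to an absolute event timeline. The readout center of an imaged
heartbeat sits a fixed trigger delay after its R-wave (default 500 ms,
end-diastole); the inversion of group *g* is placed `ti_offsets[g]` ms before
the readout center of the group's first image (defaults 100/180 ms, the
conventional clinical minimum TIs — scanner protocols rarely publish these,
so both are configuration, not derived quantities). Image *k* of a group
therefore has effective TI equal to the group offset plus the sum of the *k*
recorded RR intervals — the property that makes the training database
acquisition-specific. Effective TI is referenced to the echo of the center
k-space line. 5(3)3 spans 11 heartbeats, 5(0)3 spans 8, independent of RR.

The synthetic ECG draws i.i.d. Gaussian RR intervals truncated at 300 ms.
Phantom-style experiments use 60 bpm with zero variance, matching a
metronomic scanner trigger.

## Bloch simulation

21 isochromats (odd, so one is exactly on-resonance) are spread uniformly
over twice the 6 mm slice thickness. Per scheduled image the ensemble
experiences: a non-selective 4.74 ms hyperbolic-secant adiabatic inversion
(once per group), free relaxation, then a single-shot bSSFP readout — 10
linearly ramped preparation excitations (α·k/10) followed by 62 phase-encode
lines at 35°, phases alternating 0/π, TR 2.2 ms, TE = TR/2. The emitted
sample is |Σ Mxy| over the ensemble at the echo of line 31 (of 62; 124
matrix with parallel-imaging factor 2, linear order). Magnitudes only, as
on the scanner.

Numerical scheme. Shaped pulses are integrated at their 5 µs raster with
relaxation inside the pulse: per raster step, a symmetric (Strang) relaxation
split around a 4th-order commutator-free Magnus rotation pair (two
Gauss-node field evaluations per step). Halving the raster changes the
output signals by < 1e-7 relative, so the raster choice is not a resolved
error source. During selective pulses, off-center isochromats precess at the
slice-gradient offset (pulse bandwidth = TBW/duration mapped across one
slice thickness); the refocusing lobe is applied as a phase rewind of half
the pulse duration. Between pulses gradients are balanced and everything is
on-resonance: no B0/B1 inhomogeneity is modelled, no flip-angle variation.

The sech pulse uses µ = 4.9, β = 2236 s⁻¹ (βτ/2 ≈ 5.3, sweep ≈ 3.5 kHz) and
peak γB1/2π = 1600 Hz, giving > 99.9 % on-resonance inversion without
relaxation and ≈ −0.99 Mz at (T1, T2) = (1000, 200) ms. The sinc envelope is
normalized against the same Gauss quadrature the integrator uses, so the
on-resonance small-tip flip is exact. The 490 µs figure is read as the
excitation-pulse duration; bSSFP TR/TE are unpublished for this protocol and
default to 2.2/1.1 ms — chosen so that the 41 TRs preceding the center line
(≈ 92 ms) fit inside the 100 ms minimum TI.

Two independent execution paths share the physics: a transparent per-step
integrator for single states, and a batched path that pre-composes each
pulse into an exact affine operator `M → A·M + b` per (T1, T2) entry —
rotations are shared across entries, relaxation is per-entry — making a
1,078-entry database ≈ 9 s and the 21,560-entry database ≈ 3 min on one CPU.
Tests pin the two paths together at 1e-12. An ideal-pulse mode
(instantaneous inversion, readout disabled) is verified against the
closed-form piecewise Look-Locker recursion at 1e-6.

## Signal database

Grid: T1 ∈ [600, 2000) ms (half-open), T2 ∈ [20, 400] ms (closed), with
combinations T1 < T2 or T2 < 20 ms excluded. This endpoint convention is the
unique one reproducing all three published sizes — 280×77 = 21,560 (5 ms),
1400×381 = 533,400 (1 ms), 14×77 = 1,078 (100 ms T1 step) — simultaneously;
with the default ranges the exclusion rules are vacuous. Augmentation
replaces each entry by 10 copies with i.i.d. Gaussian noise of σ = (entry
max sample)/SNR on every sample, clipped at zero (magnitudes), SNR 40.
Normalization divides each 8-vector by its own L2 norm — the per-vector
reading of the published normalization, required for gain-invariant
application to scanner pixels; the global-norm reading would not survive
arbitrary receiver scaling. The same transform is applied at training and
inference, and each database carries the schedule fingerprint so a
train/apply timing mismatch is detectable.

## The regression network

Dense 8 → 40 → 20 → 8 → 1, ReLU hidden, linear output, MSE on T1 in ms,
Adam (lr 0.001, β₁ 0.6, β₂ 0.95), batch 20, exactly 100 epochs, 70/28/2
train/validation/test split (floors, remainder to training), no early
stopping — validation is monitored only. Implemented in numpy inside the
package: one seeded generator drives weight initialization (uniform fan-in),
epoch shuffling and nothing else, so fixed (data, seed) reproduces weights
and predictions bit for bit on a platform.

Optimization preprocessing: the estimator internally z-scores the 8 features
with training-set statistics and scales targets by 1/1000 during
optimization, mapping predictions and recorded losses back to ms and ms².
Unit-norm vectors have per-feature variance ~1e-3, which stalls first-layer
learning badly at the fixed learning rate and epoch budget — without this
the network plateaus ~70 ms from the attainable optimum. The transform is an
affine reparameterization carried inside the fitted model (saved and loaded
with it), not a change to the published loss or architecture.

Accuracy floor. A grid posterior-mean oracle under the SNR-40 noise model
shows that T1 is identifiable to ~1 ms from the *raw* 8-sample signal, but
after unit-norm scaling the minimum-MSE estimator itself is biased by
−10…−45 ms across the phantom range (scale removal leaves a partial T1–T2
degeneracy). The trained network sits essentially on this floor; its
residual phantom bias (≈ −15 ms) is therefore a property of the
normalization + noise model, not of the optimizer. The conventional fit's
bias on the same data is several-fold larger.

## Conventional fit

3-parameter magnitude fit S(TI) = A − B·exp(−TI/T1*) on TI-sorted samples,
Levenberg–Marquardt (analytic Jacobian, ftol 1e-10, 500-iteration budget),
with polarity restoration by exhaustive inversion-index search: each p ∈
{0..8} negates the p earliest-TI samples; minimum residual wins. Look-Locker
correction T1 = T1*(B/A − 1). Initialization A₀ = max|S|, B₀ = 2A₀,
T1*₀ = 1000 ms with 500/1500 ms restarts on non-convergence. Non-convergence
and A ≤ 0 are flagged, never raised, so pixel loops survive degenerate
pixels. On data generated exactly from the 3-parameter model the fit
recovers parameters to < 0.1 %; on Bloch-simulated signals it shows the
characteristic T2-dependent underestimation (worst at short T2), which is
the pattern the network approach removes.

## Digital phantoms and evaluation

The default phantom is 11 disks on a 128×128 canvas: six myocardium-like
regions (T2 50–65 ms) and five blood-like regions (T2 135–200 ms), T1
spanning 700–1600 ms evenly within each set. These (T1, T2) pairs are
synthetic choices sampling the stated ranges, not measurements of physical
vials. Regions are piecewise constant — one Bloch signal per region, scaled
by proton density, i.i.d. Gaussian pixel noise at the stated SNR clipped at
zero, background noise only — so region statistics isolate estimator error
from structural variation. ROIs default to the central 60 % of each region.

Agreement statistics follow relaxometry-validation convention: bias =
mean(estimate − reference) with 1.96·SD limits (modified Bland–Altman:
differences against the known reference), least-squares slope, intercept and
R², and percent error (T1_actual − T1_estimated)/T1_actual — positive for
underestimation, so the conventional fit's negative bias and positive
percent error agree in sign.

Problem sizes: tests and the acceptance script run the reduced 1,078-entry
grid (×10 augmentation) and a 64×64 phantom canvas, sizes at which the full
pipeline — simulate, train, map with both estimators — completes in about a
minute on one CPU while exercising every stage at full fidelity; the 5 ms
and 1 ms grids are enumerated and augmented exactly (their cardinalities are
asserted) without training on them by default.

## What the synthetic experiments show — and what they do not

They demonstrate, end to end and against known ground truth: correct
acquisition-specific timing; simulator correctness against closed-form and
step-refinement oracles; that a network trained on per-acquisition simulated
signals recovers T1 with several-fold smaller bias and error than the
3-parameter fit under matched conditions; the directional T2 dependence of
the conventional fit's bias; and exact reproducibility. They do not
demonstrate performance on scanner data: no B0/B1 inhomogeneity, no motion,
no partial-volume mixing, no flow, Gaussian rather than Rician magnitude
noise, and piecewise-constant anatomy. The in-vivo and bench-phantom
figures reported for the original method are not reproducible without that
data; the digital-phantom statistics here are the synthetic analogue, not a
re-measurement.

## Known limitations

- Per-vector normalization imposes the MMSE bias floor discussed above;
  recovering the raw-signal information would require a gain-calibrated
  input convention.
- The 1 ms-step database (533,400 entries → 5.33 M training rows) is
  supported but slow to simulate/train at desk scale (hours).
- Arrhythmia handling (mistrigger rejection) is out of scope; trigger series
  are taken at face value.
- DICOM ingestion is not implemented; stacks move as NIfTI + JSON sidecar.
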