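# Methods

This note documents the models, parameter choices and numerical
conventions behind `qmi`, and what the synthetic cohort does and does not
establish about real data.

## The scientific procedure

The analysis asks whether small acute cortical infarcts leave an
iron signature behind after the visible lesion resolves. Per lesion and
monthly visit it computes the mean of six quantitative parameters
(DWI trace, MD, FA, R1, R2, R2\*) inside the lesion and inside a local
control region, takes the lesion-minus-control difference, realigns the
series so the onset visit is time 0, subtracts the pre-onset mean, and
compares three stages — pre-lesional (the visit immediately before
onset), lesional (onset) and post-lesional (last available follow-up) —
with a one-way repeated-measures ANOVA and post-hoc paired t tests.
A rising post-lesional R2\* relative to pre-lesional values is the
iron-accumulation readout.

## Synthetic cohort

No imaging data are distributed with the analysis, so all inputs come
from a generator whose defaults define the study conditions:

* **Geometry.** A 72 × 72 × 18 grid of 0.8 × 0.8 × 2.0 mm voxels holding
  an ellipsoidal three-compartment brain: CSF core, white matter, and a
  cortical grey-matter shell (the outer ~25% of the ellipsoid radius).
  All visits are generated pre-aligned on this grid; registration is out
  of scope.
* **Tissue values** (typical 3 T): R2\* = 1 / 15 / 30 s⁻¹ for
  CSF / cortical GM / WM — the ordering the 5–30 s⁻¹ acceptance window
  is designed around — R1 = 0.25 / 0.83 / 1.2 s⁻¹, R2 = 0.5 / 12.5 /
  14.3 s⁻¹, MD = 3.0 / 0.8 / 0.7 × 10⁻³ mm²/s, FA = 0.05 / 0.15 / 0.45,
  and DWI-trace intensities chosen so cortex is bright at both shells.
* **Acquisition.** Ten monthly visits. The GRE series has 6 echoes at
  TE = 4.92 … 29.52 ms with magnitude PD·exp(−R2\*·TE) and phase
  2π·f·TE wrapped to (−π, π], where f is a static field-offset map:
  a smooth background (a few Hz across the head) plus localized
  negative dips at lesion sites that emulate paramagnetic perturbations
  and make the lesions SWI-testable. The spin-echo series for R2
  mapping uses the same mono-exponential machinery (10 echoes,
  ΔTE = 10 ms, no stimulated-echo effects).
* **Noise.** Complex Gaussian noise (default sd 0.01 ≈ 1% of CSF signal)
  on the real/imaginary channels before magnitude extraction, giving
  Rician magnitude statistics; directly emitted parameter maps get
  additive Gaussian noise of 2% of the cortical-GM value. Estimator
  unit tests use the noiseless mode (sd = 0).
* **Lesions.** Spheres of 3 mm diameter (9 voxels at this resolution)
  placed where the whole sphere fits inside the cortical shell, at least
  8 mm apart, with onsets spread over interior visits (2–7 of 10).
  Additive stage deltas: acute (onset visit) DWI +0.30, MD −0.16 × 10⁻³
  mm²/s, R1 −0.12 s⁻¹, R2 −2.0 s⁻¹, R2\* −3.0 s⁻¹, FA 0; from the next
  visit onward everything returns to baseline except R2\* = +2.0 s⁻¹
  (iron overshoot). In the default cohort each lesion's deltas are
  scaled by a seeded uniform factor in [0.8, 1.2]: real lesions vary in
  severity, and this between-lesion variance is what the ANOVA's error
  term estimates.

What the phantom does **not** emulate: realistic anatomy and cortical
folding, k-space/coil effects, motion and distortion, phase wraps from
large-scale field inhomogeneity, partial-volume mixing within voxels
(compartments are crisp), and diffusion tensor physics (DWI/MD/FA are
emitted as parameter maps, since only ROI statistics consume them).
Passing tests therefore demonstrate correctness of the estimators and of
the analysis logic under the stated signal models — not robustness to
scanner artifacts.

## R2\* and R2 estimation

Integrating dS/dTE = −R2\*·S from the first to the last echo gives
S₁ − S_N = R2\*·∫S dTE, hence the closed form

    R2* = (S₁ − S_N) / Σᵢ (TEᵢ₊₁ − TEᵢ)(Sᵢ + Sᵢ₊₁)/2 .

Echo times are milliseconds at every interface and converted to seconds
internally; rates are s⁻¹. On the 6-echo protocol the trapezoidal
overestimate of the integral biases the estimate low by ~0.2% at
30 s⁻¹ (second order in the echo spacing), far inside the 5% oracle
band. Voxels with a vanishing integral (zero signal) are dropped from
the validity mask. Negative estimates (S_N > S₁ under noise) are kept
as values — the downstream 5–30 s⁻¹ window removes them from ROI means.
The nonlinear least-squares fit (vectorised Gauss–Newton, log-linear
initialisation, non-converged voxels dropped and counted) exists as an
accuracy reference, not the production path. R2 uses unweighted
log-linear least squares on positive magnitudes.

## SWI

Filtering wrapped phase directly in image space corrupts phase wraps, so
the high-pass is homodyne: I = M·exp(iφ) is Fourier transformed, the
centred spectrum is windowed by a 12 × 12-point 2-D Hamming kernel
(zero outside) to form a low-pass reference L, and the high-pass phase
is arg(I·conj(L)). The window is sampled symmetrically about the DC bin;
an off-centre window would leak spurious phase into magnitude-only
structure, breaking the zero-phase identity SWI ≡ echo-averaged
magnitude. The mask is linear in negative phase, f(φ) = (π + φ)/π for
φ < 0 and 1 otherwise, applied as f⁴ ("self-multiplied four times"
read as final exponent m = 4, standard SWI nomenclature). Negative
polarity is the default because paramagnetic sources should darken the
image; the polarity is a switch since phase handedness is
scanner-dependent. Echo combination is the unweighted arithmetic mean.
No minimum-intensity projection, unwrapping or QSM.

## Lesion screening

The visual criteria become thresholds: cortical voxels with DWI-trace
z ≥ 3 (z-scored against the cortical mean/sd of the same visit) are
grouped into 26-connected components; a component is accepted if its
maximum diameter is < 5 mm, its mean MD z-score is ≤ +1 ("hypo- or
isointense" on MD), it lies inside the cortex mask, and it has ≥ 3
voxels. The size floor is needed because under z-scoring the expected
number of supra-threshold noise voxels — and of chance-adjacent pairs,
about 0.5 per volume on this cortex — is independent of the noise
level; three mutually connected false voxels are rare (a lesion-free
volume is clean in >95% of seeds), and a sub-3-voxel lesion is below
the 2 mm slice thickness in any case. Screening uses the b = 3000
trace (higher infarct conspicuity); the longitudinal analysis uses the
b = 1000 trace as its DWI panel. The diameter convention is the maximum
pairwise distance between voxel centers plus one mean voxel extent, so
a single voxel has a nonzero diameter; components above 400 voxels are
first reduced to their boundary voxels (which preserves the maximum).
Detections are ordered by size, then seed coordinate, for determinism.

## Control ROI, acceptance window, normalization

The control region is the one-voxel 26-neighbourhood shell (dilation
minus lesion). Because it is adjacent and approximately symmetric around
the lesion, any spatially smooth additive bias affects both ROIs almost
equally: for a linear field the two centroids coincide and cancellation
is exact to first order, leaving a curvature term of order
(ROI radius / field length scale)² — measured at ≲0.2% of the bias
amplitude for fields varying over the head. ROI means for **all**
parameters at a visit are gated by that visit's own R2\* map through the
inclusive window [5, 30] s⁻¹; a gated-out ROI yields NaN (flagged
missing), never a silent zero. Lesions with fewer than 3 accepted lesion
voxels at any visit are excluded as pial-surface/partial-volume cases.
Series are realigned to onset and the mean of all pre-onset differences
is subtracted, so pre-lesional entries average to zero by construction
(and the operation is idempotent). Lesions with onset at the first or
last available visit are excluded (no pre- or post-lesional data).
The three stage values entering inference are the visit immediately
before onset, the onset visit, and the last available visit; interior
follow-up visits are carried in the aligned series (and plotted) but do
not enter the tests.

## Inference

The repeated-measures ANOVA partitions SS_total into lesion, stage and
error components; F = MS_stage/MS_error on (k−1, (k−1)(n−1)) df, no
sphericity correction, matching the convention of reporting unadjusted
post-hoc two-tailed paired t tests (a Holm adjustment is available but
off by default). Zero error variance is reported as a limiting p-value
(0 or 1) with a warning rather than NaN. Lesions are treated as
independent units even when several could share a subject — a known
simplification of per-lesion analyses. Type-I calibration under a
simulated null (n = 15, 10⁴ replicates) lands in [0.04, 0.06] at
α = .05 for both tests, and F = t² holds at two levels to 10⁻¹⁰.

## Problem sizes and determinism

The default cohort (72 × 72 × 18 grid, 10 visits, 15 lesions) runs end
to end in a few seconds on one CPU; the calibration uses 10⁴ replicates.
These sizes make the full suite and the acceptance script cheap to rerun
while keeping every Monte-Carlo tolerance comfortably resolved. All
randomness flows through `numpy.random.default_rng` seeds carried in the
specs/configs; two runs with the same seed produce byte-identical
tables.

## Known limitations

* The phantom's crisp compartments understate partial-volume effects;
  the pial-exclusion rule is exercised only by construction, not by
  realistic cortical geometry.
* The static field-offset model makes lesion SWI contrast present at
  every visit (including pre-onset); modelling susceptibility evolution
  over stages was not needed for any consumer of the SWI volume.
* Motion artifacts, which motivate the local-control design in real
  data, are represented only by smooth synthetic bias fields in the
  cancellation tests.
* R1 maps are consumed, never reconstructed; diffusion maps are emitted
  directly rather than fitted from diffusion acquisitions.
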