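# Methods

## Scope

This package implements simultaneous myocardial T1/T2 mapping by
Bloch-dictionary matching ("multimapping"): a ten-beat, ECG-triggered,
single-shot bSSFP acquisition with two inversion pulses and three T2
preparations, reconstructed by phase-sensitive polarity restoration (PSIR)
followed by two-stage dictionary matching with a global B1 correction.
Alongside it sit the two clinical reference methods it is compared
against — MOLLI 5(3s)3 T1 mapping with Look-Locker correction and
four-echo T2prep-bSSFP T2 mapping — plus synthetic-hematocrit ECV mapping,
a short-axis numerical phantom with ground truth, and the agreement
statistics used to compare mapping methods.

## Signal model

The sequence engine (`sequence_model`) simulates a single on-resonance
isochromat per pixel.  Assumptions:

- **On-resonance, single isochromat.** No off-resonance profile, no
  slice-profile integration, no magnetization transfer, diffusion or flow.
  This matches common dictionary-matching practice and keeps an
  independent per-TR oracle tractable.
- **bSSFP shot.** Each single-shot readout is `n_startup` linearly ramped
  startup pulses followed by `n_readout_lines` pulses of alternating RF
  phase (modeled as alternating rotation sense about one axis), TR
  spacing, free relaxation between pulses, and an echo at TE = TR/2.  The
  sample is the transverse magnitude at the k-space-centre echo (line
  `n_readout_lines/2` for linear profile order), signed by the
  longitudinal magnetization entering the shot.  Residual transverse
  magnetization is discarded at shot end (no tip-back); Mz carries
  forward.
- **Preparations.** Adiabatic inversion is applied as `Mz -> -e Mz` with a
  fixed efficiency `e` (default 0.89); the hyperbolic-secant pulse
  integrator (`simulate_hs_inversion`) exists to validate that number, not
  to run per pixel.  T2 preparation is ideal: `Mz -> Mz exp(-TE/T2)`,
  occupying TE of sequence time with no T1 recovery (hard 90s plus an
  adiabatic refocusing train justify ideality).

Key defaults (multimapping protocol): flip angle 50 deg, TR/TE 2.3/1.2 ms,
10 startup pulses, 80 readout lines (320 mm FOV / 2 mm resolution /
SENSE 2), inversions 300 ms before the shots of beats 1 and 5, T2prep TEs
30/50/70 ms in beats 8–10.  The reference protocols are identical except
for a 35 deg flip angle and their own preparation schemes: MOLLI 5(3s)3
(11 beats at 60 bpm, nominal TIs 120/200 ms to the centre echo — vendor
values are proprietary, these are representative) and T2prep-bSSFP with
TEs 0/23/46/70 ms and three recovery beats between images.

The adiabatic pulse defaults are the classic HS1 constants beta = 672
rad/s, mu = 5 at the nominal 8.4 ms duration and 13.5 uT peak B1.  Bloch
integration (operator splitting, 10 us step) then yields an inversion
efficiency of 0.93 for myocardium (T1 1100 ms / T2 50 ms) and 1.00 in the
lossless limit.  Because the exact vendor pulse constants are not public,
beta and mu are configurable.

**Short R-R intervals.** When the 300 ms inversion delay does not fit
between the previous shot's end and the next shot (RR below roughly 507 ms
at the default readout length), the inversion is clamped to immediately
after the previous readout.  Dictionaries are built with the same engine
and the same clamping, so matching remains self-consistent at high heart
rates.

## PSIR

Polarity is restored per pixel by conjugating the phase of a reference
frame assumed positive everywhere — by default the last frame, which is
maximally recovered and follows the longest-TE T2prep.  Magnitudes are
preserved exactly; only signs are estimated.  Pixels whose reference
magnitude falls below a configurable noise floor default to +1 and are
flagged.  No spatial phase smoothing is applied by default (an optional
Gaussian smoothing of the reference is available for low SNR).

## Two-stage dictionary matching

Stage 1 builds a coarse dictionary — T1 100–2000 ms step 20, T2 10–300 ms
step 5, B1 0.5–1.2 step 0.05 (the published description gives no grids, so
these are package defaults) — and matches the pixels of a septal
myocardial ROI; the median matched B1, snapped to the grid, becomes the
single global B1 correction.  The median is used rather than the mean for
robustness to ROI edge pixels.  Stage 2 rebuilds a (T1, T2) dictionary at
that fixed B1 with 1 ms steps in T1 (and, by symmetry, in T2; defaults
T1 50–2500 ms, T2 10–300 ms) and matches every pixel.

Similarity is the normalized inner product between the signed measured
series and unit-norm simulated fingerprints — equivalent to least squares
under a free positive scale, and invariant to positive rescaling of the
data.  Ties break toward smaller T1, then smaller T2, then B1 nearest 1
(realized by entry ordering plus first-occurrence argmax).  The matcher
runs in chunked BLAS matrix products with de-duplication of identical
pixel rows and is tested for exact equality against a naive exhaustive
scan.  All-zero pixels are flagged and map to NaN.

## Reference fitting

MOLLI is fitted on magnitude data with the three-parameter model
`S(TI) = A - B exp(-TI/T1*)` and a polarity-restoration search (negate the
k earliest-TI samples for k = 0..n, keep the minimum-residual fit),
then Look-Locker corrected: `T1 = T1* (B/A - 1)`.  Initialization
A = max|S|, B = 2A, T1* = 800 ms.  T2prep-bSSFP T2 uses a two-parameter
monoexponential by default (optional three-parameter variant with
offset), initialized from the two-point closed form.

Both reference methods inherit well-known biases that the simulations
reproduce: MOLLI underestimates T1 (readout-driven saturation and
imperfect inversion), and T2prep-bSSFP overestimates T2 and drifts down
with heart rate.  In this model the dominant T2bSSFP mechanism is T1
recovery during the ~114 ms between the preparation and the k-space-centre
echo, plus incomplete recovery across the three-beat pauses at short R-R
intervals; the dictionary-matched T2 is heart-rate stable because the
dictionary is rebuilt with the scan-specific R-R intervals.

## ECV

`ECV = (1 - Hct) * dR1_myo / dR1_blood`, `dR1 = 1/T1_post - 1/T1_native`.
When no blood sample exists, hematocrit is estimated from native
blood-pool T1 as `Hct = 866.0 / T1_blood - 0.1232` (a published linear
relationship in R1 for native MOLLI blood T1 at 1.5T), clipped to
[0.2, 0.6] with a warning; the coefficients are fully configurable, and no
mapping-method-specific recalibration is invented.  Native and
post-contrast maps are aligned by exhaustive rigid registration (integer
shifts within ±10 px, rotations within ±5 deg step 0.5 deg) maximizing
normalized cross-correlation with bilinear interpolation; out-of-frame
pixels are excluded.  The returned transform is the displacement of the
moving image relative to the fixed one; `align()` applies its inverse.

## Phantom

The phantom emulates a mid-ventricular short-axis slice on a 160x160 grid
(2 mm nominal): a blood disk (radius 20 px), a myocardial annulus
(20–32 px), and an optional 60 deg lesion sector.  Default relaxation
times are literature-typical native 1.5T values — blood 1600/250 ms,
myocardium 1100/50 ms, lesion 1400/70 ms (edema-like) — chosen for
plausibility, configurable, and carrying no claim about any particular
cohort.  A second-order polynomial background phase and per-channel
complex Gaussian noise complete the forward model; SNR is defined as the
noiseless blood-pool magnitude in the last acquired frame divided by the
noise sigma.  What the phantom does **not** model: respiratory or cardiac
motion, through-plane flow (the mechanism behind in vivo blood T1
overestimation), coil sensitivities, B0 inhomogeneity, and partial-volume
edges beyond pixelation.  Passing phantom tests therefore demonstrates
the correctness of the reconstruction chain, not in vivo accuracy.

## Statistics

Bland–Altman (bias, bias ± 1.96 SD limits), two-tailed paired t tests at a
Bonferroni-corrected threshold (0.05/4 = 0.0125 for the four standard
comparisons), squared Pearson correlation, and the absolute-agreement
two-way single-measure intraclass correlation ICC(A,1) from ANOVA mean
squares, with the McGraw & Wong F-based confidence interval (the
average-measure form is available via a flag).  A Shapiro–Wilk normality
check is exposed but informational.  All statistics are tested to 1e-10
against direct textbook-formula evaluation, and the ICC against an
independent implementation.

## Numerical choices and degenerate inputs

- Dictionary entries and matching in float64; unit normalization guarded
  against zero-norm entries.
- MOLLI fits that never converge, all-zero matching pixels and T2 fits
  with fewer than two positive samples are flagged; flagged pixels are NaN
  in maps and excluded from ROI statistics and counts.
- Zero-variance difference vectors in the paired t test: p = 1 when the
  mean difference is zero, p = 0 otherwise.  All-identical rating matrices
  give ICC (1, 1, 1).
- Flat images return the identity transform from registration, with a
  warning.

## Problem sizes used in the validation suite

The test suite and the reproduction script favour sizes that exercise
every code path at full fidelity: the fine dictionary is built on T1
200–2000 ms (1 ms steps; the full 50–2500 ms default remains available),
the Monte-Carlo precision experiment uses 20 noise seeds at SNR 30 on the
default phantom, and the heart-rate sweep covers 40–120 bpm in 10 bpm
steps with a 1 ms dictionary restricted to T1 1000–1200 ms / T2 30–70 ms
around the simulated myocardium.

## Known limitations

- The fixed scalar inversion efficiency ignores its tissue and B1
  dependence (the integrator shows ~0.93 for myocardium at the nominal
  pulse, not exactly 0.89).
- Ideal T2prep neglects refocusing-train imperfections and B1 dependence.
- Stage-2 matching fixes one global B1; spatial B1 variation within the
  slice maps into T1/T2 error.
- The MOLLI vendor fit is re-implemented from its standard published form;
  exact vendor TI schemes and fit variants are proprietary.
- The synthetic-hematocrit relationship was established for MOLLI blood
  T1; applying it to dictionary-matched blood T1 carries a known bias and
  no method-specific coefficients exist.
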