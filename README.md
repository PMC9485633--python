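# multimapping

Simultaneous myocardial T1 and T2 mapping by Bloch-dictionary matching,
with the clinical reference methods and agreement statistics needed to
evaluate it.

Quantitative cardiac MRI estimates the relaxation times T1 and T2 of
myocardium pixel by pixel; both are altered by edema, fibrosis,
infiltration and infarction.  The clinical workhorses map them in
separate breath-holds: MOLLI for T1 (precise but biased low) and
T2-prepared bSSFP for T2 (biased high and heart-rate dependent).  The
*multimapping* approach acquires both in one ten-beat breath-hold:
ECG-triggered single-shot bSSFP images in ten consecutive cardiac cycles,
with adiabatic inversion pulses before beats 1 and 5 and T2-preparation
modules (TE 30/50/70 ms) before beats 8–10.  Reconstruction restores the
signal polarity with a phase-sensitive (PSIR) operation, then matches
each pixel's 10-point signed fingerprint against Bloch-simulated
dictionaries built with the scan-specific R-R intervals: a first coarse
(T1, T2, B1) match over a septal ROI fixes one global RF-scale (B1)
factor, and a second fine (T1, T2) match at 1 ms resolution produces the
maps.  The match maximizes the normalized inner product

    (s / ||s||) . d(T1, T2, B1),    ||d|| = 1,

equivalent to least squares under a free positive scale.  Synthetic-ECV
maps follow from native/post-contrast T1 via
`ECV = (1 - Hct) ΔR1_myo / ΔR1_blood` with hematocrit estimated from
native blood T1 (`Hct = 866/T1_blood - 0.1232`), after rigid
registration.  Method agreement is quantified with Bland–Altman bias and
limits of agreement, Pearson r², Bonferroni-corrected paired t tests and
the absolute-agreement single-measure ICC(A,1).

Because no clinical data ship with the package, a short-axis numerical
phantom (blood pool, myocardial annulus, optional lesion sector, smooth
background phase, complex Gaussian noise) provides acquisitions with
known ground truth for every experiment.

Who is this for: MR physicists and image-analysis researchers who want a
transparent, fully simulated reference implementation of
dictionary-based T1/T2 mapping — to study its error sources, compare it
against MOLLI/T2-bSSFP behaviour, or prototype protocol changes.

## Worked example

```python
import numpy as np
from multimapping import *
from multimapping.phantom import (make_phantom, myocardial_roi, septal_roi,
                                  simulate_acquisition, snr_noise_sd)
from multimapping.io import StudyBundle, run_pipeline
from multimapping.dictionary_matching import fine_default_grid
from multimapping.sequence_model import multimapping_schedule

definition = PhantomDefinition()            # blood 1600/250, myo 1100/50, lesion 1400/70 ms
maps = make_phantom(definition)
params = PulseSequenceParams.multimapping() # 50 deg, TR/TE 2.3/1.2 ms, 80 lines
schedule = multimapping_schedule(rr_ms=1000.0, params=params)

sigma = snr_noise_sd(maps, 30.0, schedule=schedule, params=params)
series, _ = simulate_acquisition(maps, "multimapping", schedule=schedule,
                                 params=params, noise_sd=sigma, seed=7)
bundle = StudyBundle(series=series, schedule=schedule, params=params,
                     protocol="multimapping", masks={"septum": septal_roi(definition)})
result = run_pipeline(bundle, fine_grid=fine_default_grid(t1_min=200.0, t1_max=2000.0))

myo = myocardial_roi(definition)
t1_mean, t1_sd, n = roi_stats(result["t1_map"], myo)
t2_mean, t2_sd, _ = roi_stats(result["t2_map"], myo)
print(f"global B1 = {result['b1']:.2f}")
print(f"myocardial T1 = {t1_mean:.0f} +/- {t1_sd:.0f} ms (truth 1100, n={n})")
print(f"myocardial T2 = {t2_mean:.1f} +/- {t2_sd:.1f} ms (truth 50)")
```

prints (about 90 s on one CPU; most of it the 1 ms dictionary build):

```
global B1 = 1.00
myocardial T1 = 1103 +/- 36 ms (truth 1100, n=1356)
myocardial T2 = 50.5 +/- 3.3 ms (truth 50)
```

The estimated global B1 is exact, and the healthy-annulus ROI mean T1/T2
sit within a fraction of a percent of the phantom truth at SNR 30; the
per-pixel SDs reflect the noise, not bias (a noiseless run recovers every
pixel's on-grid truth exactly).  Two more numbers the package computes:

```python
simulate_hs_inversion(AdiabaticPulseParams(), TissueParams(1100.0, 50.0))
# 0.933  — inversion efficiency of the 8.4 ms / 13.5 uT HS pulse for myocardium
synthetic_hematocrit(1600.0)
# 0.418  — hematocrit estimated from a native blood T1 of 1600 ms
```

The same pipeline is scriptable from a shell: `multimapping
simulate-phantom`, `fit-multimap`, `fit-molli`, `fit-t2prep`,
`compute-ecv`, `evaluate` (see `multimapping --help`).

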