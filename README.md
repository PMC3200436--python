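# axiomerf

Axiomatic testing of reward-prediction-error signals in event-related
M/EEG sensor data — a tested, reusable reimplementation of the full
analysis pipeline, validated by parameter recovery on synthetic cohorts.

## The problem

A reward prediction error (RPE) is the signed discrepancy between an
outcome's value and its prior expectation. Formally (Caplin–Dean), any
neural signal s(valence, P) claiming to encode an RPE in a 2 (win/loss)
x 4 (outcome probability P ∈ {.25, .50, .75, 1}) gambling design must:

1. distinguish wins from losses at uncertain outcomes;
2. be modulated by P within *both* valences, with slopes that are
   nonzero, different from each other, and of **opposite sign**
   (for wins s ∝ +β(1−P), for losses s ∝ −β(1−P)); and
3. be equivalent for fully anticipated (P = 1) wins and losses.

Demonstrating that a difference wave (e.g. the feedback-related
negativity, FRN = loss − win at a fronto-central electrode) varies with
probability is **not** sufficient: the separate win and loss signals
can both scale *positively* with P — the classic EEG pattern — which
violates requirement 2 even while the FRN shrinks with P.

This package is for electrophysiologists and computational-psychiatry
methodologists who want to run (or scrutinize) that test: it provides
the gambling-session simulator, the preprocessing chain, the
sensor-to-image statistics, the mass-univariate ANCOVA with the
P = 1 inclusive mask, and the axiom battery, end to end.

## What the pipeline computes

Per subject, epoched outcome-locked data (trials x channels x samples,
−160..700 ms) are band-pass filtered (Butterworth 0.5–30 Hz, zero
phase), downsampled to 200 Hz, baseline-corrected (t < 0), cleaned
(amplitude rejection at 1.5e−10 T; blink SSP with 4 principal
components of the blink-locked average), and averaged per condition.
Averages are projected to a 64 x 64 pixel (3 mm) plane, linearly
interpolated, smoothed (Gaussian FWHM 8 mm x 8 mm x 8 ms), masked to
100–600 ms, and entered into a second-level ANCOVA: win/loss regressors
with mean-centered probability modulators ([4,3,2,1] → [1.5,.5,−.5,−1.5])
plus subject effects. Three F contrasts — valence [1,−1,0,0],
probability [0,0,1,1], interaction [0,0,1,−1] — are thresholded at peak
α = 0.005 with a 100-voxel extent filter (26-connected in x,y,t). The
interaction map is restricted to voxels where P = 1 wins and losses do
**not** differ (paired F at α = .05, inverted — the inclusive mask), and
condition means at the surviving peak (295–345 ms window) are graded
against the three axioms. An electrode-level FRN analysis (difference
wave minimum in 0–600 ms, one-way repeated-measures ANOVA over P with a
linear trend) mirrors the EEG tradition.

There is no deposited human data for this design; the package ships a
first-class synthetic-session generator (540 trials in 9 blocks with
gamble counts {0: 45, .25: 180, .50: 90, .75: 180, 1: 45} — read as 45
gambles at each certain probability, the only reading that sums to 540 —
and exact-frequency outcome realization) whose injected components have
known ground truth. See `docs/methods.md` for the full model and every
numerical choice.

## Worked example

Recover an injected prediction-error component (320 ms, gains ±β(1−P),
β = 100 fT) from a 17-subject synthetic cohort:

```bash
python analysis/04_glm_and_axioms.py --seed 0 --out-dir results/meg
```

Key lines of the report (seed 0):

```
[interaction] F_crit=8.19 (alpha=0.005, df=[1, 116]), extent_min=100
  cluster 1: k=47534 peak F=607.14 Z=14.50 at x=21 mm, y=9 mm, t=325 ms
[interaction, P=1-masked] 5 cluster(s); mask excluded 14.54% of voxels

Axiom battery at peak ({'x_mm': 21.0, 'y_mm': 9.0, 't_ms': 325.0, ...}):
  axiom 1 pass=True  axiom 2 pass=True (win slope -8.13e-14, loss slope 8.36e-14)  axiom 3 pass=True
  overall: compliant
FRN: probability F=178.41 p=5.022e-26; linear trend F=268.46 p=2.018e-11
```

The masked interaction localizes the injected component to 325 ms
(truth: 320 ms, within the 5 ms frame spacing plus subject latency
jitter); the window-mean slopes against probability at the peak voxel
have opposite signs with magnitudes equal to within 3%, as the ±β(1−P)
construction demands, and the battery grades the signal compliant. The
window-level repeated-measures ANOVA shows the valence x probability
interaction at F(3,48) = 180.3.

The EEG-pattern study, in which both valence signals rise with P while
the difference wave still shrinks with it:

```bash
python analysis/05_eeg_frn_study.py --seed 0 --out-dir results/eeg
```

```
axiom battery at Cz (200-300 ms window): overall = violated
  win slope +5.764e-07 V/P, loss slope +1.948e-06 V/P (sign opposition: False)
FRN (loss - win minimum, 0-600 ms):
  probability main effect F(3,48) = 11.92, p = 5.9e-06
  linear trend F(1,16) = 20.67, p = 0.00033
```

A textbook FRN — significant probability effect and linear trend — that
nonetheless **fails** the axiomatic test, because both slopes are
positive. This is exactly the dissociation the battery exists to expose.

Calibration of the statistical machinery:

```bash
python analysis/06_null_calibration.py --seed 0
# suprathreshold fraction at alpha=0.005: 0.00490 (nominal 0.005)
# equivalence-mask exclusion at alpha=0.05: 0.0500 (nominal 0.05)
```

The remaining drivers (`01_simulate_session.py`, `02_preprocess_session.py`,
`03_scalp_maps.py`) expose the single-session stages and the HDF5
session container; `axiomerf --help` offers the same stages as a CLI.

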