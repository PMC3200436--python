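# Methods

`axiomerf` implements an axiomatic test for reward-prediction-error (RPE)
signals in event-related M/EEG sensor data, validated end to end by
parameter recovery on synthetic cohorts. This note documents the model,
the synthetic data it is validated on, the statistical machinery, and the
numerical and design choices a maintainer would want to know about.

## The axiomatic test

A signed RPE integrates outcome value and prior expectation: it is
positive for wins and negative for losses, largest in magnitude for the
least likely outcomes, and exactly zero for fully anticipated ones. For
a 2 (valence: win/loss) x 4 (outcome probability P in {.25, .50, .75, 1})
gambling design this implies three testable requirements on any candidate
signal s(valence, P):

1. **Valence ordering** — win and loss signals differ at uncertain
   outcomes (tested with paired t-tests per probability; the default
   pass rule requires the low-probability conditions P = .25 and .50,
   where separation must be largest; the rule is configurable and all
   per-probability results are reported).
2. **Probability modulation with opposite signs** — the within-valence
   slopes of s against P are each nonzero, differ from each other
   (the valence x probability interaction), and have opposite signs.
3. **Equivalence at P = 1** — fully predicted wins and losses do not
   differ. This is a null claim; it is tested as absence of a
   significant difference at alpha = .05, and an optional two-one-sided
   (TOST) equivalence test with a user-set bound is available, since a
   non-significant difference cannot prove equivalence.

The overall grade is `compliant` when all three axioms pass and every
adjacent-probability step of the valence difference is individually
significant, `weakly_compliant` when the axioms pass but one or more
adjacent steps are not, and `violated` otherwise.

Because axiom 3 is an alpha-level null test, a *perfectly axiomatic*
signal is flagged in ~5% of cohorts by construction. Tests of the
battery therefore assert the compliance rate across seeds, not the
outcome of a single draw.

## Synthetic sessions

The generator is first-class, tested code: it defines the conditions
under which every downstream claim is validated.

**Design.** 540 target gambles per session in 9 blocks of 60: 45 gambles
at win probability 0 and at 1, 90 at .50, 180 at .25 and at .75.
Outcomes are realized by exact stratified assignment (at win probability
P with N gambles, exactly N·P wins), so realized frequencies match the
nominal probabilities in every session; an i.i.d. Bernoulli mode exists
behind a flag. Conditions are labeled by the probability of the
*realized* outcome (a loss after a .25-win gamble is a P = .75 loss),
which fills the 2 x 4 grid with 45/45/135/45 trials per valence. Note
the asymmetry: the P = .75 cells hold 135 trials, three times the
others. This is a property of the stated design, and it has statistical
consequences handled below.

**Evoked model.** Each trial's clean signal is a sum of components; a
component is a fixed sensor topography times a Gaussian temporal kernel
(peak latency, SD width) times a gain g(valence, P):

| component | peak | width (SD) | gain | default amplitude |
|---|---|---|---|---|
| valence | 200 ms | 30 ms | +a (win) / -a (loss) | a = 60 fT |
| probability | 340 ms | 40 ms | c·P, both valences | c = 50 fT |
| prediction error | 320 ms | 35 ms | +b(1-P) (win) / -b(1-P) (loss) | b = 100 fT |

Topographies default to the radial field of an ideal current dipole
sampled at the sensors, giving the bilateral two-lobed pattern of a
tangential source under an axial-gradiometer array; a Gaussian-on-scalp
pattern centered on a named electrode is available for EEG fixtures.
The MEG layout is a quasi-uniform 275-sensor spherical cap (Fibonacci
spiral, radius 9 cm, polar angles <= 1.05 rad) sized so its flattened
image fits the 64 x 64 (3 mm) grid. Per-subject variation: a lognormal
gain multiplier (sigma = 0.2) and a Gaussian latency shift (SD 5 ms)
shared by all components of a subject.

**Noise and artifacts.** Background activity is 1/f + white noise
(defaults 80 fT and 50 fT per sample at 600 Hz; exponent 1). Ocular
blinks add a rank-1 spatial pattern (dipolar source behind the eyes)
with a stereotyped 50 ms-SD time course at 0.8 pT, on 5% of trials;
channel jumps add a 5-sample excursion exceeding the rejection
threshold on 1% of trials. All stochastic draws derive from one
session seed through a documented SeedSequence split (noise / blinks /
jumps; subject seeds spawn from the cohort seed).

**What the generator does not emulate** — and hence what passing tests
do *not* establish about real recordings: realistic forward head
modeling and sensor cross-talk, non-stationary or spatially correlated
background sources, component-latency variability across trials,
learning or sequential effects across blocks, muscle/cardiac artifacts,
and continuous (non-epoched) acquisition.

## Preprocessing

Zero-phase 4th-order Butterworth band-pass (0.5-30 Hz for MEG, 2-30 Hz
for EEG; the high-pass is dropped when the low edge is 0), anti-aliased
downsampling to 200 Hz, pre-outcome baseline subtraction (t < 0),
whole-trial rejection at |amplitude| > 1.5e-10 T, and signal-space
projection of the ocular subspace: blinks are detected on the
strongest-loading ocular channel as robust-z (median/MAD) threshold
crossings (default |z| > 4, >= 200 ms apart), blink-locked segments are
averaged, and the top-k (default 4) spatial principal components of
that average form the projector I - BB'. Epochs span -160 <= t < 700 ms.
The driver enforces the order filter -> downsample -> baseline ->
reject -> SSP -> average.

**Robust averaging.** Per channel and time point, trials are averaged
by IRLS with residuals scaled by 1.4826·MAD; the scale is pooled over
trials x time per channel by default, because the sample MAD over a
few dozen trials alone is noisy enough that an unlucky low draw trims
perfectly clean values (per-point scaling remains available). The
default weight is a soft trim, w = min(1, (c/u)^2) with cutoff
c = 4.5: on outlier-free data no sample is down-weighted, so the
robust and arithmetic means agree (to well under 0.1 standard errors),
while a 20-SD burst receives weight < 0.1. The classical Huber weight
min(1, c/u) is available but is *not* the default: at its conventional
tuning (c = 1.345) it perturbs clean-data averages by up to ~1 SEM,
which would make "robust equals mean on clean data" false. Degenerate
scale (MAD = 0 with nonzero residuals) falls back to 1.2533 x mean
absolute residual; convergence is 1e-6 relative change or 20
iterations (warn and return the last iterate). The average is low-pass
filtered at 30 Hz afterwards, since reweighting can introduce high
frequencies. MEG condition averages use plain arithmetic means; the
robust averager is the EEG default and available for either modality.

## Scalp images

Sensor positions are projected azimuthal-equidistantly about the vertex
(a sensor at polar angle theta maps to radius r·theta, preserving
great-circle distance; orthographic available via config), then each
condition average is rasterized per frame by barycentric interpolation
over the Delaunay triangulation of the projected sensors onto a
64 x 64 grid of 3 x 3 mm pixels (grid center = projection origin;
coordinates reported in mm). Pixels outside the sensor hull are invalid
and excluded from all statistics rather than extrapolated. Volumes are
smoothed with a separable Gaussian of FWHM 8 mm x 8 mm x 8 ms
(SD = FWHM/2.3548 per axis), renormalized over valid pixels at the hull
boundary so constants are preserved, and masked temporally to
100-600 ms (101 frames at 200 Hz).

## Second-level model and inference

One image row per subject x condition (17 x 8 = 136). Regressors: win
and loss indicators plus one probability modulator per valence, coded
[4, 3, 2, 1] over P = [.25, .50, .75, 1] and mean-centered within each
valence's rows ([1.5, .5, -.5, -1.5]); subject block effects enter in
sum-to-zero coding (full-rank alongside win + loss = constant) and can
be disabled. F contrasts: valence [1, -1, 0, 0], probability
[0, 0, 1, 1] (sum of slopes), interaction [0, 0, 1, -1] (the RPE
signature). Fitting is per-voxel least squares with the
extra-sum-of-squares F and classical residual df = n - rank(X); the
critical value is the alpha-quantile of F(df) computed from these df
and logged (an externally fixed F_crit is never hard-coded, since
software-specific non-sphericity adjustments are not recoverable).

**Row weighting.** Because the P = .75 cells average 135 trials against
45 elsewhere, condition-average rows are heteroscedastic and a plain
OLS voxel test is miscalibrated (measured null rate 0.0096 at
alpha = 0.005). The pipeline therefore passes each row's kept-trial
count as a known relative precision; rows are rescaled by sqrt(count),
i.e. ordinary least squares on the variance-standardized problem.
`fit_and_contrast` without weights remains plain OLS.

**Thresholding.** Voxels above the peak-level alpha = 0.005 quantile
form 26-connected components in (x, y, t) (6/18 selectable); clusters
below 100 voxels are dropped ("extent 100" is read in voxels of the
3 mm x 3 mm x 5 ms grid). Peaks are reported in mm/ms with Z-equivalents
(standard-normal quantile of the F upper-tail probability). Note that
at FWHM 8 mm/8 ms the extent filter is weak protection: smoothed null
noise routinely forms blobs of 100-600 voxels, so surviving small
clusters must be interpreted against their peak statistics (null peaks
reach Z ~ 4 against ~14 for recovered signals). No random-field or
permutation correction is applied (out of scope).

**Inclusive masking.** The fully-predicted outcomes enter a separate
matched-subject comparison: per voxel, a paired F test (t squared,
df (1, n-1)) of win-P1 vs loss-P1 images at lenient alpha = .05. The
inverted sensitivity map — voxels where certain wins and losses do
*not* differ — multiplies the interaction map before clustering, so the
RPE candidate is only sought where axiom 3's premise holds. Under the
null the mask excludes ~5% of voxels; in recovery runs it excludes more
(~15%) because the valence component genuinely differs at P = 1 in
regions remote from the RPE source.

## Window analyses

Condition means over a stated window (295-345 ms at the interaction
peak voxel for the MEG-style analysis; 200-300 ms at Cz for the
EEG-style analysis) feed a two-way repeated-measures ANOVA implemented
as the explicit within-subject sums-of-squares partition, each effect
tested against its own effect-by-subject interaction with uncorrected
df (no sphericity correction by default, Greenhouse-Geisser is not
reported); degenerate cells are handled explicitly (zero numerator ->
F = 0, p = 1; zero denominator with nonzero numerator -> F = inf,
flagged). The linear trend of the valence difference uses the
orthogonal polynomial contrast [-3, -1, 1, 3] as a one-sample t
(reported as F = t^2). Paired t-tests are reported uncorrected (a Holm
option exists, off by default).

The FRN analysis takes the per-subject loss-minus-win difference wave
at one electrode, defines the FRN as the minimum within the search
window (0-600 ms; earliest sample on ties, for determinism) with its
latency, and runs a one-way repeated-measures ANOVA over probability
plus the linear trend. Because the FRN is a minimum statistic its
expectation is biased negative by residual averaging noise, and the
bias differs across conditions through the unequal cell counts — a
property of the stated design that the EEG study conditions must (and
do) overcome with literature-typical effect sizes (FRN ~5 uV against
~6 uV trial RMS in the 2-30 Hz band at 45-135 trials per cell).

## Problem sizes and reproducibility

The validation suite runs the full cohort once (17 subjects, 540 trials,
275 channels, simulated at 600 Hz and analyzed at 200 Hz; 64 x 64 x 101
volumes), the EEG study at 17 subjects x 11 electrodes, the null
calibration on 100 replicates of direct second-level noise images
(16 x 16 x 6 grid — the voxel F test is exact at any grid size), and
scaled-down cohorts (3-8 subjects, 48 channels) for end-to-end
determinism and null-behavior checks. Long sessions are held in float32
(statistics upcast to float64 where it matters); everything is
reproducible bit-for-bit from (config, seed), and every pipeline stage
appends a provenance record to the session container.

## Known limitations

- Sensor-space only: no source localization, no forward model.
- Cluster extents carry no corrected p-values; inference rests on the
  peak-level threshold and the recovery/null contrast documented above.
- The axiom-3 rule inherits the logic of testing a null: its 5%
  false-exclusion rate is irreducible without an equivalence bound.
- The generator's independence assumptions (trials, subjects) are
  stronger than real data warrant; between-subject variance enters only
  through gain and latency scaling.
- Robust averaging estimates one noise scale per channel (pooled over
  time); weights are per sample but there is no spatial pooling, and
  genuinely non-stationary noise within an epoch is mis-scaled.
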