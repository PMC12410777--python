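# Methods

This note documents the models, numerical choices and limitations behind
the package: what the synthetic cohort emulates, how each preprocessing
and feature-extraction step is defined, and how the small-sample
statistics are computed.

## Study design being modelled

Seventeen participants anticipate a brief social interaction for 300 s
while seven signal streams are recorded: 27-channel EEG, 2-electrode ECG,
4-electrode EOG, skin conductance and a respiration belt at 500 Hz; a
binocular pupil-diameter trace at 200 Hz; and head-roll angular velocity
from a head-mounted gyroscope at 110 Hz. A 7-item anxiety questionnaire
(each item a continuous 0–3 visual-analogue scale) is administered
immediately before and after; the change in the mean item score defines
each participant's anxiety response, and a median split of the 17 change
scores defines the anxious (9) and non-anxious (8) groups.

## Synthetic cohort

The generator is driven by one integer seed through a single
`numpy.random.Generator`, making a cohort bit-reproducible. It emulates
only the statistical structure the analysis consumes:

- **ECG** — a narrow Gaussian QRS template (σ = 8 ms, amplitude 1
  arbitrary-mV unit over broadband noise of SD 0.02) placed at beat times
  with inter-beat intervals 60/HR plus Gaussian jitter (default SD 30 ms).
  The template is split with opposite sign across the two electrodes so
  the bipolar derivation recovers it; a common-mode baseline wander
  cancels in the derivation.
- **EDA** — tonic level (+ optional slope and sub-0.02 Hz sinusoidal
  drift) plus sparse skin-conductance responses: Poisson events
  (default 3/min), instantaneous rise, exponential decay τ = 3 s,
  amplitudes 0.1–0.5 μS. Noiseless tonic and phasic components are stored
  as ground truth.
- **Respiration** — a sinusoid at rate/60 Hz plus noise; rates outside
  6–30 breaths/min trigger a warning because they leave the 0.1–0.5 Hz
  analysis band.
- **Pupil** — per-eye slowly varying traces (two sub-0.1 Hz sinusoids,
  small offset and linear trend).
- **Head roll** — zero-mean Gaussian noise band-limited to 0.5–35 Hz and
  rescaled to the requested sample variance exactly. The band is kept
  well inside the 45 Hz effective low-pass used in preprocessing: a
  forward–backward 4th-order filter attenuates power as |H|⁴, so content
  near the cutoff would lose up to half its power and break variance
  conservation; with a 35 Hz upper edge the loss through the whole
  pipeline is ~3%, comfortably inside the 10% recovery tolerance.
- **EEG** — per channel, a sum of five independent noise processes shaped
  by band-pass filters (delta 1–4, theta 4–8, alpha 8–13, beta 13–30,
  gamma 30–50 Hz), each scaled so its variance equals the requested PSD
  level times the bandwidth; plus per-channel gains on the ground-truth
  vertical/horizontal EOG traces and a 50 Hz power-line sinusoid
  (default 3 μV). The four EOG electrodes carry ±half the ocular traces so
  the vertical and horizontal bipolar derivations recover them.
- **Questionnaire** — item scores are a zero-sum jitter around total/7,
  bounded so each item stays in [0, 3] and sums are exact. Change scores
  are drawn all-distinct with every anxious change above every
  non-anxious change, so the median split recovers the generating groups;
  ties would make a median split ambiguous and are rejected downstream.

Group templates encode the between-group contrasts: heart rate
79.445 vs 66.75 bpm, respiratory rate 17.879 vs 15.37 brpm, tonic level
8.099 vs 4.84 μS, head-roll variance 8.261 vs 2.104 dps², and 2× boosts of
theta/beta/gamma EEG power in the anxious group. Between-subject scatter
is Gaussian for HR (SD 5 bpm), respiration (1.2 brpm) and tonic level
(1 μS) and lognormal (SD 0.25 of log) for roll variance and per-band EEG
power — deliberately tighter than a clinical sample so that a 17-person
synthetic cohort separates reliably.

What the generator does **not** emulate: realistic cardiac morphology,
EEG microstates or 1/f spectra, blinks, eye-gaze kinematics, movement
artifacts, device clock drift, or skewed/heavy-tailed between-subject
distributions. Passing tests therefore demonstrate that the pipeline's
operations are correct and calibrated on signals with the assumed
structure, not that the pipeline is robust to every artifact of real
recordings. Two known side-effects: (i) the interval-variability ratio
SD/RMS differs between groups simply because jitter SD is constant while
the mean interval differs, so the synthetic cohort shows a group effect
in this measure that the modelled study did not; (ii) head-roll PSD bins
separate across the whole 0.5–35 Hz band because the injected variance
ratio is broadband.

## Preprocessing

All filters are zero-phase: 4th-order Butterworth designs (second-order
sections) applied forward–backward with `sosfiltfilt`, plus a Q = 30
second-order IIR notch at 50 Hz for EEG. Cutoffs per modality: cardiac
2–30 Hz band-pass after bipolar derivation; tonic 0.05 Hz low-pass and
phasic 0.05 Hz high-pass; pupil 50 Hz low-pass; respiration 0.1–0.5 Hz
band-pass; head roll 50 Hz low-pass, clipped to 90% of Nyquist (45 Hz) at
the 110 Hz native rate where a 4th-order design at 50/55 of Nyquist is
numerically fragile. For the 0.05 Hz filters the reflection padding is
extended to three filter time constants (60 s at 500 Hz) so edge
transients do not contaminate a 300 s recording.

EEG order: mastoid re-reference (mean of TP9/TP10 subtracted, both
dropped, 27 → 25 channels) → 0.5–50 Hz band-pass + 50 Hz notch → EOG
regression → common average reference. The EOG regressors are the bipolar
vertical/horizontal derivations, filtered identically to the EEG; one OLS
model (intercept + both regressors) is fitted per channel over the whole
recording and only the fitted EOG contribution is subtracted. Regressors
with zero variance cause a warned pass-through.

Filtering precedes resampling deliberately: the 50 Hz low-pass and notch
sit exactly at the Nyquist frequency of a 100 Hz signal and would be
ill-posed after resampling. Resampling is polyphase rational resampling
(`resample_poly`, linear-extension padding), which preserves amplitude
spectra below the target Nyquist; 500, 200 and 110 Hz streams all map to
30 000 samples for a 300 s recording. Epochs are half-open windows
[k·5 s, k·5 s + 30 s) — 55 of them at 300 s — so adjacent epochs never
share a boundary sample.

## Feature extraction

- **Heart rate**: each epoch is z-normalized, first-differenced and
  negated; peaks above 0.5× the epoch maximum with a 250 ms refractory
  period are beats; the rate is 60 × n_intervals / Σ intervals, which is
  robust to partial beats at epoch edges. Epochs yielding < 2 peaks, a
  rate outside 30–240 bpm, or an interval coefficient of variation above
  0.4 are flagged missing — the CV gate is what rejects pure-noise
  epochs, whose threshold crossings are irregular, without touching
  physiological rhythms (CV ≈ 0.03 at 30 ms jitter).
- **Interval variability**: sample (n−1) SD of the inter-beat intervals
  divided by their RMS; dimensionless; needs ≥ 3 beats. Exactly 0 for a
  regular rhythm and invariant to rescaling all intervals.
- **Respiratory rate**: same normalized peak counting with a 2 s
  refractory period (30 brpm ceiling) and a 4–30 brpm plausibility range.
- **Tonic/phasic/pupil**: epoch means; pupil traces are zeroed to their
  first epoch per participant before testing.
- **Head roll**: sample variance per epoch.
- **Spectra**: Welch with 1 s Hann segments and 50% overlap at 100 Hz,
  giving exactly 1 Hz bins; band power is the mean over half-open band
  intervals, so gamma = [30, 50) excludes the Nyquist bin.

## Statistics

The rank-sum statistic reported is the sum of pooled midranks of the
anxious group. For tie-free samples with n1 + n2 ≤ 25 the two-sided
p-value is exact: the null distribution of the rank sum is built by the
standard counting recursion over subsets of ranks (cached per group-size
pair), and p = 2 × min(lower tail, upper tail), capped at 1. With ties or
larger samples a normal approximation with midranks, tie-corrected
variance and a 0.5 continuity correction is used. Cohen's d uses the
pooled (n−1)-SD denominator. Benjamini–Hochberg adjustment is the
standard step-up procedure (delegated to statsmodels), applied across the
51 roll PSD bins and across all 125 EEG channel × band cells; per-epoch
time-course p-values are deliberately left uncorrected and flagged
exploratory. Whole-task tests average each participant over all epochs
first; participants with no valid epoch are excluded and listed. The
"95% CI" descriptives are empirical 2.5/97.5 percentiles of the
per-participant values and are labelled as such.

Degenerate inputs are handled explicitly: constant epochs give missing
features, zero pooled SD gives an undefined (NaN) effect size, p-values
outside (0, 1] are rejected by the BH routine, and a median split over
tied change scores raises rather than guessing a tie policy.

## Problem sizes and calibration checks

The test suite validates calibration by simulation at the study's group
sizes (9 vs 8): per-epoch type-I error over 1000 null cohorts must land
in [0.03, 0.07], and BH-corrected EEG maps over 300 null cohorts must
make essentially zero discoveries (median 0). Parameter-recovery checks
run 4-participant, 300 s cohorts through the full pipeline; the
acceptance script uses 9 recordings per modality (8 for roll) at 300 s.
These sizes were chosen as the smallest that keep Monte-Carlo error well
below the recovery tolerances (1 bpm, 0.5 brpm, 5%, 10%).

## Known limitations

- The exact rank-sum path assumes tie-free data; heavily tied features
  silently use the approximate path, which is anti-conservative for very
  small samples with many ties.
- EOG regression is fitted once per recording; time-varying ocular
  coupling would leave residual artifacts.
- The tonic/phasic split by complementary 0.05 Hz filters assigns the
  slow tail of each skin-conductance response to the tonic component, so
  tonic means are biased upward by roughly rate × amplitude × τ /
  duration (≈ 0.05 μS at the defaults).
- Resampling a 0.5–50 Hz band-passed EEG to 100 Hz attenuates content
  just below 50 Hz (anti-alias transition band); gamma-band comparisons
  are unaffected because both groups see the same attenuation, but
  absolute gamma power is underestimated near the band edge.
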