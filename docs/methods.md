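# Methods

This note documents the models implemented in `affectcare`, the parameter
choices that matter, and what the synthetic experiments do and do not show.

## Signal simulator (`signal_sim`)

The simulator is a forward model of a low-cost wearable acquisition chain;
its purpose is to provide labelled recordings with known class structure,
not biophysical fidelity beyond the statistical/spectral realism the
downstream features consume.

**ECG.** A beat-onset train with mean interval 60/heart-rate and Gaussian
beat-to-beat jitter (`hr_variability`, expressed as a fraction of the mean
interval, floored so intervals stay positive) is rendered as a fixed
sum-of-Gaussians PQRST template per beat, riding on a 1.45 V baseline with
a small 0.25 Hz respiratory wander. A template train was chosen over a
biophysical model because the pipeline consumes only per-recording
statistics.

**PPG.** The same beat-train construction rendered as a systolic Gaussian
pulse plus a smaller dicrotic bump, with per-class amplitude.

**EDA.** Skin *resistance* is modelled directly: a slowly drifting tonic
level (two incommensurate sinusoids at 0.02 and 0.055 Hz) plus
skin-conductance responses arriving as a Poisson process
(`eda_scr_rate_per_min`), each a resistance drop with ~0.75 s rise and
~3.5 s decay. The resistance is mapped to volts through the sensing
front end's voltage divider `V = vref · R1 / (R1 + RL)` (R1 = 500 kΩ,
vref = 3.3 V), so arousal (lower resistance) raises the recorded voltage.

**Contaminants and digitisation.** A mains sinusoid (default 50 Hz) with
configurable amplitude and a broadband EMG-like artifact (first-differenced
white noise, unit-RMS-normalised, scaled by `motion_artifact_level`) are
added before quantization. The ADC clips to [0, 3.3 V] and snaps to the
12-bit grid (step 3.3/4096 ≈ 0.0008 V); saturation, not an error, is the
defined out-of-range behaviour, mirroring real converters. Samples are
returned in volts on the code grid so downstream arithmetic is
unit-stable; `adc_counts` exposes integer codes.

**Defaults as study conditions.** Sampling rate 250 Hz (keeps the 48–52 Hz
stop band well below Nyquist) and 10 s per recording are package defaults;
neither is dictated by the problem, so they are declared here once and used
everywhere. The seven per-emotion parameter sets follow arousal/valence
intuition (fast heart, frequent SCRs and low tonic resistance for Afraid /
Angry; the reverse for Sad; Neutral calm) and were fixed a priori to be
separable but overlapping in heart-rate variance. Per-recording seeds are
spawned deterministically from the dataset seed.

## Band-stop filter (`preprocess`)

Order-3 Butterworth band-stop, 48–52 Hz, designed by `scipy.signal.butter`
and applied forward–backward (`filtfilt`) with reflect padding of 3× the
tap order — zero-phase response, which is appropriate for offline windowed
processing and keeps the group delay at zero at the cost of doubling the
effective magnitude order. The padding convention is fixed so outputs are
bit-reproducible.

A point worth documenting: for a *windowed* tone at the notch centre, any
linear zero-phase filter leaves a fixed amount of residual energy at the
window edges (the rectangular window leaks spectral energy past the notch;
equivalently, the filter's transient responds to the tone's apparent onset
and offset). The steady-state attenuation — better than −120 dB at 50 Hz
for this design, −40 dB across most of the stop band — is therefore
measured in the tests on tones long enough (minutes) that this constant
edge energy is negligible in the overall RMS, and separately on the
transient-free interior. Linear-predictive edge extension would suppress
the transient but would make the operator nonlinear, violating the
filter's linearity contract; the linear convention was kept.

## Features (`features`)

Six statistics per channel; sample (1/(N−1)) normalisation is used for the
standard deviation everywhere, including inside the z-normalisation. The
normalized variants AFDN and ASDN are the first/second difference
statistics of the z-scored samples — the second-difference normalized
statistic is genuinely a second difference (the pair (ASD, ASDN) differ
only in z-scoring, exactly like (AFD, AFDN)). Constant signals leave the
normalized statistics undefined; the default is an explicit
`DegenerateSignalError`, with `allow_constant=True` defining them as the
limit value 0 (the raw difference statistics are already 0). The assembled
vector is fixed at ECG block, PPG block, EDA block, six statistics each,
and features are computed on the *filtered* signal by default (a cleaned
signal is the natural input to statistics meant to reflect physiology, not
mains pick-up); passing `filter_spec=None` to `extract_vector` switches to
raw.

## Classifier (`emotion_model`)

A fully-connected network 18 → [32, 64, 128, 64, 32] → 7 with ReLU hidden
units, softmax outputs, and mean-squared-error loss against one-hot
targets; dropout 0.2 on hidden activations (inverted dropout, disabled at
inference) and an L2 weight penalty of 0.01. The L2 penalty follows the
scikit-learn normalisation — penalty `l2/(2·n_batch)·Σ‖W‖²`, gradient
`l2·W/n_batch` — which keeps it commensurate with the per-sample-averaged
data loss; an unnormalised per-batch penalty at this coefficient swamps
the MSE gradient and stalls learning. Training uses Adam (lr 1e-3, batch
32), early stopping on validation loss with min-delta 1e-3 and patience
20, restoring the best weights; inputs are standardised on training
statistics that travel with the model. All stochastic elements
(initialisation, shuffling, dropout masks) run off one seeded generator,
so training is reproducible at a fixed thread count. Cross-entropy is
available as a non-default loss.

The min-delta default of 1e-3 is the usable interpretation for a loss
bounded by 1; a literal min-delta of 10 (one published configuration of
this architecture reports that value, units unstated) would stop training
after the patience window regardless of progress and can be set explicitly
by anyone wanting that preset.

The 80/10/10 split computes test and validation sizes as round(0.1·n) and
absorbs the rounding remainder into the training partition.

Model objects follow the model/results idiom: `EmotionClassifier(...)`
holds data and config; `.fit()` returns `EmotionClassifierResults` with
the per-epoch history frame, `predict` / `predict_proba`, `evaluate`
(accuracy, MSE, 7×7 confusion frame), `summary()`, and JSON-header +
npz-blob persistence.

## Recommender (`fitcla`)

Compatibility between an activity's impact and a user's tolerance on the
4-level ordinal scale is 1 when impact ≤ tolerance and otherwise decays
linearly with the ordinal gap (1 − gap/3); the `dangerous_tools` feature
is binary (compatible or not), since partial credit for unsafe tool use
has no sensible meaning. The activity score is
`Σ_f w_f · compat_f + preference_share · preference(activity)` with equal
initial weights summing to `feature_cap = 0.9` and
`preference_share = 0.1`. Features an activity does not rate count as
"none" impact; features a user does not rate count as "hard" tolerance
(no declared limitation).

Feedback: acceptance adds the learning step δ = 0.05 to the activity's
preference (clipped to [0, 1]) and resets the user's consecutive-denial
counter; denial subtracts δ and — only when the denied activity's score is
at least `close_fit_min_score` (default 0.75) — advances the counter.
At 7 consecutive close-fit denials the feature cap is reduced by 0.05, the
preference share raised to keep the sum at exactly 1 (feature weights are
rescaled proportionally), the counter resets and a "re-weight" caregiver
notification is logged; the nudge re-applies if denials continue. δ and
the re-weight step are configurable; 0.05 makes the 7-denial dynamics
visible within short simulations. The denial counter is interpreted as
*consecutive* denials because the threshold is meant to flag abnormal
behaviour, not accumulate over a lifetime.

Emotion policy (configurable): Sad and Neutral → high-intensity boosters;
Angry, Afraid, Disgusted → low-intensity de-stressers; Happy and
Surprised → no filter. If the filter empties the catalog the recommender
falls back to the full catalog and logs a notification. Ties are broken by
higher preference weight, then lexicographic activity id, so ranking is
deterministic. Scheduling is earliest-fit into the user's free slots, a
no-fit returning `None` rather than raising.

## Synthetic-recovery experiment and its limits

The acceptance experiment generates 7 × 60 recordings at the default
conditions (seed 1), filters, extracts features, splits 80/10/10, trains
with the default configuration, and requires ≥ 0.90 held-out accuracy;
it completes in a few seconds. The generator's class-conditional
parameters are *more* cleanly separated than real inter-subject
physiology: real recordings add inter-individual baselines, label noise
from self-report, posture and electrode artifacts, and overlapping
autonomic responses between emotions. Recovery here therefore validates
the pipeline's mechanics (filtering does not destroy class information,
the features carry it, the trainer finds it) — it is not evidence of
field accuracy on real subjects, where published accuracies for comparable
pipelines sit far below ceiling. The motion-artifact robustness test
(corrupting only the validation recordings must not raise validation
accuracy) checks the expected degradation direction for the same reason.

## Numerical and degenerate-input choices

- Quantization: round-half-to-even to the code grid; error ≤ step/2 in
  range; idempotent.
- Filter response values are floored at −300 dB (the notch zero is −∞).
- `filter_response` on an empty frequency list returns an empty array.
- Signals must have ≥ 3 samples (second differences need N ≥ 3); shorter
  construction fails early with `InvalidParameterError`.
- Splits need n ≥ 10 so each partition is non-empty.
- All dataset-level randomness derives from a single integer seed via
  spawned `SeedSequence`s; seeds are masked to 31 bits.

## Known limitations

- The ECG/PPG beat trains are drawn independently per channel, so
  beat-to-beat timing is not synchronised across channels (per-recording
  statistics, which the pipeline consumes, are unaffected).
- One feature vector per recording; no windowing within recordings.
- No spectral or HRV features; the six statistics are the whole feature
  set by design.
- The trainer is single-threaded numpy; it is sized for 18-dimensional
  inputs and hundreds of samples, not for large-scale training.
- Preference learning is a per-user per-activity scalar; no generalisation
  across similar activities.
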