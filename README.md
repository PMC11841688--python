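# avmotion

Audio–visual motion cue integration during active head movement: a tested
analysis pipeline covering simulation, kinematics preprocessing,
psychometric fitting, correlated-cue combination models, and model
evaluation.

During self-generated yaw head rotation, auditory and visual motion cues
start in different coordinate frames and must be compensated for
self-movement before they can be integrated. This package implements that
analysis end to end:

- **`avmotion.synthetic_data`** — a generative observer for gain-coded
  left/right judgments: interleaved trial schedules (8 conditions × 13
  gain levels × 30 repetitions), truncated-Gaussian head speeds,
  modality-specific compensation biases, jitter-inflated image noise, and
  a self-movement noise source shared across modalities within a trial.
  Also stimulus-trace kinematics (5 Hz positional jitter, leaky amplitude
  gating) and closed-form psychometric oracles for fixed head speed.
- **`avmotion.kinematics`** — head-trace preprocessing (zero-phase 8 Hz
  lowpass, causal 13-sample turn detection with its 7-sample lag, sweep
  segmentation, median velocity over the 20–60% region of the judged
  sweep, Gaussian velocity-distribution summaries) and eye-trace cleaning
  (confidence gating with linear gap fill, frequency-domain Gaussian
  smoothing, jerk-threshold saccade removal, VOR expectation
  `E = −H(1 + R/D)`).
- **`avmotion.psychometrics`** — maximum-likelihood cumulative-Gaussian
  fits with a lapse rate bounded at 0.02, gain-stratified nonparametric
  bootstrap, and an across-trial-noise model that marginalizes the
  amplitude-coded decision variable over head-speed variability.
- **`avmotion.cue_models`** — the three audio–visual predictions from
  unimodal fits: reliability-weighted integration (BCI), integration
  adjusted for the shared-noise correlation ρ = σ²_SM/(σ_a σ_v) (BCI+),
  and image-only integration after variance-sum-law subtraction (ICI,
  zero predicted bias), plus the shared-noise estimator with its
  negative-variance exclusion rule and per-replicate bootstrap
  propagation.
- **`avmotion.evaluation`** — squared-error tables (precision and bias,
  ICI excluded from bias), percentile bootstrap CIs of
  prediction-minus-empirical differences, RMSE of model-implied curves
  against observed proportions, and model ranking with per-case win
  counts.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria; the Monte-Carlo
parameter-recovery and model-discrimination criteria take a few minutes
each.

## CLI

```sh
avmotion simulate --config config.yaml --out sim/ --seed 1
avmotion fit --in sim/trials.csv --model standard --boot 2000 --seed 1 --out fits.json
avmotion predict --fits fits.json --sigma-sm sigma_sm.json --out predictions.csv
avmotion evaluate --fits fits.json --pred predictions.csv --out eval/
avmotion kinematics --in head.csv --what head --out head_summary.json
avmotion pipeline --config config.yaml --out run/ --seed 1
```

A config is a YAML file with an `observer` block (amplitude-unit noise
SDs, compensation gains, head-speed distribution, lapse), plus optional
`gains` (list or `"canonical"`), `n_reps`, and `n_participants`. Example:

```yaml
observer:
  sigma_img_audio: 8.0        # deg/s
  sigma_img_visual: 5.0
  sigma_img_audio_jitter: 14.0
  sigma_img_visual_jitter: 11.0
  sigma_sm: 4.0               # shared self-movement noise, deg/s
  r_audio: 0.97               # compensation gain; PSE = 1 - r
  r_visual: 0.85
  head_mu: 80.0               # deg/s
  head_sd: 0.0
n_reps: 30
gains: canonical
```

Trial tables are plain CSV (`participant_id, modality, audio_jitter,
visual_jitter, gain, response, head_velocity, sweep_index` with responses
`with`/`against`); traces are CSV with a JSON sidecar declaring the sample
rate and channel; every simulation output carries a sidecar with the
config hash and seed.

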