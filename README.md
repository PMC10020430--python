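# speechsev

Automated severity scoring of ataxic speech disturbance from three
standardized recordings per assessment — free speech (≥ 30 s), counting
one-to-ten-and-back, and 10 s of PATA syllable repetition. The pipeline
extracts 141 named features per recording set (117 prosodic + 24 lexical),
trains a gradient-boosted tree ensemble on severity labels 0–5 (SARA
item 4; anarthria, label 6, is excluded), and evaluates with a hold-out
plus 6-fold cross-validation design. Because clinical recordings of this
kind cannot be shared, the package includes a severity-parameterized
synthetic speech simulator, so the entire pipeline is buildable and
testable without any patient data.

## What the pipeline computes

1. **Pre-processing** (`speechsev.preprocess`) — peak amplitude
   normalization, an energy-based voice activity detector (geometric mean
   of the P10/P90 frame-RMS percentiles as threshold), and per-bin
   magnitude spectral subtraction of the voiceless frames' mean spectrum,
   on a shared 25 ms / 10 ms Hann STFT grid at 16 kHz.
2. **Prosodic features** (`speechsev.prosodic`) — 39 per task: spectral
   descriptors (centroid, bandwidth, rolloff, flatness, flux, RMS with
   mean/SD/IQR summaries plus dynamic range, centroid slope, flux P90),
   rhythm aggregates from Fourier and autocorrelation tempograms of the
   onset envelope, and word / syllable / sub-syllable band tempo peaks
   (0.5–2 / 2–8 / 8–30 Hz) with a pause ratio.
3. **Lexical features** (`speechsev.lexical`) — 8 per task from per-word
   transcripts with probabilities: detected/real word rates, word-duration
   statistics, and the mean word probability as an intelligibility
   (confidence) score. Transcription is a pluggable contract; the shipped
   backend reads JSON sidecar files.
4. **Modeling** (`speechsev.model`) — subject-grouped stratified splits,
   multiclass gradient boosting, exact and ±1-tolerance accuracy, Spearman
   rank correlation, bootstrap CIs, a label-permutation test, 6×6
   confusion matrices, and gain-based feature importance averaged per tree
   and across folds.
5. **Simulation** (`speechsev.synthetic`) — recording sets whose syllable
   rate, rhythm regularity, noise level, word probabilities, and pausing
   degrade monotonically with severity 0–5; all constants overridable.

## CLI

```bash
# generate a synthetic cohort (WAVs + transcript sidecars + manifest)
speechsev simulate --out-dir cohort/ --n-subjects 120 --seed 1

# extract the 141 features per recording set
speechsev extract --manifest cohort/manifest.tsv --out features.tsv

# train + evaluate (report JSON, confusion CSVs, importance TSV)
speechsev train-eval --features features.tsv --labels cohort/labels.tsv \
    --out-dir run/ --seed 1

# top features by mean gain
speechsev importance --importance run/importance.tsv --top 20
```

`train-eval` accepts a YAML config (`--config`) with keys `seed`,
`holdout_n`, `n_folds`, `n_boot`, `n_perm`, `n_estimators`, `max_depth`,
`learning_rate`; the full configuration is echoed into `report.json`.
Every command is deterministic given identical inputs and seed. Exit
codes: 0 success, 2 input error, 3 capability error (e.g. no transcript
sidecar and no speech-to-text backend).

## Layout

```
src/speechsev/
  audio_io.py     WAV I/O, mono float canonicalization, resampling
  _stft.py        shared STFT geometry (25 ms Hann, 10 ms hop, 16 kHz)
  preprocess.py   normalization, VAD, noise profile, spectral subtraction
  prosodic.py     spectral + tempogram + band-tempo features
  lexical.py      transcripts, word list, confidence and word statistics
  features.py     141-column feature assembly per recording set
  model.py        splits, boosting, metrics, importance, experiment driver
  synthetic.py    severity-parameterized cohort simulator
  cli.py          simulate / extract / train-eval / importance commands
tests/            unit, property and acceptance suites
scripts/acceptance.py
```
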