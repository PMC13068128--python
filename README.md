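# radarsleep

Contactless sleep staging from under-mattress Doppler radar, at desk scale.

Sleep laboratories score sleep stages from EEG in 30 s epochs, but
polysomnography is expensive and intrusive. Continuous-wave Doppler radar
under the mattress picks up chest-wall breathing motion, cardiac
micromotion and gross body movement without any body contact, and the
autonomic signature of each sleep stage (heart slowing and regular
breathing in deep sleep, high heart-rate variability and muscle atonia in
REM, movement in wake) makes staging from those signals possible. The
catch is data: labelled radar nights are scarce, so radar-only classifiers
overfit, while large wearable/PSG cohorts with the same kind of movement,
heart-rate-variability (HRV) and respiration-rate-variability (RRV)
features are public. `radarsleep` implements that whole pipeline —
feature extraction from multi-node radar I/Q waveforms, an LSTM sequence
stager, and cross-modality transfer learning — together with a seeded
cohort simulator so every stage runs end to end with no data download.

## What is inside

- **`radarsleep.simulate`** — seeded synthetic cohorts: Markov-chain
  hypnograms (five AASM stages W/N1/N2/N3/R on a 30 s grid) calibrated to
  a realistic architecture (N1 ≈ 7.3 % of epochs, mean total sleep time
  ≈ 428 min per 8 h night), stage-conditioned beat/breath/movement event
  streams, multi-node radar-like I/Q waveforms, and a cleaner "reference
  modality" (jittered event times + per-epoch activity counts). The gap in
  corruption between the two renderings is a controllable domain shift.
- **`radarsleep.dsp`** — the radar front end: the six-step epochized
  movement feature (10 s moving average → standardize → |derivative| →
  min–max → 0.2 threshold → epoch mean, max-fused across nodes), a
  deterministic per-sample beat-likelihood detector with max-fusion across
  nodes and peak picking into NN intervals, and respiration extraction
  (zero-phase 2nd-order Butterworth low-pass at 0.5 Hz → Hilbert envelope
  → peak detection into BB intervals).
- **`radarsleep.features`** — 13 features per 30 s epoch in fixed sliding
  windows: movement/ACT; MedianNN (0.5 & 2.5 min), SD2/SD1 (Poincaré,
  0.5 min), VLF/LF/HF/LF-HF/total power of the 4 Hz-resampled NN tachogram
  (2.5 min; bands 0.003–0.04, 0.04–0.15, 0.15–0.4 Hz); MedianBB, BB-LF
  power, CVBB (2.5 min) and MCVBB (4.5 min).
- **`radarsleep.staging`** — `LSTMSleepStager`, a scikit-learn-style
  whole-night sequence classifier (2×64 LSTM + softmax, class-weighted
  cross-entropy, Adam, early stopping) written in numpy, with
  `fit` / `fine_tune` / `predict` and single-file checkpoints that carry
  their normalization statistics.
- **`radarsleep.evaluation`** — per-participant accuracy/F1/MCC/precision/
  recall/specificity from confusion matrices (Gorodkin multiclass MCC,
  support-weighted one-vs-rest averaging), cohort median (IQR) summaries,
  row-normalized confusion matrices, and participant-wise cross-modal
  feature correlations.
- **`radarsleep.experiment`** — the scratch-vs-transfer comparison:
  pretrain on a large reference cohort, fine-tune on a small radar cohort,
  evaluate both models on identical held-out radar nights in the
  five-class and merged three-class (W/NREM/R) schemes.
- **`radarsleep` CLI** — `simulate`, `extract-features`, `train`,
  `finetune`, `evaluate`, `correlate`, `experiment`.

## Worked example

```python
import radarsleep as rs
from radarsleep.experiment import radar_night_table

sim = rs.SimConfig(night_len_epochs=120)          # a 1 h night for speed
night = rs.simulate_night(sim, seed=9, participant_id="P1")
table = radar_night_table(night, sim)             # radar front end + features
print(len(table), "epochs;", int(table["valid"].sum()), "valid")
print(table.loc[11, ["ACT", "MedianNN_long", "MedianBB", "CVBB", "stage"]])
```

prints

```
120 epochs; 120 valid
ACT               0.00181
MedianNN_long      1062.5
MedianBB         4.195312
CVBB             0.038964
stage                  N3
```

— a quiet deep-sleep epoch: essentially no movement, a slow heart (median
NN ≈ 1063 ms over the 2.5 min window), and long, very regular breaths
(median BB ≈ 4.2 s at a coefficient of variation ≈ 0.04). Exact values
depend on the seed.

To run one replicate of the transfer experiment (about two minutes on one
CPU):

```python
from radarsleep.experiment import ExperimentConfig, run_transfer_experiment
report = run_transfer_experiment(ExperimentConfig(), seed=0)
print(report.to_markdown())
```

The report tabulates median (IQR) metrics for the scratch-trained and
fine-tuned radar models in both label schemes and their pooled confusion
matrices; with the default configuration the fine-tuned model's five-class
Matthews correlation coefficient clearly exceeds the scratch model's
(replicating the experiment over a few seeds, as
`tests/test_acceptance.py` does, gives scratch medians around 0.3 against
transfer medians around 0.9), with per-stage recall gains including Wake,
N3 and REM.

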