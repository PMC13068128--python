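# Methods

This note documents the models behind `radarsleep`: what the simulator
emulates, how the radar front end and features are defined, how the stager
is trained and transferred, and the numerical choices made where the
design was genuinely open.

## Sleep-architecture simulator

Hypnograms are sampled from a five-state Markov chain over
(W, N1, N2, N3, R) on the 30 s AASM epoch grid, starting in Wake
(lights-off). The transition matrix is the "sticky" family
`P = (1-s) I + s 1 piᵀ` with stickiness `s = 0.06` and target stationary
distribution `pi = (0.09237, 0.07429, 0.46667, 0.16667, 0.20)`. This family
has stationary law exactly `pi` for any `s`, and mean stage dwell time
`1/(s(1-pi_i))` ≈ 8–9 min, a plausible bout length. Starting in Wake
inflates the pooled Wake share of a finite night by
`(1-pi_W)(1-(1-s)^T)/(sT)`; `pi_W` was solved in closed form so that a
960-epoch (8 h) night has a mean total sleep time of 428 min, and `pi_N1`
so that the pooled N1 share of all epochs is 7.3 % — the two cohort
marginals the simulator is calibrated to. Nothing else about the dynamics
is cohort-matched: real hypnograms have ultradian NREM/REM cycling that a
first-order chain does not reproduce, so tests that pass here say nothing
about cycle structure.

Stage-conditioned physiology (defaults, per stage W/N1/N2/N3/R):

| parameter | W | N1 | N2 | N3 | R | unit |
|---|---|---|---|---|---|---|
| mean NN | 850 | 950 | 1000 | 1050 | 900 | ms |
| LF modulation (0.1 Hz) | 40 | 30 | 20 | 10 | 55 | ms |
| HF modulation (0.25 Hz) | 15 | 25 | 30 | 30 | 15 | ms |
| mean BB | 3.6 | 3.8 | 4.0 | 4.2 | 3.7 | s |
| BB coefficient of variation | 0.20 | 0.13 | 0.09 | 0.05 | 0.18 | – |
| movement bursts / epoch | 0.80 | 0.15 | 0.08 | 0.02 | 0.03 | – |

These encode the standard autonomic orderings: heart rate and HRV fall
with NREM depth; breathing is irregular in Wake and REM and most regular
in N3; movement is frequent in Wake and nearly absent in REM (atonia)
while REM keeps strong low-frequency NN fluctuation. Values are round
numbers in the physiological range for healthy adults; they are regime
choices, not fits. Beats advance by the instantaneous NN interval
(stage mean + LF/HF sinusoids with random night phases + 8 ms white
jitter, floored at 300 ms); BB intervals are gamma distributed with the
stage mean and CV (gamma keeps them positive with the exact configured
CV); movement bursts are per-epoch Poisson with uniform start, 0.5–4 s
duration and 0.3–1 intensity.

### Waveform rendering

Each radar node's in-phase channel is
`g_resp · respiration + g_card · cardiac + movement`, clipped to ±4
(channel saturation) and then corrupted with additive white noise
(default SD 0.05). Per-node gains are drawn uniformly from (0.4, 1.2), so
different nodes see different components best — the rationale for
max-fusion downstream. Components:

- *Respiration*: one raised-cosine chest bump per breath, width 0.7× the
  local BB interval, amplitude 1. A unipolar bump train (rather than a
  pure sinusoid) is what makes the respiration pipeline's envelope step
  meaningful: the Hilbert envelope of a pure sinusoid is flat, whereas
  the envelope of a bump train peaks once per breath.
- *Cardiac micromotion*: a Gabor pulse (Gaussian-windowed 8 Hz
  oscillation, σ = 40 ms, amplitude 0.1) at each beat time. The sampling
  rate must be ≥ 8× the pulse frequency; the test default is 64 Hz, and
  the hardware-scale 1953.125 Hz is accepted but slow.
- *Movement*: large (amplitude 12×intensity) slow oscillations
  (0.2–1 Hz: turning over takes seconds) during bursts, each followed by
  a persistent baseline shift — the body settles in a new position
  relative to the radar. Movement dwarfs the breathing excursion, as it
  does physically, and because it exceeds the clip level it saturates
  the channel and destroys cardiac information — beat detection
  therefore degrades during movement, as it does in practice. With
  probability 0.04 per epoch a spurious artifact burst (absent from the
  ground truth) is injected.

The quadrature channel repeats the construction with quarter-period
shifts. The reference modality passes the true event times through with
5 ms beat jitter, 50 ms breath jitter and a 0.5 % drop rate, and emits
Poisson activity counts proportional to the per-epoch movement load. The
asymmetry between the two renderings — waveform-level corruption,
saturation and detection error on the radar side versus small timing
jitter on the reference side — is the simulated domain shift.

## Radar front end

- **Movement**: per node, a 10 s centered moving average (shrinking
  window at the boundaries), standardization over the recording, the
  absolute first difference × fs as movement intensity (sign carries no
  intensity information), min–max normalization to [0, 1] over the
  recording, zeroing below the 0.2 threshold, and the mean per 30 s
  epoch; nodes are fused by taking the maximum of the per-epoch feature.
  Fusing before epoch aggregation is available via `fusion="pre_epoch"`;
  the two readings differ only during partial-epoch movement.
- **Beat likelihood**: the unavailable pretrained detector is replaced by
  a deterministic surrogate with the same contract (a per-sample
  probability): band-pass 4–12 Hz on both channels (matching the rendered
  pulse bandwidth), summed analytic envelopes, 0.1 s smoothing, and the
  squash `s²/(s²+1)` with `s` the envelope over 5× its median (a robust
  background level). Samples inside saturation regions (|x| above ≈ 93 %
  of the clip level, dilated by 0.5 s) are multiplied by 0.05. Node
  probabilities are fused by the element-wise maximum; beats are peaks
  above 0.15 separated by a 0.35 s refractory period, so NN intervals are
  bounded below by the refractory period by construction.  The peak
  threshold is the surrogate's operating point, calibrated on simulated
  nights so the detected median NN matches the ground truth at the default
  radar noise (higher thresholds halve the detection rate and double the
  apparent NN; the published detector's threshold is not recorded).
- **Respiration**: zero-phase 2nd-order Butterworth low-pass at 0.5 Hz,
  subtraction of a 60 s moving-average baseline (so posture-change DC
  offsets do not dominate the envelope), Hilbert envelope, peak
  detection with 1.5 s minimum separation and a prominence floor of 10 %
  of the envelope's 5–95 percentile spread. Zero-phase filtering
  everywhere avoids group-delay misalignment with the epoch grid.

On noise-free rendered nights the front end recovers NN intervals with a
mean absolute error under 20 ms (sample quantization at 64 Hz contributes
~8 ms) and breath counts within 5 %; error grows monotonically with the
configured waveform noise.

## Features

Thirteen features per epoch, each on its own sliding window centered on
the epoch midpoint (trailing windows are available; centering avoids a
systematic label lag). Windows are truncated at recording boundaries and
such epochs flagged. An interval belongs to the window in which its
ending event falls. The NN/BB tachograms are resampled to a uniform 4 Hz
grid by cubic interpolation and band powers come from a single-taper
(boxcar) periodogram integrated rectangularly over half-open bands; total
power integrates 0.003–0.4 Hz and therefore equals VLF+LF+HF exactly.
A 2.5 min window cannot resolve the 0.003 Hz VLF lower edge; the band is
integrated as defined and the leakage accepted. All dispersion statistics
use population (not sample) normalization — an O(1/n) choice that is
applied identically in both modalities. Epochs whose core features
(MedianNN, MedianBB, total power) cannot be computed are flagged invalid
and their feature values imputed by per-night forward fill at model input
only; correlation analyses exclude them pairwise. MCVBB follows the
mean-absolute-deviation/median definition and requires ≥ 4 intervals (the
minimum for which the statistic is well-behaved); other interval features
require 3 (medians, CV) or 5 (spectral).

## Staging model and transfer

`LSTMSleepStager` is a stacked unidirectional LSTM (2 layers × 64 hidden
units, inter-layer dropout 0.25) with a linear softmax head, trained
many-to-many on whole-night sequences with class-weighted (inverse
frequency) cross-entropy — the minimal remedy for the heavy stage
imbalance (N1 ≈ 7 %).  Power-like features (the band powers, LF/HF ratio
and activity counts) enter the model as `log1p`: beat-detection glitches
during movement inflate spectral power by several orders of magnitude,
and without the compression the z-normalization is dominated by those
outliers.  The transform is applied identically in both modalities at the
table-to-sequence boundary. Optimization is Adam (lr 0.01, global-norm clip 5)
on seeded minibatches of 16 nights; early stopping monitors loss on the
last 20 % of training nights (patience 12 by default) and restores the
best parameters. Inverse-frequency weights are capped at 5× the average
so a very rare stage in a tiny cohort cannot dominate the loss.
Feature normalization is robust — per-feature median and IQR/1.349
rather than mean/SD — because a single night with degraded beat
detection otherwise sets the scale for the interval features and crushes
the ~50 ms contrast between adjacent NREM stages. Everything is numpy, so a fixed seed reproduces training
bit-for-bit. The network, its config, and the per-feature normalization
mean/SD travel together in a single checkpoint file.

Fine-tuning continues optimization of *all* weights with a fresh Adam at
0.1× the learning rate, and by default recomputes normalization
statistics on the target training nights — radar features live on
different scales than reference features (activity counts vs a [0, 1]
movement feature, noisier spectra), and per-domain standardization is the
first-order domain adaptation. Using source statistics is available as an
ablation. A zero-epoch fine-tune is the exact identity.

Bidirectional layers are implemented and config-selectable; the default
stays unidirectional as the cheaper architecture adequate at this feature
resolution.

## The transfer experiment

`run_transfer_experiment` pretrains on 100 reference-modality nights,
then trains two radar models on the same 12 radar training nights — one
from random initialization, one fine-tuned from the pretrained weights —
and evaluates both on the same 6 held-out radar nights, in the five-class
scheme and in the merged three-class scheme (obtained by mapping
five-class predictions and labels through N1/N2/N3 → NREM). The scratch
and fine-tuned arms share data, feature schema, training protocol
(including the early-stopping rule and the epoch budget) and metric code;
only the initialization differs. Both arms are repeated for three
training seeds and metrics pooled across seeds and participants.

Problem sizes are a scaled-down rendition of the study design: 120-epoch
(1 h) training nights keep the radar cohort data-scarce relative to the
pretraining corpus — the regime in which the scratch/transfer comparison
is scientifically interesting, approximating the full-size study's
source:target epoch ratio — while the held-out test nights are full 480
epochs so the pooled per-stage recalls are estimated from enough epochs.
One replicate runs in under two minutes on one CPU. The epoch budget
(150) is large enough that both arms reach their early-stopping optimum:
the scratch arm typically stops after a few dozen steps, while
fine-tuning at 0.1× learning rate needs the longer horizon. Replicating
the experiment with fresh seeds (cohorts and training) and pooling the
test confusion matrices across replicates is the stable way to compare
per-stage recalls: a single scratch run occasionally collapses into a
degenerate solution that over-predicts REM, whose inflated REM recall is
an artifact rather than skill.

Under the default domain shift the fine-tuned model's median five-class
test MCC exceeds the scratch model's, with the clearest pooled-recall
gains in Wake, N3 and REM; and participant-wise cross-modal correlations
are high for timing features (MedianNN, MedianBB) but low for spectral
HRV features, because beat-detection jitter of the order of 10 ms barely
moves a median but overwhelms modulation amplitudes of 10–30 ms in the
band powers. These statements are asserted, at these problem sizes, by
`tests/test_acceptance.py`; the simulator is stylized, so they demonstrate
the pipeline's behaviour under the modelled shift, not performance on any
real cohort.

## Numerical choices and limitations

- Tachogram resampling at 4 Hz with cubic splines; windows shorter than
  ~8 resampled samples or with fewer than 4 events are invalid rather
  than extrapolated.
- The movement chain treats a zero-variance node as contributing zeros
  (with a warning) instead of failing the night.
- Quantile aggregation uses linear-interpolation (type-7) quantiles; IQR
  is Q3 − Q1.
- Support-weighted one-vs-rest averaging makes recall identical to
  accuracy by construction; macro averaging is available. Per-class
  precision with zero predicted support counts as 0 with a warning.
  Multiclass MCC is the Gorodkin form, which reduces exactly to the
  binary formula on 2×2 tables.
- The simulator renders stylized, stationary stage physiology: no
  ultradian cycling, no apnea or periodic breathing, no postural drift,
  no inter-participant anatomy differences beyond node gains. Passing
  tests bound the pipeline's correctness on this model of the data, not
  its clinical performance.
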