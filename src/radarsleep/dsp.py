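"""Radar waveform processing: movement feature, heartbeat detection, respiration.

Three primitive streams are derived from the multi-node I/Q waveforms:

* an epochized large-body-movement feature in [0, 1],
* a normal-to-normal (NN) heartbeat interval series, obtained from a fused
  per-sample beat-likelihood signal, and
* a breath-to-breath (BB) interval series from the low-frequency respiration
  component.

All filtering is zero-phase (forward-backward) so features stay aligned
with the 30 s epoch grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .hypnogram import EPOCH_LEN_S
from .simulate import RadarNight

__all__ = [
    "MovementEpochSeries",
    "ProbabilitySeries",
    "BeatSeries",
    "BreathSeries",
    "movement_feature",
    "beat_probability",
    "fuse_probabilities",
    "detect_beats",
    "extract_respiration",
    "process_radar_night",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class MovementEpochSeries:
    """Per-epoch movement value in [0, 1] plus per-node diagnostics."""

    values: np.ndarray              # (n_epochs,)
    per_node: np.ndarray            # (n_nodes, n_epochs)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("movement values must lie in [0, 1]")


@dataclass
class ProbabilitySeries:
    """Per-sample beat likelihood in [0, 1]."""

    values: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class BeatSeries:
    """Strictly increasing beat times and the derived NN intervals (ms)."""

    beat_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if np.any(np.diff(self.beat_times_s) <= 0):
            raise ValueError("beat times must be strictly increasing")

    @property
    def nn_intervals_ms(self) -> np.ndarray:
        return np.diff(self.beat_times_s) * 1000.0

    def __len__(self) -> int:
        return len(self.beat_times_s)


@dataclass
class BreathSeries:
    """Strictly increasing breath times and the derived BB intervals (s)."""

    breath_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.breath_times_s = np.asarray(self.breath_times_s, dtype=float)
        if np.any(np.diff(self.breath_times_s) <= 0):
            raise ValueError("breath times must be strictly increasing")

    @property
    def bb_intervals_s(self) -> np.ndarray:
        return np.diff(self.breath_times_s)

    def __len__(self) -> int:
        return len(self.breath_times_s)


# ---------------------------------------------------------------------------
# movement feature


def _centered_moving_average(x: np.ndarray, win: int) -> np.ndarray:
    """Centered moving average with a shrinking window at the boundaries."""
    kernel = np.ones(win)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def _node_movement_series(x: np.ndarray, fs: float, threshold: float) -> np.ndarray:
    """Single-node processing chain: 10 s moving average -> z-standardize ->
    |first difference| x fs -> min-max to [0, 1] -> zero below threshold ->
    per-epoch mean."""
    n_epochs = int(len(x) // round(EPOCH_LEN_S * fs))
    sd = np.std(x)
    if sd < 1e-12:
        warnings.warn("constant node waveform contributes zero movement", stacklevel=3)
        return np.zeros(n_epochs)
    smoothed = _centered_moving_average(x, max(1, int(round(10.0 * fs))))
    z = (smoothed - np.mean(smoothed)) / max(np.std(smoothed), 1e-12)
    deriv = np.abs(np.diff(z, prepend=z[0])) * fs
    lo, hi = deriv.min(), deriv.max()
    norm = (deriv - lo) / (hi - lo) if hi > lo else np.zeros_like(deriv)
    norm[norm < threshold] = 0.0
    spe = int(round(EPOCH_LEN_S * fs))
    return norm[: n_epochs * spe].reshape(n_epochs, spe).mean(axis=1)


def movement_feature(night: RadarNight, threshold: float = 0.2,
                     fusion: str = "post_epoch") -> MovementEpochSeries:
    """Epochized large-body-movement feature from the in-phase channels.

    Per node: a 10 s centered moving average, standardization to zero mean
    and unit variance over the recording, the magnitude of the first-order
    derivative as movement intensity, min-max normalization to [0, 1] over
    the recording, zeroing of values below ``threshold`` (default 0.2), and
    the mean within each 30 s epoch.  Nodes are then combined by taking the
    maximum across radars; ``fusion`` selects whether the max is taken on
    the per-epoch feature (default) or sample-wise before epoch averaging.
    """
    if night.n_nodes == 0:
        raise ValueError("night has no radar nodes")
    if night.duration_s < EPOCH_LEN_S:
        raise ValueError("night shorter than one epoch")
    if fusion not in ("post_epoch", "pre_epoch"):
        raise ValueError("fusion must be 'post_epoch' or 'pre_epoch'")
    fs = night.fs_hz
    per_node = np.stack([
        _node_movement_series(night.inphase[k], fs, threshold)
        for k in range(night.n_nodes)
    ])
    if fusion == "post_epoch":
        fused = per_node.max(axis=0)
    else:
        spe = int(round(EPOCH_LEN_S * fs))
        n_epochs = per_node.shape[1]
        samplewise = []
        for k in range(night.n_nodes):
            x = night.inphase[k]
            sd = np.std(x)
            if sd < 1e-12:
                samplewise.append(np.zeros(n_epochs * spe))
                continue
            smoothed = _centered_moving_average(x, max(1, int(round(10.0 * fs))))
            z = (smoothed - np.mean(smoothed)) / max(np.std(smoothed), 1e-12)
            deriv = np.abs(np.diff(z, prepend=z[0])) * fs
            lo, hi = deriv.min(), deriv.max()
            norm = (deriv - lo) / (hi - lo) if hi > lo else np.zeros_like(deriv)
            norm[norm < threshold] = 0.0
            samplewise.append(norm[: n_epochs * spe])
        fused_samples = np.max(np.stack(samplewise), axis=0)
        fused = fused_samples.reshape(n_epochs, spe).mean(axis=1)
    return MovementEpochSeries(values=fused, per_node=per_node)


# ---------------------------------------------------------------------------
# beat likelihood (deterministic surrogate for a pretrained detector)


def _saturation_mask(x: np.ndarray, fs: float, level: float, dilate_s: float = 0.5) -> np.ndarray:
    """Boolean mask of samples inside (dilated) channel-saturation regions."""
    hit = np.abs(x) >= level
    if not hit.any():
        return hit
    win = max(1, int(round(dilate_s * fs)))
    return np.convolve(hit.astype(float), np.ones(2 * win + 1), mode="same") > 0


def beat_probability(inphase: np.ndarray, quadrature: np.ndarray, fs: float,
                     band_hz: tuple[float, float] = (4.0, 12.0),
                     smooth_s: float = 0.10,
                     saturation_level: float = 3.7) -> ProbabilitySeries:
    """Per-sample heartbeat likelihood from one node's I/Q channels.

    A deterministic signal-processing detector: both channels are band-pass
    filtered in the cardiac-micromotion band, their analytic envelopes are
    summed and smoothed, and the result is squashed to [0, 1] by
    ``s^2 / (s^2 + 1)`` with ``s`` the envelope scaled by a robust (median)
    background level.  Samples inside detected saturation regions — where
    gross movement clips the channel and destroys cardiac information — are
    pulled toward zero.
    """
    inphase = np.asarray(inphase, dtype=float)
    quadrature = np.asarray(quadrature, dtype=float)
    if inphase.shape != quadrature.shape:
        raise ValueError("inphase and quadrature must have equal length")
    n = len(inphase)
    if n == 0:
        return ProbabilitySeries(np.empty(0), fs)
    if not np.any(inphase) and not np.any(quadrature):
        return ProbabilitySeries(np.zeros(n), fs)
    nyq = fs / 2.0
    lo, hi = band_hz
    sos = sps.butter(2, [lo / nyq, min(hi / nyq, 0.99)], btype="bandpass", output="sos")
    env = np.zeros(n)
    for ch in (inphase, quadrature):
        bp = sps.sosfiltfilt(sos, ch)
        env += np.abs(sps.hilbert(bp))
    win = max(1, int(round(smooth_s * fs)))
    env = np.convolve(env, np.ones(win) / win, mode="same")
    background = 5.0 * np.median(env) + 1e-12
    s = env / background
    prob = s * s / (s * s + 1.0)
    mask = (_saturation_mask(inphase, fs, saturation_level)
            | _saturation_mask(quadrature, fs, saturation_level))
    prob[mask] *= 0.05
    return ProbabilitySeries(prob, fs)


def fuse_probabilities(series: list[ProbabilitySeries]) -> ProbabilitySeries:
    """Element-wise maximum across node probability series: a beat detected
    at any node at a given sample is retained in the fused signal."""
    if not series:
        raise ValueError("need at least one probability series")
    fs = series[0].fs_hz
    n = len(series[0].values)
    for p in series[1:]:
        if p.fs_hz != fs or len(p.values) != n:
            raise ValueError("probability series must share length and sampling rate")
    return ProbabilitySeries(np.max(np.stack([p.values for p in series]), axis=0), fs)


def detect_beats(prob: ProbabilitySeries, min_height: float = 0.15,
                 refractory_s: float = 0.35) -> BeatSeries:
    """Peak-pick the fused likelihood into a beat series.

    Peaks must exceed ``min_height`` and be separated by the refractory
    period, so derived NN intervals are bounded below by ``refractory_s``.
    """
    if refractory_s <= 0:
        raise ValueError("refractory_s must be positive")
    idx, _ = sps.find_peaks(prob.values, height=min_height,
                            distance=max(1, math.ceil(refractory_s * prob.fs_hz)))
    if len(idx) < 2:
        raise ValueError("insufficient beats: fewer than 2 likelihood peaks")
    return BeatSeries(idx / prob.fs_hz)


# ---------------------------------------------------------------------------
# respiration


def extract_respiration(inphase: np.ndarray, fs: float,
                        cutoff_hz: float = 0.5,
                        min_breath_separation_s: float = 1.5,
                        detrend_s: float = 60.0) -> BreathSeries:
    """Breath times from one node's in-phase channel.

    A second-order zero-phase Butterworth low-pass at 0.5 Hz removes
    cardiac and noise components; a slow moving-average baseline
    (``detrend_s``) is subtracted so posture-change DC offsets do not
    dominate the envelope; the Hilbert-transform envelope of the result
    accentuates the per-breath chest excursions; breaths are the envelope
    peaks separated by at least ``min_breath_separation_s``.
    """
    if fs <= 1.0:
        raise ValueError("fs must exceed 1 Hz")
    x = np.asarray(inphase, dtype=float)
    sos = sps.butter(2, cutoff_hz / (fs / 2.0), btype="lowpass", output="sos")
    low = sps.sosfiltfilt(sos, x)
    if detrend_s > 0 and len(low) > 2:
        low = low - _centered_moving_average(low, max(1, int(round(detrend_s * fs))))
    env = np.abs(sps.hilbert(low))
    spread = np.percentile(env, 95) - np.percentile(env, 5)
    idx, _ = sps.find_peaks(env, distance=max(1, int(round(min_breath_separation_s * fs))),
                            prominence=0.1 * spread if spread > 0 else None)
    if len(idx) < 2:
        raise ValueError("insufficient breaths: fewer than 2 envelope peaks")
    return BreathSeries(idx / fs)


# ---------------------------------------------------------------------------
# whole-night convenience


def process_radar_night(night: RadarNight, movement_threshold: float = 0.2,
                        beat_min_height: float = 0.15, refractory_s: float = 0.35,
                        resp_node: int | str = "best", saturation_level: float = 3.7,
                        ) -> tuple[MovementEpochSeries, BeatSeries, BreathSeries]:
    """Run the full radar front end on one night.

    Beat likelihoods are computed per node and max-fused before peak
    detection.  Respiration uses the node whose low-passed in-phase channel
    carries the most 0.1-0.5 Hz power (``resp_node="best"``) or an explicit
    node index.  ``saturation_level`` is the amplitude beyond which a
    channel is treated as clipped by gross movement; it sits just below the
    channel's dynamic-range limit.
    """
    movement = movement_feature(night, threshold=movement_threshold)
    probs = [
        beat_probability(night.inphase[k], night.quadrature[k], night.fs_hz,
                         saturation_level=saturation_level)
        for k in range(night.n_nodes)
    ]
    beats = detect_beats(fuse_probabilities(probs), min_height=beat_min_height,
                         refractory_s=refractory_s)
    if resp_node == "best":
        k_best, best_power = 0, -1.0
        sos = sps.butter(2, [0.1 / (night.fs_hz / 2), 0.5 / (night.fs_hz / 2)],
                         btype="bandpass", output="sos")
        step = max(1, int(night.n_samples // (200_000)))
        for k in range(night.n_nodes):
            bp = sps.sosfiltfilt(sos, night.inphase[k][::step])
            p = float(np.mean(bp * bp))
            if p > best_power:
                k_best, best_power = k, p
        resp_idx = k_best
    else:
        resp_idx = int(resp_node)
    breaths = extract_respiration(night.inphase[resp_idx], night.fs_hz)
    return movement, beats, breaths
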