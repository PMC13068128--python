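"""Configuration dataclasses for the simulator, feature windows and staging model.

Every constant the pipeline depends on (movement threshold, filter cutoffs,
feature windows, stage physiology) lives here so that experiments are fully
described by a config object plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .hypnogram import AASM5, EPOCH_LEN_S

# ---------------------------------------------------------------------------
# stage physiology


@dataclass
class StageParams:
    """Stage-conditioned physiology regime.

    mean_nn_ms
        Mean normal-to-normal heartbeat interval. Heart rate slows with sleep
        depth, so N3 has the longest and Wake the shortest NN interval.
    lf_amp_ms / hf_amp_ms
        Amplitudes of sinusoidal NN modulation at the low-frequency (0.1 Hz,
        baroreflex) and high-frequency (0.25 Hz, respiratory sinus arrhythmia)
        rhythms. REM carries strong LF fluctuation despite muscle atonia.
    mean_bb_s / bb_cv
        Mean breath-to-breath interval and its coefficient of variation.
        Breathing is irregular in Wake and REM and very regular in N3.
    movement_rate
        Expected number of gross-movement bursts per 30 s epoch.
    """

    mean_nn_ms: float
    lf_amp_ms: float
    hf_amp_ms: float
    mean_bb_s: float
    bb_cv: float
    movement_rate: float


def default_stage_physiology() -> dict[str, StageParams]:
    return {
        "W": StageParams(850.0, 40.0, 15.0, 3.6, 0.20, 0.80),
        "N1": StageParams(950.0, 30.0, 25.0, 3.8, 0.13, 0.15),
        "N2": StageParams(1000.0, 20.0, 30.0, 4.0, 0.09, 0.08),
        "N3": StageParams(1050.0, 10.0, 30.0, 4.2, 0.05, 0.02),
        "R": StageParams(900.0, 55.0, 15.0, 3.7, 0.18, 0.03),
    }


# ---------------------------------------------------------------------------
# sleep architecture

# Target stationary stage distribution (W, N1, N2, N3, R).  With the sticky
# chain P = (1-s) I + s 1 pi^T the stationary law is exactly pi.  Starting the
# night in Wake inflates the pooled Wake fraction by (1-pi_W)(1-(1-s)^T)/(sT);
# pi_W is chosen so a 960-epoch night averages 428.1 min of sleep and pi_N1 so
# the pooled N1 share of all epochs is 7.3 %.
STATIONARY_STAGE_DIST = np.array([0.09237, 0.07429, 0.46667, 0.16667, 0.20000])
STAGE_STICKINESS = 0.06


def default_stage_transition() -> np.ndarray:
    s = STAGE_STICKINESS
    return (1.0 - s) * np.eye(5) + s * np.tile(STATIONARY_STAGE_DIST, (5, 1))


# ---------------------------------------------------------------------------
# modality noise


@dataclass
class ModalityNoise:
    """Corruption model for one sensing modality.

    The reference (wearable/electrophysiology-style) modality applies small
    timing jitter and a low event-drop rate directly to the true event
    streams.  The radar modality is corrupted at the waveform level: additive
    sensor noise, per-node gain spread, channel saturation during movement
    and occasional spurious movement artifacts.
    """

    waveform_noise_sd: float = 0.0
    beat_jitter_sd_ms: float = 0.0
    breath_jitter_sd_s: float = 0.0
    event_drop_rate: float = 0.0
    node_gain_range: tuple[float, float] = (1.0, 1.0)
    artifact_prob: float = 0.0

    def validate(self) -> None:
        for name in ("waveform_noise_sd", "beat_jitter_sd_ms", "breath_jitter_sd_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.event_drop_rate < 1.0:
            raise ValueError("event_drop_rate must be in [0, 1)")
        if not 0.0 <= self.artifact_prob <= 1.0:
            raise ValueError("artifact_prob must be in [0, 1]")
        lo, hi = self.node_gain_range
        if lo < 0 or hi < lo:
            raise ValueError("node_gain_range must satisfy 0 <= lo <= hi")


def default_reference_noise() -> ModalityNoise:
    return ModalityNoise(
        beat_jitter_sd_ms=5.0,
        breath_jitter_sd_s=0.05,
        event_drop_rate=0.005,
    )


def default_radar_noise() -> ModalityNoise:
    return ModalityNoise(
        waveform_noise_sd=0.05,
        node_gain_range=(0.4, 1.2),
        artifact_prob=0.04,
    )


# ---------------------------------------------------------------------------
# simulator config


@dataclass
class SimConfig:
    """Full description of a simulated night (modulo the seed)."""

    epoch_len_s: float = EPOCH_LEN_S
    night_len_epochs: int = 960
    fs_hz: float = 64.0
    n_nodes: int = 4
    stage_transition: np.ndarray = field(default_factory=default_stage_transition)
    stage_physiology: dict[str, StageParams] = field(default_factory=default_stage_physiology)
    radar_noise: ModalityNoise = field(default_factory=default_radar_noise)
    reference_noise: ModalityNoise = field(default_factory=default_reference_noise)
    seed: int = 0

    # waveform rendering; gross movement (clipped at clip_level) must dwarf
    # the chest-breathing excursion, as it does for real radar returns
    resp_amp: float = 1.0
    resp_bump_frac: float = 0.7      # breath bump width as a fraction of the local BB
    cardiac_amp: float = 0.10
    cardiac_freq_hz: float = 8.0     # centre frequency of the cardiac micromotion pulse
    cardiac_sigma_s: float = 0.04    # Gaussian envelope width of the pulse
    movement_amp: float = 12.0       # pre-clipping amplitude of gross-movement bursts
    clip_level: float = 4.0          # radar channel saturation level
    nn_jitter_sd_ms: float = 8.0     # white beat-to-beat jitter on top of the modulation

    def __post_init__(self) -> None:
        self.stage_transition = np.asarray(self.stage_transition, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.epoch_len_s != EPOCH_LEN_S:
            raise ValueError("epoch_len_s is fixed at 30 s")
        if self.night_len_epochs < 1:
            raise ValueError("night_len_epochs must be >= 1")
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        P = self.stage_transition
        if P.shape != (5, 5):
            raise ValueError("stage_transition must be 5x5 over (W, N1, N2, N3, R)")
        if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("stage_transition rows must be non-negative and sum to 1")
        if set(self.stage_physiology) != set(AASM5):
            raise ValueError(f"stage_physiology must cover exactly {AASM5}")
        for stage, p in self.stage_physiology.items():
            if p.mean_nn_ms <= 0 or p.mean_bb_s <= 0:
                raise ValueError(f"{stage}: mean intervals must be positive")
            if min(p.lf_amp_ms, p.hf_amp_ms, p.bb_cv, p.movement_rate) < 0:
                raise ValueError(f"{stage}: amplitudes/rates must be >= 0")
        # the cardiac pulse is the highest-frequency rendered component
        if self.fs_hz < 8.0 * self.cardiac_freq_hz:
            raise ValueError(
                f"fs_hz={self.fs_hz} too low: need >= 8x cardiac pulse frequency "
                f"({8.0 * self.cardiac_freq_hz} Hz)"
            )
        self.radar_noise.validate()
        self.reference_noise.validate()

    @property
    def night_duration_s(self) -> float:
        return self.night_len_epochs * self.epoch_len_s


# ---------------------------------------------------------------------------
# feature windows (sliding-window lengths in minutes per feature)


@dataclass
class FeatureWindowSpec:
    """Per-feature sliding-window lengths (minutes) and anchoring mode.

    Defaults follow the feature table: activity 0.5; MedianNN at 0.5 and
    2.5; SD2/SD1 0.5; the HRV band powers 2.5; the breathing features 2.5
    except MCVBB at 4.5.  Windows are centered on the epoch midpoint by
    default; ``anchor="trailing"`` ends the window at the epoch end instead.
    """

    act: float = 0.5
    median_nn_short: float = 0.5
    median_nn_long: float = 2.5
    sd2sd1: float = 0.5
    hrv_power: float = 2.5
    median_bb: float = 2.5
    rrv_lf: float = 2.5
    cvbb: float = 2.5
    mcvbb: float = 4.5
    anchor: str = "centered"

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name == "anchor":
                continue
            w = getattr(self, f.name)
            if w < EPOCH_LEN_S / 60.0:
                raise ValueError(f"window {f.name} shorter than one epoch")
            if round(w * 2.0, 9) % 1 != 0:
                raise ValueError(f"window {f.name} must be a multiple of 0.5 min")
        if self.anchor not in ("centered", "trailing"):
            raise ValueError("anchor must be 'centered' or 'trailing'")

    def window_for(self, name: str, epoch_index: int, duration_s: float) -> tuple[float, float]:
        """(start_s, end_s) of feature ``name``'s window for one epoch, clipped
        to the recording."""
        w_s = getattr(self, name) * 60.0
        if self.anchor == "centered":
            mid = (epoch_index + 0.5) * EPOCH_LEN_S
            t0, t1 = mid - w_s / 2.0, mid + w_s / 2.0
        else:
            t1 = (epoch_index + 1) * EPOCH_LEN_S
            t0 = t1 - w_s
        return max(0.0, t0), min(duration_s, t1)


# ---------------------------------------------------------------------------
# staging model config


@dataclass
class StagingModelConfig:
    """Hyperparameters of the LSTM sequence classifier."""

    hidden_size: int = 64
    n_layers: int = 2
    bidirectional: bool = False
    dropout: float = 0.25
    learning_rate: float = 0.01
    fine_tune_lr_factor: float = 0.1
    max_epochs: int = 120
    patience: int = 12
    val_fraction: float = 0.2
    class_weight: str = "balanced"   # "balanced" or "none"
    grad_clip: float = 5.0
    scheme: str = "aasm5"
    batch_size: int | None = 16      # nights per optimization step; None = full batch
    seed: int = 0

    def validate(self) -> None:
        if self.hidden_size < 1 or self.n_layers < 1:
            raise ValueError("hidden_size and n_layers must be positive")
        if not 0.0 < self.fine_tune_lr_factor <= 1.0:
            raise ValueError("fine_tune_lr_factor must be in (0, 1]")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")
        if self.class_weight not in ("balanced", "none"):
            raise ValueError("class_weight must be 'balanced' or 'none'")


# ---------------------------------------------------------------------------
# nested run config (CLI)


def _to_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _to_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(v) for v in obj]
    return obj


def _dataclass_from_dict(cls: type, data: Mapping[str, Any]) -> Any:
    """Build a (possibly nested) config dataclass from a plain mapping,
    rejecting unknown fields so config typos fail loudly."""
    if not isinstance(data, Mapping):
        raise ValueError(f"expected a mapping for {cls.__name__}, got {type(data).__name__}")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown field(s) for {cls.__name__}: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if cls is SimConfig and key == "stage_physiology":
            kwargs[key] = {k: _dataclass_from_dict(StageParams, v) for k, v in value.items()}
        elif cls is SimConfig and key in ("radar_noise", "reference_noise"):
            kwargs[key] = _dataclass_from_dict(ModalityNoise, value)
        elif key == "node_gain_range":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def config_to_dict(obj: Any) -> dict:
    return _to_dict(obj)


def sim_config_from_dict(data: Mapping[str, Any]) -> SimConfig:
    return _dataclass_from_dict(SimConfig, data)


def window_spec_from_dict(data: Mapping[str, Any]) -> FeatureWindowSpec:
    return _dataclass_from_dict(FeatureWindowSpec, data)


def model_config_from_dict(data: Mapping[str, Any]) -> StagingModelConfig:
    cfg = _dataclass_from_dict(StagingModelConfig, data)
    cfg.validate()
    return cfg
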