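"""Synthetic sleep-cohort generator.

Produces seeded multi-night recordings with the statistical structure the
pipeline needs end to end: Markov-chain hypnograms whose pooled stage
marginals match a realistic adult cohort (N1 share ~ 7.3 % of epochs, mean
total sleep time ~ 428 min per 8 h night), stage-conditioned heartbeat /
breath / gross-movement event streams, multi-node in-phase & quadrature
radar-like waveforms, and a cleaner "reference modality" stream (jittered
event times plus per-epoch activity counts) standing in for a wearable/PSG
domain.  The gap in corruption between the two renderings is the simulated
domain shift.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModalityNoise, SimConfig
from .hypnogram import AASM5, EPOCH_LEN_S, SCHEME_AASM5, Hypnogram

__all__ = [
    "PhysioEvents",
    "RadarNight",
    "ReferenceNight",
    "SimulatedNight",
    "Cohort",
    "simulate_hypnogram",
    "simulate_physiology",
    "render_radar_night",
    "render_reference_night",
    "simulate_night",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class PhysioEvents:
    """Ground-truth physiological event streams for one night.

    ``movement_bursts`` has one row per burst: (start_s, duration_s,
    intensity in [0, 1]).  The per-epoch summaries are the simulator's own
    bookkeeping (true mean NN, true BB coefficient of variation, true
    movement load) used by recovery tests; entries are NaN where an epoch
    holds fewer than two intervals.
    """

    beat_times_s: np.ndarray
    breath_times_s: np.ndarray
    movement_bursts: np.ndarray  # shape (n, 3)
    duration_s: float
    true_mean_nn_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_bb_cv: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_movement_load: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        for name in ("beat_times_s", "breath_times_s"):
            t = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, t)
            if len(t) and (t[0] < 0 or t[-1] > self.duration_s):
                raise ValueError(f"{name} outside [0, night duration]")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        self.movement_bursts = np.asarray(self.movement_bursts, dtype=float).reshape(-1, 3)

    @property
    def nn_intervals_ms(self) -> np.ndarray:
        return np.diff(self.beat_times_s) * 1000.0

    @property
    def bb_intervals_s(self) -> np.ndarray:
        return np.diff(self.breath_times_s)


@dataclass
class RadarNight:
    """Multi-node in-phase/quadrature radar-like waveforms for one night."""

    inphase: np.ndarray    # (n_nodes, n_samples)
    quadrature: np.ndarray  # (n_nodes, n_samples)
    fs_hz: float
    node_ids: list[str]
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.inphase = np.atleast_2d(np.asarray(self.inphase, dtype=float))
        self.quadrature = np.atleast_2d(np.asarray(self.quadrature, dtype=float))
        if self.inphase.shape != self.quadrature.shape:
            raise ValueError("inphase and quadrature must have equal shapes")
        if self.inphase.shape[0] != len(self.node_ids):
            raise ValueError("node_ids must match the number of nodes")

    @property
    def n_nodes(self) -> int:
        return self.inphase.shape[0]

    @property
    def n_samples(self) -> int:
        return self.inphase.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class ReferenceNight:
    """Clean-modality streams: jittered event times + per-epoch activity counts."""

    beat_times_s: np.ndarray
    breath_times_s: np.ndarray
    activity_counts: np.ndarray
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.activity_counts = np.asarray(self.activity_counts, dtype=float)
        if np.any(self.activity_counts < 0):
            raise ValueError("activity_counts must be >= 0")


@dataclass
class SimulatedNight:
    """Everything the simulator knows about one participant-night."""

    participant_id: str
    seed: int
    hypnogram: Hypnogram
    events: PhysioEvents
    radar: RadarNight | None = None
    reference: ReferenceNight | None = None


# ---------------------------------------------------------------------------
# hypnogram


def simulate_hypnogram(config: SimConfig, seed: int) -> Hypnogram:
    """Sample a night's stage sequence from the configured Markov chain.

    The chain starts in Wake (lights-off) and runs for
    ``config.night_len_epochs`` epochs of 30 s.
    """
    P = np.asarray(config.stage_transition, dtype=float)
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("stage_transition rows must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    n = config.night_len_epochs
    cum = np.cumsum(P, axis=1)
    u = rng.random(n - 1)
    states = np.empty(n, dtype=np.int64)
    states[0] = 0  # Wake
    s = 0
    for i in range(1, n):
        s = int(np.searchsorted(cum[s], u[i - 1], side="right"))
        s = min(s, 4)
        states[i] = s
    stages = np.array(AASM5, dtype=object)[states]
    return Hypnogram(stages, SCHEME_AASM5)


# ---------------------------------------------------------------------------
# physiology


def _epoch_slice_stats(times: np.ndarray, n_epochs: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch (mean interval, interval CV) for an event-time series.

    An interval is attributed to the epoch in which it ends.  Epochs with
    fewer than two intervals get NaN.
    """
    mean = np.full(n_epochs, np.nan)
    cv = np.full(n_epochs, np.nan)
    if len(times) < 2:
        return mean, cv
    iv = np.diff(times)
    ends = times[1:]
    idx = np.minimum((ends // EPOCH_LEN_S).astype(int), n_epochs - 1)
    for e in range(n_epochs):
        vals = iv[idx == e]
        if len(vals) >= 2:
            m = float(np.mean(vals))
            mean[e] = m
            cv[e] = float(np.std(vals) / m)
        elif len(vals) == 1:
            mean[e] = float(vals[0])
    return mean, cv


def simulate_physiology(hypnogram: Hypnogram, config: SimConfig, seed: int) -> PhysioEvents:
    """Generate beat/breath/movement event streams conditioned on the hypnogram.

    Heartbeats: the instantaneous NN interval is the stage mean plus two
    sinusoidal modulations (LF at 0.1 Hz, HF at 0.25 Hz, stage-dependent
    amplitudes) plus white jitter.  Breaths: BB intervals are gamma
    distributed with stage mean and CV (gamma keeps them strictly positive
    with exactly the configured CV).  Movement bursts: per-epoch Poisson
    counts at the stage rate with uniform start, duration and intensity.
    """
    if hypnogram.scheme.name != "aasm5":
        raise ValueError("physiology is conditioned on five-class hypnograms")
    rng = np.random.default_rng(seed)
    dur = hypnogram.duration_s
    n_epochs = len(hypnogram)
    stages = hypnogram.stages
    phys = config.stage_physiology
    mean_nn = np.array([phys[s].mean_nn_ms for s in stages])
    lf_amp = np.array([phys[s].lf_amp_ms for s in stages])
    hf_amp = np.array([phys[s].hf_amp_ms for s in stages])
    mean_bb = np.array([phys[s].mean_bb_s for s in stages])
    bb_cv = np.array([phys[s].bb_cv for s in stages])
    move_rate = np.array([phys[s].movement_rate for s in stages])

    # --- heartbeats (sequential; intervals depend on current time) ---
    phi_lf, phi_hf = rng.uniform(0.0, 2.0 * math.pi, size=2)
    jitter_sd = config.nn_jitter_sd_ms
    est = int(dur / (np.min(mean_nn) / 1000.0)) + 64
    jit = rng.normal(0.0, jitter_sd, size=est)
    beats: list[float] = []
    t = float(rng.uniform(0.2, 1.0))
    k = 0
    two_pi = 2.0 * math.pi
    while t < dur and k < est:
        beats.append(t)
        e = min(int(t / EPOCH_LEN_S), n_epochs - 1)
        nn = (
            mean_nn[e]
            + lf_amp[e] * math.sin(two_pi * 0.1 * t + phi_lf)
            + hf_amp[e] * math.sin(two_pi * 0.25 * t + phi_hf)
            + jit[k]
        )
        t += max(nn, 300.0) / 1000.0
        k += 1
    beat_times = np.asarray(beats)

    # --- breaths ---
    breaths: list[float] = []
    t = float(rng.uniform(0.5, 2.0))
    while t < dur:
        breaths.append(t)
        e = min(int(t / EPOCH_LEN_S), n_epochs - 1)
        cv = bb_cv[e]
        if cv > 1e-9:
            shape = 1.0 / (cv * cv)
            bb = float(rng.gamma(shape, mean_bb[e] / shape))
        else:
            bb = float(mean_bb[e])
        t += max(bb, 0.5)
    breath_times = np.asarray(breaths)

    # --- movement bursts ---
    counts = rng.poisson(move_rate)
    bursts: list[tuple[float, float, float]] = []
    for e in range(n_epochs):
        for _ in range(int(counts[e])):
            start = e * EPOCH_LEN_S + rng.uniform(0.0, EPOCH_LEN_S)
            duration = rng.uniform(0.5, 4.0)
            intensity = rng.uniform(0.3, 1.0)
            bursts.append((start, min(duration, dur - start), intensity))
    burst_arr = np.asarray(bursts, dtype=float).reshape(-1, 3)

    mean_nn_epoch, _ = _epoch_slice_stats(beat_times, n_epochs)
    _, bb_cv_epoch = _epoch_slice_stats(breath_times, n_epochs)
    load = np.zeros(n_epochs)
    for start, duration, intensity in burst_arr:
        e0 = int(start // EPOCH_LEN_S)
        e1 = min(int((start + duration) // EPOCH_LEN_S), n_epochs - 1)
        for e in range(e0, e1 + 1):
            lo = max(start, e * EPOCH_LEN_S)
            hi = min(start + duration, (e + 1) * EPOCH_LEN_S)
            if hi > lo:
                load[e] += (hi - lo) * intensity

    return PhysioEvents(
        beat_times_s=beat_times,
        breath_times_s=breath_times,
        movement_bursts=burst_arr,
        duration_s=dur,
        true_mean_nn_ms=mean_nn_epoch * 1000.0,
        true_bb_cv=bb_cv_epoch,
        true_movement_load=load,
    )


# ---------------------------------------------------------------------------
# radar rendering


def _add_bumps(signal: np.ndarray, centers_s: np.ndarray, widths_s: np.ndarray,
               amps: float | np.ndarray, fs: float, phase_shift: float = 0.0) -> None:
    """Add raised-cosine bumps in place.  ``phase_shift`` (fraction of the
    width) shifts the bump centre, used to build a quadrature counterpart."""
    n = len(signal)
    amps = np.broadcast_to(np.asarray(amps, dtype=float), centers_s.shape)
    for c, w, a in zip(centers_s + phase_shift * widths_s, widths_s, amps):
        half = w / 2.0
        i0 = max(0, int(math.ceil((c - half) * fs)))
        i1 = min(n, int(math.floor((c + half) * fs)) + 1)
        if i1 <= i0:
            continue
        tau = np.arange(i0, i1) / fs - c
        signal[i0:i1] += a * 0.5 * (1.0 + np.cos(2.0 * math.pi * tau / (2.0 * half)))


def _cardiac_pulse_train(n: int, beat_times: np.ndarray, fs: float, amp: float,
                         f0: float, sigma: float, phase: float = 0.0) -> np.ndarray:
    """Gaussian-windowed oscillation (Gabor pulse) at each beat time."""
    sig = np.zeros(n)
    half_w = 3.0 * sigma
    for b in beat_times:
        i0 = max(0, int(math.ceil((b - half_w) * fs)))
        i1 = min(n, int(math.floor((b + half_w) * fs)) + 1)
        if i1 <= i0:
            continue
        tau = np.arange(i0, i1) / fs - b
        sig[i0:i1] += amp * np.exp(-0.5 * (tau / sigma) ** 2) * np.sin(
            2.0 * math.pi * f0 * tau + phase
        )
    return sig


def _movement_waveform(n: int, bursts: np.ndarray, fs: float, amp: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Large low-frequency excursions during gross-movement bursts, each
    followed by a persistent baseline shift (the body ends up in a new
    position relative to the radar)."""
    sig = np.zeros(n)
    baseline = np.zeros(n)
    level = 0.0
    order = np.argsort(bursts[:, 0]) if len(bursts) else []
    for start, duration, intensity in bursts[order]:
        i0 = max(0, int(start * fs))
        i1 = min(n, int((start + duration) * fs))
        if i1 <= i0:
            continue
        tau = np.arange(i1 - i0) / fs
        # gross movements are slow (turning over takes seconds); keeping the
        # oscillation below ~1 Hz lets it survive a 10 s moving average
        f = rng.uniform(0.2, 1.0)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        env = np.sin(math.pi * tau / duration) ** 2
        sig[i0:i1] += amp * intensity * env * np.sin(2.0 * math.pi * f * tau + phase)
        new_level = float(np.clip(level + rng.normal(0.0, 0.8) * intensity, -1.5, 1.5))
        baseline[i0:i1] = level + (new_level - level) * tau / (tau[-1] + 1e-9)
        baseline[i1:] = new_level
        level = new_level
    return sig + baseline


def _breath_widths(breath_times: np.ndarray, frac: float) -> np.ndarray:
    """Per-breath bump width: ``frac`` times the local BB interval."""
    if len(breath_times) == 0:
        return np.empty(0)
    if len(breath_times) == 1:
        return np.array([frac * 4.0])
    iv = np.diff(breath_times)
    local = np.minimum(np.concatenate([[iv[0]], iv]), np.concatenate([iv, [iv[-1]]]))
    return frac * local


def render_radar_night(events: PhysioEvents, config: SimConfig, seed: int,
                       participant_id: str = "") -> RadarNight:
    """Render per-node I/Q waveforms from the event streams.

    Each node sees: respiration as a raised-cosine chest bump per breath,
    cardiac micromotion as a small Gabor pulse per beat, and saturating
    gross-movement excursions, each scaled by a per-node gain drawn from the
    configured range (so different nodes favour different components, which
    is what motivates max-fusion downstream).  The clean mixture is clipped
    at the saturation level — movement bursts therefore destroy cardiac
    information — and additive white noise is applied after clipping.
    Occasional spurious artifact bursts (absent from the ground truth) model
    sensor glitches.
    """
    if len(events.beat_times_s) and events.beat_times_s[-1] > events.duration_s:
        raise ValueError("events extend past the night duration")
    noise = config.radar_noise
    fs = config.fs_hz
    n = int(round(events.duration_s * fs))
    rng = np.random.default_rng(seed)
    widths = _breath_widths(events.breath_times_s, config.resp_bump_frac)

    # spurious artifact bursts, drawn once and shared across nodes
    n_epochs = int(round(events.duration_s / EPOCH_LEN_S))
    hit = rng.random(n_epochs) < noise.artifact_prob
    artifacts = [
        (e * EPOCH_LEN_S + rng.uniform(0.0, EPOCH_LEN_S - 2.0), rng.uniform(0.5, 2.0),
         rng.uniform(0.5, 1.0))
        for e in np.flatnonzero(hit)
    ]
    all_bursts = np.concatenate(
        [events.movement_bursts, np.asarray(artifacts, dtype=float).reshape(-1, 3)], axis=0
    )

    lo, hi = noise.node_gain_range
    inphase = np.empty((config.n_nodes, n))
    quadrature = np.empty((config.n_nodes, n))
    for k in range(config.n_nodes):
        g_resp = rng.uniform(lo, hi)
        g_card = rng.uniform(lo, hi)
        resp_i = np.zeros(n)
        _add_bumps(resp_i, events.breath_times_s, widths, config.resp_amp, fs)
        resp_q = np.zeros(n)
        _add_bumps(resp_q, events.breath_times_s, widths, config.resp_amp, fs,
                   phase_shift=0.25)
        card_i = _cardiac_pulse_train(n, events.beat_times_s, fs, config.cardiac_amp,
                                      config.cardiac_freq_hz, config.cardiac_sigma_s)
        card_q = _cardiac_pulse_train(n, events.beat_times_s, fs, config.cardiac_amp,
                                      config.cardiac_freq_hz, config.cardiac_sigma_s,
                                      phase=math.pi / 2.0)
        move = _movement_waveform(n, all_bursts, fs, config.movement_amp, rng)
        clean_i = g_resp * resp_i + g_card * card_i + move
        clean_q = g_resp * resp_q + g_card * card_q + move
        np.clip(clean_i, -config.clip_level, config.clip_level, out=clean_i)
        np.clip(clean_q, -config.clip_level, config.clip_level, out=clean_q)
        if noise.waveform_noise_sd > 0:
            clean_i += rng.normal(0.0, noise.waveform_noise_sd, size=n)
            clean_q += rng.normal(0.0, noise.waveform_noise_sd, size=n)
        inphase[k] = clean_i
        quadrature[k] = clean_q

    node_ids = [f"node_{k}" for k in range(config.n_nodes)]
    return RadarNight(inphase, quadrature, fs, node_ids, participant_id)


# ---------------------------------------------------------------------------
# reference rendering


def _corrupt_times(times: np.ndarray, jitter_sd_s: float, drop_rate: float,
                   duration_s: float, rng: np.random.Generator) -> np.ndarray:
    out = times
    if drop_rate > 0 and len(out):
        out = out[rng.random(len(out)) >= drop_rate]
    if jitter_sd_s > 0 and len(out):
        out = out + rng.normal(0.0, jitter_sd_s, size=len(out))
        out = np.sort(out)
        out = out[(out >= 0) & (out <= duration_s)]
        keep = np.concatenate([[True], np.diff(out) > 1e-6])
        out = out[keep]
    return np.asarray(out, dtype=float)


def render_reference_night(events: PhysioEvents, config: SimConfig, seed: int,
                           participant_id: str = "") -> ReferenceNight:
    """Render the clean reference-modality streams.

    Beat and breath times pass through with small jitter and a low drop
    rate; activity counts per 30 s epoch are Poisson with mean proportional
    to the true movement load.  Under default configs this modality is
    strictly less corrupted than the radar rendering — that asymmetry is the
    simulated domain shift.
    """
    noise = config.reference_noise
    rng = np.random.default_rng(seed)
    beats = _corrupt_times(events.beat_times_s, noise.beat_jitter_sd_ms / 1000.0,
                           noise.event_drop_rate, events.duration_s, rng)
    breaths = _corrupt_times(events.breath_times_s, noise.breath_jitter_sd_s,
                             noise.event_drop_rate, events.duration_s, rng)
    n_epochs = int(round(events.duration_s / EPOCH_LEN_S))
    load = events.true_movement_load
    if len(load) != n_epochs:
        load = np.zeros(n_epochs)
    counts = np.where(load > 0, rng.poisson(15.0 * load), 0).astype(float)
    return ReferenceNight(beats, breaths, counts, participant_id)


# ---------------------------------------------------------------------------
# cohort


def simulate_night(config: SimConfig, seed: int, participant_id: str = "",
                   modalities: tuple[str, ...] = ("radar", "reference")) -> SimulatedNight:
    """Simulate one participant-night.  Sub-seeds are derived from ``seed``
    deterministically so each stage is independently reproducible."""
    ss = np.random.SeedSequence(seed)
    s_hyp, s_phys, s_radar, s_ref = (int(x) for x in ss.generate_state(4) % (2**31))
    hyp = simulate_hypnogram(config, s_hyp)
    events = simulate_physiology(hyp, config, s_phys)
    radar = (render_radar_night(events, config, s_radar, participant_id)
             if "radar" in modalities else None)
    ref = (render_reference_night(events, config, s_ref, participant_id)
           if "reference" in modalities else None)
    return SimulatedNight(participant_id, seed, hyp, events, radar, ref)


@dataclass
class Cohort:
    """A simulated cohort: a manifest plus lazy per-night generation.

    Nights are not materialized up front (full-night waveforms are large);
    ``night()`` regenerates any participant-night deterministically from the
    per-night seed recorded in the manifest.
    """

    config: SimConfig
    manifest: pd.DataFrame  # columns: participant_id, split, seed

    def participants(self, split: str | None = None) -> list[str]:
        m = self.manifest
        if split is not None:
            m = m[m["split"] == split]
        return list(m["participant_id"])

    def night(self, participant_id: str,
              modalities: tuple[str, ...] = ("radar", "reference")) -> SimulatedNight:
        row = self.manifest[self.manifest["participant_id"] == participant_id]
        if len(row) != 1:
            raise KeyError(f"unknown participant {participant_id!r}")
        return simulate_night(self.config, int(row["seed"].iloc[0]),
                              participant_id, modalities)


def simulate_cohort(config: SimConfig, n_train: int, n_test: int, seed: int) -> Cohort:
    """Build a cohort manifest with disjoint train/test participant sets.

    Per-night seeds are derived from the master seed via a seed sequence, so
    the same master seed always yields an identical manifest.
    """
    if n_train <= 0 or n_test <= 0:
        raise ValueError("n_train and n_test must be positive")
    n = n_train + n_test
    ss = np.random.SeedSequence(seed)
    night_seeds = (ss.generate_state(n) % (2**31)).astype(np.int64)
    rows = []
    for i in range(n):
        split = "train" if i < n_train else "test"
        rows.append({
            "participant_id": f"P{i + 1:04d}",
            "split": split,
            "seed": int(night_seeds[i]),
        })
    return Cohort(config, pd.DataFrame(rows))
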