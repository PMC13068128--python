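"""Radar DSP: movement chain, beat likelihood, fusion, peak detection,
respiration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import radarsleep as rs
from radarsleep.dsp import (
    BeatSeries,
    ProbabilitySeries,
    _centered_moving_average,
)
from radarsleep.hypnogram import EPOCH_LEN_S
from radarsleep.simulate import RadarNight


def night_from_inphase(channels, fs):
    """Build a RadarNight from raw in-phase arrays (quadrature = copy)."""
    inphase = np.atleast_2d(np.asarray(channels, dtype=float))
    return RadarNight(inphase, inphase.copy(), fs,
                      [f"node_{k}" for k in range(inphase.shape[0])])


def naive_movement_oracle(x, fs, threshold=0.2):
    """Step-by-step re-implementation of the six-stage movement chain."""
    n = len(x)
    win = int(round(10.0 * fs))
    sm = np.empty(n)
    for i in range(n):  # centered moving average, shrinking at boundaries
        lo = max(0, i - win // 2)
        hi = min(n, i + win // 2 + (win % 2))
        sm[i] = np.mean(x[lo:hi])
    z = (sm - sm.mean()) / sm.std()
    deriv = np.empty(n)
    deriv[0] = 0.0
    for i in range(1, n):
        deriv[i] = abs(z[i] - z[i - 1]) * fs
    lo, hi = deriv.min(), deriv.max()
    norm = (deriv - lo) / (hi - lo) if hi > lo else np.zeros(n)
    norm = np.where(norm < threshold, 0.0, norm)
    spe = int(round(EPOCH_LEN_S * fs))
    n_ep = n // spe
    return np.array([norm[e * spe:(e + 1) * spe].mean() for e in range(n_ep)])


class TestMovementFeature:
    def test_constant_waveform_gives_zero_everywhere(self):
        night = night_from_inphase(np.full((4, 8 * 30 * 2), 3.7), fs=8.0)
        with pytest.warns(UserWarning):
            out = rs.movement_feature(night)
        assert np.all(out.values == 0.0)

    def test_flat_node_fused_with_active_node_equals_active(self):
        fs = 4.0
        active = np.zeros(int(fs * 60))
        active[140:] = 5.0  # one step change in epoch 2
        flat = np.zeros_like(active)
        with pytest.warns(UserWarning):
            fused = rs.movement_feature(night_from_inphase([flat, active], fs))
        solo = rs.movement_feature(night_from_inphase([active], fs))
        assert np.allclose(fused.values, solo.values)

    def test_matches_naive_step_by_step_oracle(self):
        fs = 4.0
        rng = np.random.default_rng(0)
        x = 0.1 * np.sin(2 * np.pi * 0.25 * np.arange(int(fs * 90)) / fs)
        x[180:200] += 4.0 * rng.random(20)  # burst in the middle epoch
        ours = rs.movement_feature(night_from_inphase([x], fs)).values
        oracle = naive_movement_oracle(x, fs)
        assert np.allclose(ours, oracle, atol=1e-12)

    @given(scale=st.floats(0.1, 50.0), offset=st.floats(-20.0, 20.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_invariant_to_affine_rescaling(self, scale, offset):
        fs = 4.0
        rng = np.random.default_rng(7)
        x = np.cumsum(rng.normal(0, 1, int(fs * 90)))
        base = rs.movement_feature(night_from_inphase([x], fs)).values
        scaled = rs.movement_feature(night_from_inphase([scale * x + offset], fs)).values
        assert np.allclose(base, scaled, atol=1e-8)

    def test_zero_nodes_rejected(self):
        with pytest.raises(ValueError):
            night = night_from_inphase(np.zeros((1, 240)), fs=4.0)
            night.inphase = np.empty((0, 240))
            night.node_ids = []
            rs.movement_feature(night)


class TestBeatProbability:
    def test_all_zero_input_gives_zero_probability(self):
        p = rs.beat_probability(np.zeros(512), np.zeros(512), fs=64.0)
        assert np.all(p.values == 0.0)

    def test_tiny_noise_stays_below_background_level(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1e-3, 64 * 60)
        p = rs.beat_probability(x, rng.normal(0, 1e-3, 64 * 60), fs=64.0)
        assert p.values.mean() < 0.1

    def test_clean_pulse_train_localizes_beats(self, clean_night, noise_free_config):
        """Likelihood maxima fall within 100 ms of true beats for >= 95 %."""
        night = clean_night.radar
        probs = [rs.beat_probability(night.inphase[k], night.quadrature[k],
                                     night.fs_hz)
                 for k in range(night.n_nodes)]
        fused = rs.fuse_probabilities(probs)
        beats = rs.detect_beats(fused)
        true = clean_night.events.beat_times_s
        det = beats.beat_times_s
        hits = 0
        for t in true:
            j = np.searchsorted(det, t)
            d = min([abs(det[i] - t) for i in (j - 1, j) if 0 <= i < len(det)],
                    default=np.inf)
            hits += d <= 0.1
        assert hits / len(true) >= 0.95

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rs.beat_probability(np.zeros(10), np.zeros(11), fs=64.0)


class TestFuseProbabilities:
    def test_elementwise_max_example(self):
        a = ProbabilitySeries(np.array([0.2, 0.9, 0.1]), 1.0)
        b = ProbabilitySeries(np.array([0.5, 0.1, 0.1]), 1.0)
        assert np.allclose(rs.fuse_probabilities([a, b]).values, [0.5, 0.9, 0.1])

    def test_idempotent_and_zero_identity(self):
        a = ProbabilitySeries(np.array([0.3, 0.6]), 1.0)
        z = ProbabilitySeries(np.zeros(2), 1.0)
        assert np.allclose(rs.fuse_probabilities([a, a]).values, a.values)
        assert np.allclose(rs.fuse_probabilities([a, z]).values, a.values)

    @given(st.lists(st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4),
                    min_size=2, max_size=4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_commutative_and_monotone(self, rows):
        series = [ProbabilitySeries(np.array(r), 1.0) for r in rows]
        fwd = rs.fuse_probabilities(series).values
        rev = rs.fuse_probabilities(series[::-1]).values
        assert np.array_equal(fwd, rev)
        # adding a node never decreases any sample
        sub = rs.fuse_probabilities(series[:-1]).values
        assert np.all(fwd >= sub)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            rs.fuse_probabilities([])


class TestDetectBeats:
    def test_one_hz_pulse_train_yields_1000ms_median_nn(self):
        fs = 64.0
        t = np.arange(int(fs * 60)) / fs
        prob = np.clip(np.cos(2 * np.pi * 1.0 * t) ** 31, 0, 1)
        beats = rs.detect_beats(ProbabilitySeries(prob, fs))
        assert abs(len(beats) - 60) <= 1
        assert np.median(beats.nn_intervals_ms) == pytest.approx(1000.0, abs=20.0)

    def test_nn_intervals_respect_refractory_period(self, clean_dsp):
        _, beats, _ = clean_dsp
        assert np.all(beats.nn_intervals_ms >= 0.35 * 1000.0)

    def test_flat_probability_raises_insufficient_beats(self):
        with pytest.raises(ValueError, match="insufficient beats"):
            rs.detect_beats(ProbabilitySeries(np.zeros(640), 64.0))


class TestExtractRespiration:
    def test_am_carrier_at_quarter_hz_gives_4s_median_bb(self):
        # sub-cutoff carrier amplitude-modulated at the 0.25 Hz breath rate
        fs = 32.0
        t = np.arange(int(fs * 120)) / fs
        x = (1.0 + 0.8 * np.sin(2 * np.pi * 0.25 * t)) * np.cos(2 * np.pi * 0.4 * t)
        breaths = rs.extract_respiration(x, fs)
        assert np.median(breaths.bb_intervals_s) == pytest.approx(4.0, abs=0.2)

    def test_component_above_cutoff_is_removed(self):
        fs = 32.0
        t = np.arange(int(fs * 120)) / fs
        base = (1.0 + 0.8 * np.sin(2 * np.pi * 0.25 * t)) * np.cos(2 * np.pi * 0.4 * t)
        noisy = base + 2.0 * np.sin(2 * np.pi * 5.0 * t)
        bb_base = np.median(rs.extract_respiration(base, fs).bb_intervals_s)
        bb_noisy = np.median(rs.extract_respiration(noisy, fs).bb_intervals_s)
        assert abs(bb_noisy - bb_base) / bb_base < 0.05

    def test_breath_count_recovered_on_simulated_night(self, noisy_night):
        _, _, breaths = rs.process_radar_night(noisy_night.radar,
                                               saturation_level=0.93 * 4.0)
        true_n = len(noisy_night.events.breath_times_s)
        assert abs(len(breaths) - true_n) / true_n < 0.05

    def test_too_low_fs_rejected(self):
        with pytest.raises(ValueError):
            rs.extract_respiration(np.zeros(100), fs=0.5)


class TestHelpers:
    def test_centered_moving_average_shrinks_at_edges(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        out = _centered_moving_average(x, 3)
        assert out[0] == pytest.approx(np.mean(x[:2]))
        assert out[1] == pytest.approx(np.mean(x[:3]))
        assert out[-1] == pytest.approx(np.mean(x[-2:]))

    def test_beat_series_requires_increasing_times(self):
        with pytest.raises(ValueError):
            BeatSeries(np.array([1.0, 0.5]))
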