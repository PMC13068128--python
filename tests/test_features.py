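"""Feature extraction: toy-value oracles, spectral estimator equivalence,
invariances, table assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import radarsleep as rs
from radarsleep.config import FeatureWindowSpec
from radarsleep.dsp import BeatSeries, BreathSeries
from radarsleep.features import (
    _band_powers_from_series,
    _resampled_tachogram,
    hrv_band_powers,
    median_nn,
    rrv_features,
    sd2sd1,
)


def beats_from_nn_ms(nn_ms, t0=0.0):
    times = t0 + np.concatenate([[0.0], np.cumsum(np.asarray(nn_ms) / 1000.0)])
    return BeatSeries(times)


def breaths_from_bb_s(bb_s, t0=0.0):
    times = t0 + np.concatenate([[0.0], np.cumsum(np.asarray(bb_s))])
    return BreathSeries(times)


def brute_force_band_power(x, fs, lo, hi):
    """O(N^2) DFT + rectangular band integration, written independently of
    the fft-based estimator."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = len(x)
    total = 0.0
    for k in range(n // 2 + 1):
        f = k * fs / n
        if not (lo <= f < hi):
            continue
        re = sum(x[j] * np.cos(-2 * np.pi * k * j / n) for j in range(n))
        im = sum(x[j] * np.sin(-2 * np.pi * k * j / n) for j in range(n))
        power = (re * re + im * im) / (fs * n)
        if k not in (0, n // 2) or (k == n // 2 and n % 2 == 1):
            power *= 2.0
        total += power * fs / n
    return total


def poincare_oracle(nn_ms):
    """Independent ellipse-fit route: SD1/SD2 as population SDs of the
    Poincare cloud (x_i, x_{i+1}) projected on the +/-45 degree axes."""
    x = np.asarray(nn_ms, dtype=float)
    p, q = x[:-1], x[1:]
    minor = (q - p) / np.sqrt(2.0)
    major = (q + p) / np.sqrt(2.0)
    sd1 = np.std(minor)
    sd2 = np.std(major)
    return sd1, sd2


class TestMedianNN:
    def test_constant_intervals(self):
        beats = beats_from_nn_ms([800] * 10)
        assert median_nn(beats, (0.0, 10.0)) == pytest.approx(800.0)

    def test_sort_and_pick_oracle(self):
        beats = beats_from_nn_ms([700, 900, 800, 1000, 600])
        assert median_nn(beats, (0.0, 10.0)) == pytest.approx(800.0)

    def test_empty_window_flags_invalid(self):
        beats = beats_from_nn_ms([800] * 10)
        assert np.isnan(median_nn(beats, (100.0, 130.0)))

    def test_interval_attributed_to_window_of_ending_beat(self):
        beats = beats_from_nn_ms([1000] * 6)  # beats at 0..6 s
        # window [2.5, 5.5) contains beats ending at 3, 4, 5 -> 3 intervals
        assert median_nn(beats, (2.5, 5.5)) == pytest.approx(1000.0)
        assert np.isnan(median_nn(beats, (2.5, 4.5)))  # only 2 intervals


class TestSD2SD1:
    def test_alternating_sequence_collapses_sd2(self):
        nn = [800, 1000, 800, 1000, 800, 1000]
        beats = beats_from_nn_ms(nn)
        ratio = sd2sd1(beats, (0.0, 10.0))
        sd1, sd2 = poincare_oracle(nn)
        # hand computation: diffs alternate +/-200 (5 values, mean 40), so
        # population var(diff) = 38400 and SD1 = sqrt(38400/2) = 138.56;
        # var(NN) = 10000, SD2^2 = 2*10000 - 19200 = 800, ratio = sqrt(1/24)
        assert sd1 == pytest.approx(138.56, abs=0.01)
        assert ratio == pytest.approx(np.sqrt(1.0 / 24.0), rel=1e-9)
        assert ratio < 0.25  # SD2 nearly collapses for a pure alternation
        _ = sd2

    def test_constant_nn_is_invalid(self):
        beats = beats_from_nn_ms([900] * 8)
        assert np.isnan(sd2sd1(beats, (0.0, 10.0)))

    @given(st.integers(0, 10_000), st.integers(150, 400))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_ellipse_fit_oracle(self, seed, n):
        # the variance identities and the direct ellipse projection agree up
        # to O(1/n) boundary terms, hence the long physiological sequences
        rng = np.random.default_rng(seed)
        t = np.arange(n)
        nn = (900.0 + 80.0 * np.sin(2 * np.pi * t / 40.0) + rng.normal(0, 30.0, n))
        beats = beats_from_nn_ms(nn)
        ratio = sd2sd1(beats, (0.0, 1e6))
        sd1, sd2 = poincare_oracle(nn)
        assert ratio == pytest.approx(sd2 / max(sd1, 1e-9), rel=1e-2)


class TestHRVBandPowers:
    def test_lf_modulation_concentrates_in_lf_band(self):
        # NN(t) = 1000 + 100 sin(2 pi 0.1 t) ms, beats placed accordingly
        times = [0.0]
        while times[-1] < 150.0:
            nn = 1000.0 + 100.0 * np.sin(2 * np.pi * 0.1 * times[-1])
            times.append(times[-1] + nn / 1000.0)
        beats = BeatSeries(np.array(times))
        p = hrv_band_powers(beats, (0.0, 150.0))
        assert p["LF"] > 10.0 * (p["VLF"] + p["HF"])

    def test_constant_nn_has_negligible_power(self):
        beats = beats_from_nn_ms([1000] * 150)
        t = np.arange(0.0, 150.0, 0.8)
        mod = BeatSeries(np.concatenate([[0.0], np.cumsum(
            (1000.0 + 100.0 * np.sin(2 * np.pi * 0.1 * t[:150])) / 1000.0)]))
        p_flat = hrv_band_powers(beats, (0.0, 150.0))
        p_mod = hrv_band_powers(mod, (0.0, 150.0))
        assert p_flat["TotalPower"] <= 1e-6 * p_mod["TotalPower"]

    def test_total_power_equals_band_sum(self, clean_night):
        beats = BeatSeries(clean_night.events.beat_times_s)
        p = hrv_band_powers(beats, (60.0, 210.0))
        assert p["TotalPower"] == pytest.approx(p["VLF"] + p["LF"] + p["HF"], rel=1e-9)

    def test_estimator_matches_brute_force_dft(self):
        """fft periodogram vs O(N^2) DFT oracle to 1e-6 relative."""
        rng = np.random.default_rng(5)
        x = rng.normal(0, 50, 240)  # 60 s at 4 Hz
        for lo, hi in [(0.003, 0.04), (0.04, 0.15), (0.15, 0.4)]:
            mine = _band_powers_from_series(x, 4.0, {"b": (lo, hi)})["b"]
            ref = brute_force_band_power(x, 4.0, lo, hi)
            assert mine == pytest.approx(ref, rel=1e-6)

    def test_sparse_window_flags_invalid(self):
        beats = beats_from_nn_ms([1000] * 5)
        p = hrv_band_powers(beats, (0.0, 150.0))
        assert all(np.isnan(v) for v in p.values())


class TestRRVFeatures:
    WINDOWS = {k: (0.0, 100.0) for k in ("MedianBB", "CVBB", "MCVBB", "RRV_LF")}

    def test_printed_toy_sequence(self):
        breaths = breaths_from_bb_s([1.0, 1.2, 0.8, 1.0])
        out = rrv_features(breaths, self.WINDOWS)
        assert out["MedianBB"] == pytest.approx(1.0)
        assert out["CVBB"] == pytest.approx(np.sqrt(0.02) / 1.0, abs=1e-4)  # 0.1414
        assert out["CVBB"] == pytest.approx(0.1414, abs=1e-3)
        # mean |BB - mean| = (0+0.2+0.2+0)/4 = 0.1; median = 1.0
        assert out["MCVBB"] == pytest.approx(0.1)

    def test_constant_bb_has_zero_dispersion(self):
        out = rrv_features(breaths_from_bb_s([4.0] * 10), self.WINDOWS)
        assert out["CVBB"] == 0.0
        assert out["MCVBB"] == 0.0

    @given(st.floats(0.25, 4.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_cv_ratios_scale_invariant(self, c):
        bb = np.array([3.1, 4.0, 3.4, 4.4, 3.9, 3.6])
        a = rrv_features(breaths_from_bb_s(bb), self.WINDOWS)
        b = rrv_features(breaths_from_bb_s(c * bb), self.WINDOWS)
        assert a["CVBB"] == pytest.approx(b["CVBB"], rel=1e-9)
        assert a["MCVBB"] == pytest.approx(b["MCVBB"], rel=1e-9)

    def test_insufficient_breaths_flagged(self):
        out = rrv_features(breaths_from_bb_s([1.0, 1.1]), self.WINDOWS)
        assert np.isnan(out["MedianBB"]) and np.isnan(out["MCVBB"])


class TestWindowsAndShiftInvariance:
    @given(st.floats(0.0, 500.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_features_invariant_under_time_origin_shift(self, shift):
        nn = [820, 930, 870, 990, 910, 860, 940]
        a = beats_from_nn_ms(nn, t0=0.0)
        b = beats_from_nn_ms(nn, t0=shift)
        w0 = (0.0, 30.0)
        w1 = (shift, shift + 30.0)
        assert median_nn(a, w0) == pytest.approx(median_nn(b, w1), rel=1e-12)
        assert sd2sd1(a, w0) == pytest.approx(sd2sd1(b, w1), rel=1e-9)

    def test_window_spec_rejects_sub_epoch_windows(self):
        with pytest.raises(ValueError):
            FeatureWindowSpec(act=0.25)

    def test_centered_window_clipped_at_recording_edges(self):
        spec = FeatureWindowSpec()
        t0, t1 = spec.window_for("mcvbb", 0, 600.0)
        assert t0 == 0.0 and t1 == pytest.approx(15.0 + 135.0)


class TestAssembleEpochTable:
    def test_one_row_per_epoch(self, clean_night, clean_dsp):
        movement, beats, breaths = clean_dsp
        table = rs.assemble_epoch_table(clean_night.hypnogram, movement, beats,
                                        breaths, participant_id="P1")
        assert len(table) == len(clean_night.hypnogram)
        assert list(table["epoch_index"]) == list(range(len(table)))

    def test_boundary_epochs_marked_truncated(self, clean_night, clean_dsp):
        movement, beats, breaths = clean_dsp
        table = rs.assemble_epoch_table(clean_night.hypnogram, movement, beats, breaths)
        assert bool(table["truncated"].iloc[0]) is True
        mid = len(table) // 2
        assert bool(table["truncated"].iloc[mid]) is False

    def test_radar_median_nn_tracks_ground_truth(self, clean_night, clean_dsp):
        """Clean-night MedianNN correlates with true per-epoch mean NN."""
        movement, beats, breaths = clean_dsp
        table = rs.assemble_epoch_table(clean_night.hypnogram, movement, beats, breaths)
        est = table["MedianNN_long"].to_numpy(float)
        true = clean_night.events.true_mean_nn_ms
        ok = np.isfinite(est) & np.isfinite(true)
        r = np.corrcoef(est[ok], true[ok])[0, 1]
        assert r > 0.9

    def test_schema_shared_between_modalities(self, clean_night, clean_dsp):
        movement, beats, breaths = clean_dsp
        radar = rs.assemble_epoch_table(clean_night.hypnogram, movement, beats, breaths)
        ref = rs.reference_epoch_table(clean_night.hypnogram, clean_night.reference)
        assert list(radar.columns) == list(ref.columns)

    def test_duration_mismatch_rejected(self, clean_night, clean_dsp):
        movement, beats, breaths = clean_dsp
        short_hyp = rs.Hypnogram(clean_night.hypnogram.stages[:10])
        with pytest.raises(ValueError):
            rs.assemble_epoch_table(short_hyp, movement, beats, breaths)

    def test_invalid_epochs_flagged_not_dropped(self):
        hyp = rs.Hypnogram(np.array(["N2"] * 8, dtype=object))
        beats = beats_from_nn_ms([900] * 30)   # only ~27 s of beats
        breaths = breaths_from_bb_s([4.0] * 12)
        table = rs.assemble_epoch_table(hyp, np.zeros(8), beats, breaths)
        assert len(table) == 8
        assert (~table["valid"]).any()
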