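"""Simulator behaviour: sleep architecture, stage physiology, renderings."""

import dataclasses

import numpy as np
import pytest

import radarsleep as rs
from radarsleep.config import STATIONARY_STAGE_DIST
from radarsleep.evaluation import nn_recovery_mae_ms
from conftest import make_stage_run_hypnogram


def identity_transition_config(n_epochs=10):
    return rs.SimConfig(night_len_epochs=n_epochs, stage_transition=np.eye(5))


class TestHypnogram:
    def test_absorbing_identity_chain_stays_in_wake(self):
        hyp = rs.simulate_hypnogram(identity_transition_config(10), seed=0)
        assert list(hyp.stages) == ["W"] * 10

    def test_same_seed_reproduces_stage_sequence(self, short_config):
        a = rs.simulate_hypnogram(short_config, seed=5)
        b = rs.simulate_hypnogram(short_config, seed=5)
        assert list(a.stages) == list(b.stages)

    def test_invalid_transition_matrix_rejected(self):
        bad = np.full((5, 5), 0.3)
        with pytest.raises(ValueError):
            rs.SimConfig(stage_transition=bad)

    def test_empirical_distribution_converges_to_stationary(self):
        cfg = rs.SimConfig(night_len_epochs=100_000)
        hyp = rs.simulate_hypnogram(cfg, seed=3)
        emp = np.array([np.mean(hyp.stages == c) for c in rs.SCHEME_AASM5.classes])
        tv = 0.5 * np.sum(np.abs(emp - STATIONARY_STAGE_DIST))
        assert tv < 0.05

    def test_pooled_n1_prevalence_near_cohort_value(self):
        # pooled over many nights, the N1 share of epochs sits near 7.3 %
        cfg = rs.SimConfig(night_len_epochs=960)
        stages = np.concatenate([
            rs.simulate_hypnogram(cfg, seed=s).stages for s in range(40)])
        assert 0.053 < np.mean(stages == "N1") < 0.093


class TestPhysiology:
    def test_all_n3_night_matches_configured_bb_cv(self, short_config):
        hyp = make_stage_run_hypnogram("N3", 40)
        ev = rs.simulate_physiology(hyp, short_config, seed=1)
        bb = ev.bb_intervals_s
        cv = np.std(bb) / np.mean(bb)
        target = short_config.stage_physiology["N3"].bb_cv
        assert abs(cv - target) < 0.02

    def test_heart_slows_in_deep_sleep(self, short_config):
        # mean NN in N3 epochs exceeds mean NN in Wake epochs (HR decreases)
        diffs = []
        for seed in range(6):
            hyp = rs.simulate_hypnogram(short_config, seed=seed)
            if not (np.any(hyp.stages == "N3") and np.any(hyp.stages == "W")):
                continue
            ev = rs.simulate_physiology(hyp, short_config, seed=seed + 100)
            nn = ev.true_mean_nn_ms
            diffs.append(np.nanmean(nn[hyp.stages == "N3"])
                         - np.nanmean(nn[hyp.stages == "W"]))
        assert diffs and np.mean(diffs) > 0

    def test_rem_atonia_reduces_movement_bursts(self, short_config):
        rem_rate, wake_rate = [], []
        for seed in range(10):
            hyp = rs.simulate_hypnogram(short_config, seed=seed)
            ev = rs.simulate_physiology(hyp, short_config, seed=seed + 50)
            counts = np.zeros(len(hyp))
            for start, _, _ in ev.movement_bursts:
                counts[min(int(start // 30.0), len(hyp) - 1)] += 1
            if np.any(hyp.stages == "R"):
                rem_rate.append(np.mean(counts[hyp.stages == "R"]))
            if np.any(hyp.stages == "W"):
                wake_rate.append(np.mean(counts[hyp.stages == "W"]))
        assert np.mean(rem_rate) < np.mean(wake_rate)

    def test_monotone_stage_orderings_in_expectation(self, short_config):
        """Configured physiology orderings hold over >= 20 seeded nights."""
        agg = {s: {"nn": [], "bbcv": [], "move": []} for s in rs.SCHEME_AASM5.classes}
        for seed in range(20):
            hyp = rs.simulate_hypnogram(short_config, seed=seed)
            ev = rs.simulate_physiology(hyp, short_config, seed=seed + 500)
            counts = np.zeros(len(hyp))
            for start, _, _ in ev.movement_bursts:
                counts[min(int(start // 30.0), len(hyp) - 1)] += 1
            for s in agg:
                sel = hyp.stages == s
                if np.any(sel):
                    agg[s]["nn"].append(np.nanmean(ev.true_mean_nn_ms[sel]))
                    agg[s]["bbcv"].append(np.nanmean(ev.true_bb_cv[sel]))
                    agg[s]["move"].append(np.mean(counts[sel]))
        mean = {s: {k: np.nanmean(v) for k, v in d.items()} for s, d in agg.items()}
        assert mean["N3"]["nn"] > mean["W"]["nn"]
        assert mean["N3"]["bbcv"] < mean["R"]["bbcv"]
        assert mean["N3"]["bbcv"] < mean["W"]["bbcv"]
        assert mean["W"]["move"] > mean["N1"]["move"] > mean["N3"]["move"]

    def test_rejects_three_class_hypnogram(self, short_config):
        hyp = rs.map_labels(make_stage_run_hypnogram("N2", 4))
        with pytest.raises(ValueError):
            rs.simulate_physiology(hyp, short_config, seed=0)

    def test_intervals_strictly_positive(self, short_config):
        hyp = rs.simulate_hypnogram(short_config, seed=9)
        ev = rs.simulate_physiology(hyp, short_config, seed=9)
        assert np.all(ev.nn_intervals_ms > 0)
        assert np.all(ev.bb_intervals_s > 0)


class TestRadarRendering:
    def test_constant_breathing_dominates_spectrum_at_breath_rate(self):
        """Zero noise, no movement, 4 s breaths: DFT argmax at 0.25 Hz."""
        cfg = rs.SimConfig(night_len_epochs=4)
        cfg.radar_noise = rs.ModalityNoise(node_gain_range=(1.0, 1.0))
        breaths = np.arange(2.0, 118.0, 4.0)
        ev = rs.PhysioEvents(
            beat_times_s=np.arange(1.0, 119.0, 1.0),
            breath_times_s=breaths,
            movement_bursts=np.empty((0, 3)),
            duration_s=cfg.night_duration_s,
        )
        night = rs.render_radar_night(ev, cfg, seed=0)
        x = night.inphase[0] - np.mean(night.inphase[0])
        spec = np.abs(np.fft.rfft(x))
        freqs = np.fft.rfftfreq(len(x), d=1.0 / cfg.fs_hz)
        assert freqs[np.argmax(spec)] == pytest.approx(0.25, abs=0.02)

    def test_zero_gain_node_is_pure_noise(self):
        cfg = rs.SimConfig(night_len_epochs=2, n_nodes=1)
        cfg.radar_noise = rs.ModalityNoise(waveform_noise_sd=0.1,
                                           node_gain_range=(0.0, 0.0))
        beats = np.arange(0.5, 59.5, 1.0)
        ev = rs.PhysioEvents(beats, np.arange(1.0, 59.0, 4.0), np.empty((0, 3)),
                             duration_s=cfg.night_duration_s)
        night = rs.render_radar_night(ev, cfg, seed=1)
        # correlation with a unit-gain rendering of the same events ~ 0
        cfg2 = dataclasses.replace(cfg)
        cfg2.radar_noise = rs.ModalityNoise(node_gain_range=(1.0, 1.0))
        clean = rs.render_radar_night(ev, cfg2, seed=2)
        r = np.corrcoef(night.inphase[0], clean.inphase[0])[0, 1]
        assert abs(r) < 0.05

    def test_same_seed_renders_identical_waveforms(self, clean_night, noise_free_config):
        again = rs.render_radar_night(clean_night.events, noise_free_config, seed=11)
        twice = rs.render_radar_night(clean_night.events, noise_free_config, seed=11)
        assert np.array_equal(again.inphase, twice.inphase)
        assert np.array_equal(again.quadrature, twice.quadrature)

    def test_fs_too_low_for_cardiac_band_rejected(self):
        with pytest.raises(ValueError):
            rs.SimConfig(fs_hz=32.0)

    def test_node_lengths_consistent(self, clean_night):
        night = clean_night.radar
        assert night.inphase.shape == night.quadrature.shape
        expected = round(clean_night.events.duration_s * night.fs_hz)
        assert abs(night.n_samples - expected) <= 1


class TestReferenceRendering:
    def test_zero_noise_reference_passes_events_through(self, clean_night,
                                                        noise_free_config):
        ref = rs.render_reference_night(clean_night.events, noise_free_config, seed=4)
        assert np.allclose(ref.beat_times_s, clean_night.events.beat_times_s)
        assert np.allclose(ref.breath_times_s, clean_night.events.breath_times_s)

    def test_epoch_without_bursts_has_zero_activity(self, short_config):
        hyp = make_stage_run_hypnogram("N3", 20)
        ev = rs.simulate_physiology(hyp, short_config, seed=21)
        ref = rs.render_reference_night(ev, short_config, seed=2)
        no_burst = ev.true_movement_load == 0
        assert no_burst.any()
        assert np.all(ref.activity_counts[no_burst] == 0)

    def test_reference_recovers_nn_better_than_radar(self, noisy_night, short_config):
        """The domain shift: NN recovery error (reference) < (radar)."""
        ev = noisy_night.events
        ref_mae = nn_recovery_mae_ms(ev.beat_times_s, noisy_night.reference.beat_times_s)
        _, beats, _ = rs.process_radar_night(
            noisy_night.radar, saturation_level=0.93 * short_config.clip_level)
        radar_mae = nn_recovery_mae_ms(ev.beat_times_s, beats.beat_times_s)
        assert ref_mae < radar_mae


class TestCohort:
    def test_manifest_disjoint_splits(self, short_config):
        cohort = rs.simulate_cohort(short_config, n_train=2, n_test=1, seed=0)
        m = cohort.manifest
        assert len(m) == 3 and m["participant_id"].is_unique
        assert set(m[m.split == "train"].participant_id).isdisjoint(
            m[m.split == "test"].participant_id)

    def test_same_master_seed_identical_manifest(self, short_config):
        a = rs.simulate_cohort(short_config, 3, 2, seed=42).manifest
        b = rs.simulate_cohort(short_config, 3, 2, seed=42).manifest
        assert a.equals(b)

    def test_nonpositive_sizes_rejected(self, short_config):
        with pytest.raises(ValueError):
            rs.simulate_cohort(short_config, 0, 1, seed=0)

    def test_mean_total_sleep_time_near_cohort_value(self):
        cfg = rs.SimConfig(night_len_epochs=960)
        tst = [rs.simulate_hypnogram(cfg, seed=s).total_sleep_time_min()
               for s in range(60)]
        assert abs(np.mean(tst) - 428.0) < 25.0
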