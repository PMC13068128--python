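import dataclasses

import numpy as np
import pytest

import radarsleep as rs


@pytest.fixture(scope="session")
def short_config() -> rs.SimConfig:
    """A 30 min night at the test sampling rate."""
    return rs.SimConfig(night_len_epochs=60)


@pytest.fixture(scope="session")
def noise_free_config(short_config) -> rs.SimConfig:
    cfg = dataclasses.replace(short_config)
    cfg.radar_noise = rs.ModalityNoise(node_gain_range=(0.8, 1.0))
    cfg.reference_noise = rs.ModalityNoise()
    return cfg


@pytest.fixture(scope="session")
def clean_night(noise_free_config):
    """One noise-free simulated night with radar and reference renderings."""
    return rs.simulate_night(noise_free_config, seed=11, participant_id="P1")


@pytest.fixture(scope="session")
def noisy_night(short_config):
    return rs.simulate_night(short_config, seed=11, participant_id="P1")


@pytest.fixture(scope="session")
def clean_dsp(clean_night, noise_free_config):
    movement, beats, breaths = rs.process_radar_night(
        clean_night.radar, saturation_level=0.93 * noise_free_config.clip_level)
    return movement, beats, breaths


def make_stage_run_hypnogram(stage: str, n: int) -> rs.Hypnogram:
    return rs.Hypnogram(np.array([stage] * n, dtype=object))
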