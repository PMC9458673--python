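import dataclasses

import numpy as np
import pytest

from avprofiler import GroundTruthProfile, SeasonConfig, simulate_season, simulate_session

REFERENCE_PROFILE = GroundTruthProfile("ref", A0=4.72, V0=8.86)


@pytest.fixture(scope="session")
def ref_profile() -> GroundTruthProfile:
    return REFERENCE_PROFILE


@pytest.fixture(scope="session")
def tiny_config() -> SeasonConfig:
    """Small season for structural tests: 6 players, short sessions."""
    return SeasonConfig(
        n_players=6,
        n_games=12,
        n_trainings=24,
        game_duration_s=900.0,
        training_duration_s=600.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_season(tiny_config):
    return simulate_season(tiny_config)


@pytest.fixture()
def noise_free_config() -> SeasonConfig:
    return dataclasses.replace(SeasonConfig(), noise_sd=0.0)


def make_session(profile, seed, duration_s=1800.0, noise_sd=0.1, kind="game"):
    cfg = dataclasses.replace(SeasonConfig(), noise_sd=noise_sd)
    rng = np.random.default_rng(seed)
    return simulate_session(profile, kind, duration_s, cfg, rng)
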