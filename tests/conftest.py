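"""Shared fixtures: synthetic sessions and random SPD samples."""

from __future__ import annotations

import numpy as np
import pytest

from streambci.pipeline import (
    SyntheticStudyConfig,
    preprocess_session,
    simulate_and_decode,
)
from streambci.synthetic_data import (
    NoiseConfig,
    SessionPlan,
    make_erp_templates,
    simulate_session,
)


def random_spd(rng: np.random.Generator, d: int, scale: float = 1.0) -> np.ndarray:
    """A well-conditioned random SPD matrix."""
    a = rng.normal(size=(d, d))
    return scale * (a @ a.T + d * np.eye(d))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def templates():
    return make_erp_templates()


@pytest.fixture(scope="session")
def small_study_config() -> SyntheticStudyConfig:
    """Reduced-scale study: 1 block x 3 runs of 120 s (fast, still decodable)."""
    return SyntheticStudyConfig(blocks=1, run_duration=120.0)


@pytest.fixture(scope="session")
def small_session(small_study_config):
    """Preprocessed small synthetic session shared across evaluation tests."""
    recs = simulate_session(
        SessionPlan.default(blocks=small_study_config.blocks),
        small_study_config.templates(),
        NoiseConfig(),
        soa=small_study_config.soa,
        deviant_prob=small_study_config.deviant_prob,
        run_duration=small_study_config.run_duration,
        seed=42,
    )
    return preprocess_session(recs)


@pytest.fixture(scope="session")
def small_decode_results(small_session):
    from streambci.pipeline import decode_session

    return decode_session(small_session, n_folds=5, seed=7)
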