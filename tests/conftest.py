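"""Shared fixtures: small synthetic bundles and a short reference fit."""

from __future__ import annotations

import numpy as np
import pytest

import gazezib as gz
from gazezib.design import ExperimentConfig


@pytest.fixture(scope="session")
def small_bundle():
    """Weight-level bundle: 6 participants x 4 images x 2 impressions x 2 conditions."""
    cfg = ExperimentConfig(
        n_participants=6,
        images_per_impression=4,
        impressions=("openness", "neuroticism"),
        trials_per_condition=8,
    )
    return gz.generate_experiment(cfg, seed=11)


@pytest.fixture(scope="session")
def gaze_bundle():
    """Gaze-level bundle exercising the preprocessing pipeline end to end."""
    cfg = ExperimentConfig(
        n_participants=3,
        images_per_impression=2,
        impressions=("openness", "neuroticism"),
        trials_per_condition=4,
        fidelity="gaze",
    )
    return gz.generate_experiment(cfg, seed=7)


@pytest.fixture(scope="session")
def recovery_bundle():
    """Weight-level bundle sized for quick but converging fits (12 x 6)."""
    cfg = ExperimentConfig(
        n_participants=12,
        images_per_impression=6,
        impressions=("openness",),
        trials_per_condition=6,
        conditions=("free",),
    )
    return gz.generate_experiment(cfg, seed=3)


@pytest.fixture(scope="session")
def short_posterior(recovery_bundle):
    """A short but well-mixed fit of one scope of the recovery bundle."""
    return gz.fit(
        recovery_bundle.weights,
        recovery_bundle.personality,
        ("free", "openness", "eyes"),
        gz.MCMCConfig(chains=4, iterations=600, warmup=300, seed=2),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
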