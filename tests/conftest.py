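"""Shared fixtures: small, fast cohort configurations.

All test cohorts run at 250 Hz with a reduced 16-channel montage (the
analysis ROI and both mastoids are always retained); that keeps every
generator call in the tens of milliseconds while preserving the spatial
structure the analyses rely on.
"""

from __future__ import annotations

import numpy as np
import pytest

from illusioneeg.config import CONDITIONS, SimConfig


def make_config(**overrides) -> SimConfig:
    defaults = dict(n_subjects=4, n_channels=16, rate_hz=250.0,
                    trials_per_condition=5, audiobook_duration_s=60.0, seed=0)
    defaults.update(overrides)
    return SimConfig(**defaults)


def make_null_config(**overrides) -> SimConfig:
    """A cohort with no injected effects: identical condition distributions."""
    defaults = dict(
        erp_gains={c: {"n1_gain": 0.0, "p2_gain": 0.0} for c in CONDITIONS},
        band_dynamics={c: {"beta": [], "gamma": []} for c in CONDITIONS},
        condition_language={c: ("english", 1.0) for c in CONDITIONS},
        rating_probs={c: [1 / 3, 1 / 3, 1 / 3] for c in CONDITIONS},
    )
    defaults.update(overrides)
    return make_config(**defaults)


def make_silent_config(**overrides) -> SimConfig:
    """No noise, no language sources, no bursts: templates only."""
    defaults = dict(
        noise={"exponent": 1.0, "spatial_scale": 0.35, "amplitude_uv": 0.0},
        band_dynamics={c: {"beta": [], "gamma": []} for c in CONDITIONS},
        language_covariance={
            "english": {"center": (-0.55, 0.05), "sigma": 0.35,
                        "gain_uv": 0.0, "band_hz": (4.0, 30.0)},
            "italian": {"center": (0.55, 0.05), "sigma": 0.35,
                        "gain_uv": 0.0, "band_hz": (4.0, 30.0)},
        },
    )
    defaults.update(overrides)
    return make_config(**defaults)


@pytest.fixture
def small_config() -> SimConfig:
    return make_config()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
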