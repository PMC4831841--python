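"""Shared fixtures.

The heavy benchmark runs (full artery scenarios) are session-scoped so the
acceptance tests and the qualitative reproduction tests share one run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from porogrowth.scenarios import preset_config, run_preset, run_scenario


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1729)


@pytest.fixture(scope="session")
def rigid_runs():
    """Time-driven growth of the rigid cylinder, both mass-source variants."""
    return run_preset("rigid-time")


@pytest.fixture(scope="session")
def stress_mphets_run():
    """Stress-driven growth of the 320-element mixture model (full run)."""
    return run_scenario(preset_config("stress-mphets"))


@pytest.fixture(scope="session")
def stress_he_run():
    """Stress-driven growth of the matching hyperelastic model."""
    return run_scenario(preset_config("stress-he"))


@pytest.fixture(scope="session")
def conc_runs():
    """Concentration-driven growth at the two diffusivities (full runs)."""
    return {
        "largeP": run_scenario(preset_config("conc-largeP")),
        "smallP": run_scenario(preset_config("conc-smallP")),
    }


def random_spd(rng, scale=0.2):
    """Random symmetric positive-definite 3x3 near the identity."""
    A = rng.uniform(-scale, scale, (3, 3))
    return np.eye(3) + 0.5 * (A + A.T) + A @ A.T
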