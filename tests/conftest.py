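"""Shared fixtures.

The expensive end-to-end training run (synthetic 200/class, tiny
preset) is session-scoped and shared by the tests that need a trained
classifier (accuracy and lesion-localisation checks).
"""

from __future__ import annotations

import numpy as np
import pytest

from gabnet.nn import set_default_dtype


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def float64_mode():
    """Run the engine in float64 (finite-difference gradient checks)."""
    set_default_dtype(np.float64)
    yield
    set_default_dtype(np.float32)


@pytest.fixture(scope="session")
def scaled_experiment():
    """One full synth -> train -> eval run on 200 images/class (tiny preset)."""
    from gabnet.pipeline import run_scaled_experiment

    return run_scaled_experiment(seed=0)
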