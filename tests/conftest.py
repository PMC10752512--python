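"""Shared fixtures: synthetic populations, truths, and one full
calibration run (six platforms, 5000 candidates, keep 100, seed 42)
reused by every test that scores recovery or summaries."""

import numpy as np
import pytest

from youthads import RunConfig, observe_truth, run_pipeline
from youthads.synthetic import (default_band_layout, default_truths,
                                make_truth, synthetic_population)


@pytest.fixture(scope="session")
def population():
    return synthetic_population()


@pytest.fixture(scope="session")
def layout():
    return default_band_layout()


@pytest.fixture(scope="session")
def truths():
    return default_truths()


@pytest.fixture(scope="session")
def flat_truth():
    """A constant-prevalence, constant-minutes truth: exactly
    representable by the midpoint-knot spline model, so recovery is
    limited only by sampling noise and search resolution."""
    return make_truth(
        "flatnet",
        prevalence=dict(pmax=0.4, a_on=-100.0, w_on=1.0, a_off=500.0, w_off=1.0),
        minutes_knots=[(0, 30), (84, 30)],
        revenue_per_minute=2e-5,
    )


@pytest.fixture(scope="session")
def observed42(truths, population, layout):
    """Noisy survey-style observations of the default truths, seed 42."""
    return [observe_truth(t, population, layout, seed=42)
            for t in truths.values()]


@pytest.fixture(scope="session")
def config42():
    return RunConfig(seed=42, n_candidates=5000, n_keep=100)


@pytest.fixture(scope="session")
def pipeline42(config42, population, observed42):
    """Full default run: fit, allocate and summarize all six synthetic
    platforms. Session-scoped because the fit is the expensive step."""
    return run_pipeline(config42, population, observed42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
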