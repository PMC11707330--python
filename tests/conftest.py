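import numpy as np
import pytest

from plasmidcge import (
    GroundTruth,
    SimulationConfig,
    correct_background,
    fit_linear_baseline,
    matched_windows,
    simulate_trace,
)


@pytest.fixture
def clean_config():
    """Noiseless, jitter-free, unclipped simulator with the default geometry."""
    return SimulationConfig(seed=0, noise_sd=0.0, migration_jitter_sd=0.0)


@pytest.fixture
def default_config():
    """Simulator at the study conditions (noise, jitter, drifting baseline)."""
    return SimulationConfig(seed=0)


@pytest.fixture
def wide_windows(clean_config):
    """Windows matched to the simulated bands (6 sigma half-widths)."""
    return matched_windows(clean_config)


def corrected_lane(truth: GroundTruth, config: SimulationConfig, windows, **kw):
    """Simulate one lane and background-correct it with a fitted line."""
    trace, _ = simulate_trace(truth, config, **kw)
    model = fit_linear_baseline(trace, [iv for _, iv in windows.items()])
    return correct_background(trace, model)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
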