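import numpy as np
import pytest

from mcmflow import OpticsConfig, apply_measurement_model, get_scenario, simulate_cells


@pytest.fixture(scope="session")
def default_optics():
    return OpticsConfig()


@pytest.fixture(scope="session")
def noise_free_optics():
    """Zero-CV, zero-background optics: measurements equal scaled truth."""
    return OpticsConfig(cv_dna=0.0, cv_width=0.0, cv_mcm=0.0, cv_rb1=0.0,
                        background_dna=0.0, background_mcm=0.0, background_rb1=0.0)


def make_events(preset="bj_exponential", timepoint=0.0, n_cells=20_000, seed=1,
                optics=None, **overrides):
    """Simulate one measured sample (no doublets) for a preset scenario."""
    sc = get_scenario(preset, n_cells=n_cells, seed=seed, **overrides)
    cells = simulate_cells(sc, timepoint)
    return apply_measurement_model(cells, optics or OpticsConfig(), seed=seed + 1)


@pytest.fixture(scope="session")
def async_events():
    """A default asynchronous BJ-like sample reused by read-only tests."""
    return make_events(n_cells=30_000, seed=11)
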