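import numpy as np
import pandas as pd
import pytest

from exocargo import SimulationConfig, generate_truth, simulate_two_channel_slides


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def noiseless_config():
    """All stochastic and bias terms off; detection is decided by construction."""
    return SimulationConfig(noise_cv=0.0, dye_bias_amplitude=0.0, seed=7)


@pytest.fixture(scope="session")
def default_truth(default_config):
    return generate_truth(default_config)


@pytest.fixture(scope="session")
def default_slides(default_config, default_truth):
    return simulate_two_channel_slides(default_truth, default_config)


def make_slide_set(hy3, hy5, hy3_bg=None, hy5_bg=None, n_slides=1, n_reps=1):
    """Hand-built long-format slide set from per-probe channel dictionaries.

    ``hy3``/``hy5`` map probe_id -> scalar (same value on every spot) or
    -> nested {slide: [replicate values]}.
    """

    def value(table, probe, slide, rep):
        entry = table[probe]
        if isinstance(entry, dict):
            return entry[slide][rep - 1]
        return entry

    rows = []
    for probe in hy3:
        for slide in range(1, n_slides + 1):
            for rep in range(1, n_reps + 1):
                rows.append(
                    {
                        "probe_id": probe,
                        "slide": slide,
                        "replicate": rep,
                        "hy3_fg": value(hy3, probe, slide, rep),
                        "hy3_bg": value(hy3_bg, probe, slide, rep) if hy3_bg else 1.0,
                        "hy5_fg": value(hy5, probe, slide, rep),
                        "hy5_bg": value(hy5_bg, probe, slide, rep) if hy5_bg else 1.0,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
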