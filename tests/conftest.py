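import numpy as np
import pytest

from calcimech.synth import TraceSynthConfig, gen_traces


@pytest.fixture(scope="session")
def default_cohort():
    """A 200-cell cohort at the default study conditions (60 % responders,
    amplitude 10x baseline SD), shared across recovery tests."""
    cfg = TraceSynthConfig(n_cells=200, responder_frac=0.6, seed=2024)
    traces, truth = gen_traces(cfg)
    return cfg, traces, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
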