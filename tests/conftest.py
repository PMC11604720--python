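import numpy as np
import pandas as pd
import pytest

from rmapcoa import AbundanceTable, ScenarioConfig, SampleDesign, scenario_time_invariant


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_study():
    """Small time-invariant-nuisance study shared across tests."""
    cfg = ScenarioConfig(n_subjects=12, n_timepoints=3, n_taxa=72, seed=7)
    return scenario_time_invariant(cfg)


@pytest.fixture
def balanced_design():
    """10 subjects x 3 visits with one binary covariate."""
    n, m = 10, 3
    rng = np.random.default_rng(5)
    md = pd.DataFrame(
        {
            "subject": np.repeat([f"s{i}" for i in range(n)], m),
            "time": np.tile(np.arange(m), n),
            "grp": np.repeat(rng.integers(0, 2, n).astype(str), m),
        },
        index=[f"obs{i}" for i in range(n * m)],
    )
    return SampleDesign(md, subject_col="subject", time_col="time", fixed_formula="grp")


@pytest.fixture
def random_table(rng):
    return AbundanceTable(rng.integers(0, 120, size=(18, 25)).astype(float))
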