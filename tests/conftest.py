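import numpy as np
import pytest
from hypothesis import settings

from odorkin import synthetic_data as sd

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    """One study-like simulated data set shared across read-only tests."""
    cfg = sd.SimulationConfig(seed=11)
    meta, ped, peaks, blanks = sd.simulate_study(cfg)
    return {"cfg": cfg, "meta": meta, "ped": ped, "peaks": peaks, "blanks": blanks}


@pytest.fixture
def small_colony_cfg():
    """A quick-to-analyze colony for simulation-heavy tests."""
    return sd.SimulationConfig(
        n_individuals=20, n_females=16, n_groups=2,
        n_shared_mother_pairs=2, n_shared_father_pairs=3,
        n_compounds_endogenous=8, n_compounds_contaminant=3,
        seed=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
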