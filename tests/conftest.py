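import numpy as np
import pytest

from pgin.io_formats import RunConfig
from pgin.signatures import read_reference_signatures
from pgin.synthetic_cohort import SimulationSpec, simulate_cohort


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def reference():
    return read_reference_signatures()


@pytest.fixture(scope="session")
def small_bundle():
    """A compact cohort exercising every input file type."""
    spec = SimulationSpec(
        n_samples=30,
        seed=11,
        mean_variants_per_sample=60.0,
        group_counts={"EP-N": 6, "NTT-N": 8, "EP-PE": 6, "NTT-PE": 10},
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def survival_cohort():
    """Hazard-scheme cohort (n=500) for log-HR recovery checks."""
    spec = SimulationSpec(
        n_samples=500,
        seed=202,
        group_counts=None,
        mean_variants_per_sample=0.0,
        n_background_genes=0,
        n_hypoxia_genes_per_set=1,
    )
    bundle = simulate_cohort(spec)
    meta = bundle.metadata.set_index("sample_id")
    df = bundle.truth["per_sample"][["z_instability", "z_hypoxia"]].copy()
    df["ga_weeks"] = meta["ga_weeks"]
    df["pe"] = meta["pe"]
    return df, bundle.truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
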