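import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_experiment():
    """A small simulated experiment shared by read-only tests."""
    from degradomap import simgen

    cfg = simgen.SimProteomeConfig(
        n_proteins=300, n_direct_targets=3, n_shared_pharmacology=6,
        n_neosubstrates=3, seed=7,
    )
    quant, design, truth = simgen.simulate_quant_experiment(cfg)
    return cfg, quant, design, truth


def make_quant(values, proteins=None, samples=None):
    values = np.asarray(values, dtype=float)
    proteins = proteins or [f"P{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(proteins, name="protein_id"),
                        columns=samples)


def make_design(samples, arms, experiment_id="exp1"):
    return pd.DataFrame({
        "sample_id": samples, "arm": arms,
        "experiment_id": [experiment_id] * len(samples),
    })
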