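import numpy as np
import pandas as pd
import pytest

from morphshift import GenotypeSimConfig, SimulationConfig
from morphshift.simulate import simulate_counts, simulate_outgroup


def small_sim_config(seed: int = 0, **kw) -> SimulationConfig:
    defaults = dict(n_genes=600, seed=seed)
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_focal():
    """Small simulated focal dataset (counts, metadata, truth)."""
    return simulate_counts(small_sim_config())


@pytest.fixture(scope="session")
def small_outgroup():
    """Matching outgroup datasets (whole-body, tissue, metadata)."""
    return simulate_outgroup(small_sim_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def nb_counts(rng):
    """Random 120-gene x 6-library NB count table."""
    mu = np.exp(rng.normal(4, 1.3, size=120))
    r = 10.0
    counts = np.column_stack(
        [rng.negative_binomial(r, r / (r + mu * f)) for f in
         (1.0, 1.2, 0.9, 1.5, 1.0, 0.7)]
    )
    return pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(120)],
        columns=[f"s{j}" for j in range(6)],
    )
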