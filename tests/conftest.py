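import numpy as np
import pandas as pd
import pytest

from ptcatlas import SimConfig, generate_single_cell_dataset, generate_toy_fixture, log_normalize


@pytest.fixture(scope="session")
def toy():
    """Hand-auditable deterministic fixtures."""
    return generate_toy_fixture()


@pytest.fixture(scope="session")
def small_sc():
    """One small synthetic single-cell dataset shared across tests."""
    cfg = SimConfig(seed=2)
    counts, annotation, truth = generate_single_cell_dataset(cfg)
    return counts, annotation, truth


@pytest.fixture(scope="session")
def small_lognorm(small_sc):
    counts, annotation, truth = small_sc
    return log_normalize(counts), annotation, truth


@pytest.fixture()
def tiny_lognorm():
    """8 genes x 4 cells, deterministic values, for module-score oracles."""
    rng = np.random.default_rng(42)
    mat = pd.DataFrame(
        rng.gamma(2.0, 1.0, size=(8, 4)).round(3),
        index=[f"g{i}" for i in range(8)],
        columns=[f"c{i}" for i in range(4)],
    )
    return mat
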