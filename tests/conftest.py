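import numpy as np
import pandas as pd
import pytest

from cernet.config import PipelineConfig
from cernet.datatypes import ExpressionDataset
from cernet.simulate import SimulationConfig, simulate, worked_example


@pytest.fixture(scope="session")
def worked():
    """The hand-sized 11-gene fixture (dataset, interactions, ground truth)."""
    return worked_example(seed=7)


@pytest.fixture(scope="session")
def worked_cfg():
    return PipelineConfig(hyper_p=0.05, initial_decile=0.6, n_initial=1, n_perm=200)


@pytest.fixture(scope="session")
def small_sim():
    """Full generator at study scale (8/8/8 samples, 30 planted triplets)."""
    return simulate(SimulationConfig(seed=11))


def toy_dataset(n_genes: int = 5, groups=("control",) * 4 + ("case",) * 4,
                seed: int = 0) -> ExpressionDataset:
    """Independent log-normal expression for plumbing tests."""
    rng = np.random.default_rng(seed)
    samples = [f"S{i}" for i in range(len(groups))]

    def mat(prefix):
        g = 8 + rng.standard_normal((n_genes, len(samples)))
        return pd.DataFrame(2.0 ** g - 1, index=[f"{prefix}{i}" for i in range(n_genes)],
                            columns=samples)

    return ExpressionDataset(mat("Y"), mat("M"), mat("L"),
                             pd.Series(groups, index=samples))
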