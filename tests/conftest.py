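import numpy as np
import pandas as pd
import pytest

from pscpipe.expression import ExpressionStudy
from pscpipe.simulate import SimConfig, gen_expression_study


@pytest.fixture
def noiseless_study():
    """Small planted study with zero noise: exact recovery everywhere."""
    cfg = SimConfig(
        n_genes=60, n_samples_per_group=4, n_de_genes=6,
        de_log2fc=2.0, noise_sd=0.0, seed=11,
    )
    matrix, samples, truth = gen_expression_study(cfg)
    return ExpressionStudy(matrix=matrix, samples=samples), truth, cfg


@pytest.fixture
def tiny_matrix():
    return pd.DataFrame(
        {"s1": [1.0, 3.0], "s2": [2.0, 4.0]}, index=["g1", "g2"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
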