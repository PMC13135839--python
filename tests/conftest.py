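import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from dconet.containers import PROTEIN, TRANSCRIPT, ExpressionMatrix, SampleDesign
from dconet.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact planted study shared by read-only tests."""
    cfg = SimulationConfig(n_genes=300, n_proteins=100, seed=11,
                           n_tf=20, n_targets=10, frac_de=0.1, hub_degree=10)
    return simulate_study(cfg)


@pytest.fixture
def design_2x6():
    samples = [f"F{i}" for i in range(1, 7)] + [f"S{i}" for i in range(1, 7)]
    groups = pd.Series(["fertile"] * 6 + ["subfertile"] * 6, index=samples)
    return SampleDesign(groups)


@pytest.fixture
def design_2x3():
    samples = ["F1", "F2", "F3", "S1", "S2", "S3"]
    groups = pd.Series(["fertile"] * 3 + ["subfertile"] * 3, index=samples)
    return SampleDesign(groups)


def count_matrix(values, features=None, samples=None):
    values = np.asarray(values)
    features = features or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=features, columns=samples), TRANSCRIPT)


def protein_matrix(values, features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=features, columns=samples), PROTEIN)
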