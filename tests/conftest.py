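import numpy as np
import pandas as pd
import pytest

from mirhic import (
    ExpressionStudy,
    RunConfig,
    SyntheticTruth,
    TargetNetwork,
    discretize_scores,
    generate_expression,
    generate_network,
)
from mirhic.synthetic import BlockSpec


@pytest.fixture
def tiny_net() -> TargetNetwork:
    """Hand-built 6-pair network over 2 families, undiscretized."""
    df = pd.DataFrame(
        {
            "family": ["m1", "m1", "m1", "m2", "m2", "m2"],
            "gene": ["gA", "gB", "gC", "gB", "gC", "gD"],
            "context_score": [-0.9, -0.2, -0.5, -0.4, -0.7, -0.1],
        }
    )
    return TargetNetwork(df)


@pytest.fixture
def tiny_net_disc(tiny_net) -> TargetNetwork:
    return discretize_scores(tiny_net, K=3, b=3)


def small_truth(seed: int, planted: bool = True, **overrides) -> SyntheticTruth:
    """Scaled-down study conditions for fast unit tests."""
    defaults = dict(
        n_genes=400,
        n_case=20,
        n_control=20,
        blocks=tuple(
            BlockSpec(40, 0.7, 2.0 * (-1) ** i) for i in range(4)
        ),
        n_families=20,
        degree_low=10,
        degree_high=80,
        planted_degree=40,
        n_planted_targets=12,
    )
    defaults.update(overrides)
    return SyntheticTruth(seed=seed, planted=planted, **defaults)


@pytest.fixture
def small_dataset():
    truth = small_truth(7)
    return generate_expression(truth), generate_network(truth), truth


@pytest.fixture
def small_config() -> RunConfig:
    return RunConfig(R=200, seed=7, min_size=10)


def two_group_study(values: np.ndarray, n_case: int, n_control: int) -> ExpressionStudy:
    """Wrap a raw array as an ExpressionStudy (first columns are cases)."""
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    groups = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=samples
    )
    return ExpressionStudy(pd.DataFrame(values, index=genes, columns=samples), groups)
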