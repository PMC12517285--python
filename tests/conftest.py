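import numpy as np
import pytest

from pathsem.expression_io import ExpressionMatrix, GroupLabels
from pathsem.simulate import end_to_end_scenario, fixture_pathways


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{j}" for j in range(8)]
    return ExpressionMatrix(genes, samples, rng.normal(8, 1, size=(6, 8)))


@pytest.fixture
def tiny_labels(tiny_matrix) -> GroupLabels:
    return GroupLabels({s: (0 if i < 4 else 1) for i, s in enumerate(tiny_matrix.sample_ids)})


@pytest.fixture(scope="session")
def fixtures():
    return fixture_pathways()


@pytest.fixture(scope="session")
def perturbed_chain():
    return end_to_end_scenario("perturbed-chain", seed=0)


@pytest.fixture(scope="session")
def null_scenario():
    return end_to_end_scenario("null", seed=0)
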