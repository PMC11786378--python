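import numpy as np
import pandas as pd
import pytest

from genediverse import simulate
from genediverse.tensor import IsoformExpressionTensor
from genediverse.tree import SampleTree


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimConfig(seed=1, n_genes=30, n_tissues=6)


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return simulate.gen_annotation(small_config)


@pytest.fixture(scope="session")
def small_tensor(small_config, small_annotation):
    return simulate.gen_isoform_tensor(small_config, small_annotation)


@pytest.fixture()
def star_tree():
    """Four-leaf star with unit branches: uniform similarity weights."""
    return SampleTree.from_newick("(S1:1,S2:1,S3:1,S4:1);")


def make_tensor(data: dict, samples: list, gene_of: dict) -> IsoformExpressionTensor:
    matrix = pd.DataFrame.from_dict(data, orient="index", columns=samples).astype(float)
    return IsoformExpressionTensor(matrix, gene_of)


@pytest.fixture()
def two_sample_tensor():
    """One gene, two isoforms, complementary profiles in two samples."""
    return make_tensor(
        {"t1": [10.0, 0.0], "t2": [0.0, 10.0]},
        samples=["A", "B"],
        gene_of={"t1": "g1", "t2": "g1"},
    )
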