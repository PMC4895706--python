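import numpy as np
import pytest

from netcov.io import ExpressionMatrix, GeneSetCollection, GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expression():
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [0.5, -0.5, 1.5, -1.5],
            [2.0, 2.0, 0.0, 4.0],
        ]
    )
    return ExpressionMatrix(
        gene_ids=["gA", "gB", "gC"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=values,
    )


@pytest.fixture
def small_genotypes():
    values = np.array(
        [
            [0.0, 0.0, 1.0, 1.0],
            [0.0, 1.0, 2.0, 1.0],
            [0.0, np.nan, 1.0, 1.0],
        ]
    )
    return GenotypeMatrix(
        marker_ids=["m1", "m2", "m3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=values,
    )


@pytest.fixture
def small_gene_sets():
    return GeneSetCollection(
        sets={"pwA": ["gA", "gB"], "pwB": ["gB", "gC", "gX"]},
        descriptions={"pwA": "toy", "pwB": "toy"},
    )
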