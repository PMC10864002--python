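import numpy as np
import pytest

from ifnsig.core_io import ExpressionMatrix, GeneSet


@pytest.fixture
def small_counts() -> ExpressionMatrix:
    """3 genes x 2 samples, integer counts."""
    return ExpressionMatrix(
        gene_ids=["G1", "G2", "G3"],
        sample_ids=["S1", "S2"],
        values=np.array([[1.0, 4.0], [3.0, 0.0], [0.0, 2.0]]),
        layer="counts",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture
def planted_set() -> GeneSet:
    return GeneSet("planted", tuple(f"GENE{i:04d}" for i in range(1, 16)))
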