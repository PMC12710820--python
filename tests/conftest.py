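import numpy as np
import pytest

from coexcopula.ingest import CountMatrix


@pytest.fixture
def tiny_cm() -> CountMatrix:
    """4 genes x 6 cells with assorted sparsity."""
    counts = np.array(
        [
            [0, 1, 2, 0, 3, 1],
            [5, 5, 5, 5, 5, 5],
            [0, 0, 0, 0, 0, 0],
            [1, 0, 0, 2, 0, 4],
        ]
    )
    return CountMatrix(
        [f"g{i}" for i in range(4)], [f"c{j}" for j in range(6)], counts
    )


@pytest.fixture
def hvg_margin_spec() -> dict:
    """Default ZINB margins of the ground-truth generator."""
    return {"mu": 5.0, "theta": 2.0, "pi": 0.1}


@pytest.fixture
def rich_margin_spec() -> dict:
    """Near-continuous ZINB margins (~50 distinct values per gene).

    Used for recovery tests of likelihood estimators whose consistency
    assumes low discretization, so the estimator is isolated from the
    attenuation that coarse margins introduce.
    """
    return {"mu": 10.0, "theta": 3.0, "pi": 0.05}
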