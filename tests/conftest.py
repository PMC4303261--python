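import numpy as np
import pandas as pd
import pytest

from mirmod.types import ExpressionMatrix, GeneSampleModule


def expr(values, genes=None, samples=None, kind="gene") -> ExpressionMatrix:
    """Build an ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes,
                                         columns=samples), kind)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_module():
    return GeneSampleModule(module_id="M1", genes={"g0", "g1", "g2"},
                            samples={"s0", "s1", "s2", "s3"})
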