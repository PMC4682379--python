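import numpy as np
import pytest

from coremark.types import ExpressionMatrix


def expression_from_values(values, condition="normal", cancer_id="", ids=None):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    ids = ids or tuple(f"P{i:02d}" for i in range(m))
    return ExpressionMatrix(
        protein_ids=tuple(ids),
        sample_ids=tuple(f"S{j:04d}" for j in range(n)),
        values=values,
        condition=condition,
        cancer_id=cancer_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
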