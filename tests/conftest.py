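import numpy as np
import pandas as pd
import pytest

from tmmeta.normalize import ExpressionMatrix


def make_matrix(values, individuals=None, conditions=None, replicates=None, study_id="s"):
    """Build an ExpressionMatrix from a 2D array with simple metadata."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    samples = [f"smp{j}" for j in range(n)]
    meta = pd.DataFrame(
        {
            "individual": individuals or [f"I{j}" for j in range(n)],
            "condition": conditions or ["treated"] * n,
            "replicate": replicates or [1] * n,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    vals = pd.DataFrame(
        values, index=pd.Index([f"p{i}" for i in range(values.shape[0])], name="probe_id"),
        columns=samples,
    )
    return ExpressionMatrix(vals, meta, study_id=study_id)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_group_matrix(rng):
    """20 probes, 4 treated + 4 control individuals, no replicates."""
    vals = rng.normal(7, 1, size=(20, 8))
    return make_matrix(
        vals,
        individuals=[f"I{j}" for j in range(8)],
        conditions=["treated"] * 4 + ["control"] * 4,
    )
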