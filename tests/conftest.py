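import numpy as np
import pytest

from adsbench.data_model import ExpressionMatrix, SampleAnnotations
from adsbench.synthetic_data import make_fixture


def make_matrix(values, kind="logcounts", gene_prefix="g", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"{gene_prefix}{i}" for i in range(values.shape[0])],
        [f"{sample_prefix}{j}" for j in range(values.shape[1])],
        kind=kind,
    )


def make_ann(batch, group=None):
    batch = list(batch)
    group = list(group) if group is not None else batch
    return SampleAnnotations([f"s{j}" for j in range(len(batch))], batch, group)


@pytest.fixture(scope="session")
def tiny_dataset():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def small_dataset():
    return make_fixture("small")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
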