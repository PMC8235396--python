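"""Shared fixtures: tiny hand-written input files and small synthetic studies."""

import io

import numpy as np
import pandas as pd
import pytest

from pharmforest.data_io import AlterationMatrix


TOY_GCT = (
    "#1.2\n"
    "3\t2\n"
    "Name\tDescription\tA549_LUNG\tSKMEL2_SKIN\n"
    "BRAF_MUT\tna\t1\t0\n"
    "TP53_DEL\tna\t0\t1\n"
    "MYC_AMP\tna\t1\t1\n"
)

TOY_RESPONSES = (
    "Compound,A549,SKMEL2,HT29\n"
    "Erlotinib,0.91,0.85,\n"
    "Nutlin,0.40,0.55,0.62\n"
)


@pytest.fixture
def toy_gct_stream():
    return io.StringIO(TOY_GCT)


@pytest.fixture
def toy_response_stream():
    return io.StringIO(TOY_RESPONSES)


def binary_matrix(values, labels=None, cells=None) -> AlterationMatrix:
    """Build an AlterationMatrix from a plain 2-d array (cells x alterations)."""
    values = np.asarray(values)
    n, p = values.shape
    labels = labels or [f"G{j + 1:03d}_MUT" for j in range(p)]
    cells = cells or [f"CL{i + 1:03d}" for i in range(n)]
    return AlterationMatrix(pd.DataFrame(values, index=cells, columns=labels))


@pytest.fixture
def random_binary_matrix():
    def make(n=60, p=10, seed=0, prevalence=(0.2, 0.6)):
        rng = np.random.default_rng(seed)
        x = (rng.random((n, p)) < rng.uniform(*prevalence, p)).astype(np.int8)
        for j in range(p):  # clustering needs non-constant columns
            if x[:, j].std() == 0:
                x[0, j] = 1 - x[0, j]
        return binary_matrix(x)

    return make
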