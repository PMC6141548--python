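import numpy as np
import pandas as pd
import pytest

from circage import REGIONS, JunctionCountMatrix, SampleTable


@pytest.fixture()
def design32() -> SampleTable:
    """The full 8-region x 2-sex x 2-age design, one sample per cell."""
    rows = [
        (f"{r}_{s}_{a}", r, s, a)
        for r in REGIONS
        for s in ("M", "F")
        for a in (10, 20)
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "region", "sex", "age_years"])
    return SampleTable(data=df.set_index("sample_id"))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


def make_matrix(values, sample_ids, circ_ids=None) -> JunctionCountMatrix:
    values = np.asarray(values)
    if circ_ids is None:
        circ_ids = [f"chr1:{100 * i}|{100 * i + 500}:+" for i in range(values.shape[0])]
    return JunctionCountMatrix(
        counts=pd.DataFrame(values, index=circ_ids, columns=sample_ids)
    )


@pytest.fixture()
def make_matrix_fn():
    return make_matrix
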