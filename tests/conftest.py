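import numpy as np
import pytest
from hypothesis import settings

from encflda import AssociationMatrix, EntityIndex

settings.register_profile("deterministic", derandomize=True, database=None,
                          deadline=None)
settings.load_profile("deterministic")


def make_index(prefix: str, n: int, kind: str) -> EntityIndex:
    return EntityIndex(tuple(f"{prefix}{i}" for i in range(n)), kind)


_PREFIX = {"lncRNA": "L", "miRNA": "M", "disease": "D"}


def make_matrix(values, row_kind="lncRNA", col_kind="disease") -> AssociationMatrix:
    values = np.asarray(values, dtype=float)
    rows = make_index(_PREFIX[row_kind], values.shape[0], row_kind)
    cols = make_index(_PREFIX[col_kind], values.shape[1], col_kind)
    return AssociationMatrix(rows, cols, values)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
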