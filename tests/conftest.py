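import numpy as np
import pytest

from localvalidity import IncompleteDataset

# The 4-case / 4-feature worked example: x1 misses f1,f2; x2 misses f3,f4;
# x3 is complete; x4 misses f3.
TABLE2_VALUES = np.array(
    [
        [np.nan, np.nan, 1.0, 0.0],
        [1.0, 1.0, np.nan, np.nan],
        [0.0, 1.0, 1.0, 0.0],
        [1.0, 0.0, np.nan, 1.0],
    ]
)

TABLE2_CSV = (
    "U,f1,f2,f3,f4\n"
    "x1,*,*,1,0\n"
    "x2,1,1,*,*\n"
    "x3,0,1,1,0\n"
    "x4,1,0,*,1\n"
)


@pytest.fixture
def table2() -> IncompleteDataset:
    return IncompleteDataset(
        case_ids=("x1", "x2", "x3", "x4"),
        feature_names=("f1", "f2", "f3", "f4"),
        values=TABLE2_VALUES.copy(),
    )


@pytest.fixture
def table2_csv(tmp_path):
    path = tmp_path / "table2.csv"
    path.write_text(TABLE2_CSV)
    return path


@pytest.fixture
def table2_labelled() -> IncompleteDataset:
    return IncompleteDataset(
        case_ids=("x1", "x2", "x3", "x4"),
        feature_names=("f1", "f2", "f3", "f4"),
        values=TABLE2_VALUES.copy(),
        labels=np.array(["a", "b", "a", "b"]),
    )


def random_incomplete(rng, n, d, p_missing=0.3, labelled=False):
    """Random ordinal table with MCAR holes; every case keeps >=1 observed."""
    values = rng.integers(1, 5, size=(n, d)).astype(float)
    while True:
        holes = rng.random((n, d)) < p_missing
        if not holes.all(axis=1).any():
            break
    values[holes] = np.nan
    labels = None
    if labelled:
        labels = np.array([f"c{i}" for i in rng.integers(0, 2, size=n)])
    return IncompleteDataset(
        case_ids=tuple(f"x{i + 1}" for i in range(n)),
        feature_names=tuple(f"f{j + 1}" for j in range(d)),
        values=values,
        labels=labels,
    )
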