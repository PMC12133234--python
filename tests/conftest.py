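import numpy as np
import pandas as pd
import pytest

from lingvbm.ngram import Transcript
from lingvbm.synthetic import CohortConfig, simulate_cohort_table
from lingvbm.vbm import DesignMatrix
from lingvbm.volume_io import VolumeImage


@pytest.fixture(scope="session")
def cohort_table() -> pd.DataFrame:
    return simulate_cohort_table(CohortConfig(seed=11))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def ab_corpus() -> list[Transcript]:
    """Tiny deterministic corpus: one transcript 'a a b'."""
    return [Transcript("t1", ["a", "a", "b"])]


def make_volumes(data4d: np.ndarray, affine: np.ndarray | None = None):
    """Wrap an (n, x, y, z) array as a list of VolumeImage on one grid."""
    if affine is None:
        affine = np.eye(4)
    return [VolumeImage(data4d[i], affine) for i in range(data4d.shape[0])]


def make_design(x: np.ndarray, columns: list[str], tested: str) -> DesignMatrix:
    return DesignMatrix(
        matrix=np.asarray(x, dtype=float),
        columns=columns,
        participant_ids=[f"S{i:03d}" for i in range(x.shape[0])],
        tested=tested,
    )
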