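import numpy as np
import pandas as pd
import pytest

from habdiv.hill import IncidenceFrequencies


@pytest.fixture
def toy_freq() -> IncidenceFrequencies:
    """4 sampling units, phenotype incidence frequencies (4, 2, 1, 1).

    Hand-derived reference values: T=4, U=8, S_obs=4, Q1=2, Q2=1,
    Chao2 = 5.5, coverage = 0.8125, 1D = 3.3636, 2D = 32/11.
    """
    return IncidenceFrequencies(T=4, Q=np.array([4, 2, 1, 1]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_incidence_matrix(rng, T=6, S=8, p_lo=0.1, p_hi=0.9) -> np.ndarray:
    """Random binary presence matrix with at least one occurrence."""
    p = rng.uniform(p_lo, p_hi, S)
    m = (rng.random((S, T)) < p[:, None]).astype(int)
    if m.sum() == 0:
        m[0, 0] = 1
    return m


def freq_from_matrix(m: np.ndarray) -> IncidenceFrequencies:
    rows = m.sum(axis=1)
    return IncidenceFrequencies(T=m.shape[1], Q=rows[rows > 0])


@pytest.fixture
def wide_counts() -> pd.DataFrame:
    return pd.DataFrame(
        [[0, 3, 1], [2, 0, 4], [1, 1, 0]],
        index=["ph1", "ph2", "ph3"],
        columns=["s1", "s2", "s3"],
    )
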