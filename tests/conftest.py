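import numpy as np
import pandas as pd
import pytest

from epiclock.matrix import CohortMetadata, MethylationMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_matrix():
    """4 sites x 3 samples with one missing value and a detection-p aux."""
    values = pd.DataFrame(
        [
            [0.10, 0.20, 0.30],
            [0.40, np.nan, 0.60],
            [0.70, 0.80, 0.90],
            [0.25, 0.25, 0.25],
        ],
        index=["cg1", "cg2", "cg3", "cg4"],
        columns=["S1", "S2", "S3"],
    )
    aux = pd.DataFrame(
        np.full((4, 3), 0.001), index=values.index, columns=values.columns
    )
    return MethylationMatrix(values, aux)


@pytest.fixture
def tiny_meta():
    return CohortMetadata(
        pd.DataFrame(
            {
                "sample_id": ["S1", "S2", "S3"],
                "age": [25.0, 40.0, 60.0],
                "sex": ["F"] * 3,
                "cohort": ["c"] * 3,
                "pair_id": [None] * 3,
            }
        )
    )


def random_matrix(rng, n_sites=100, n_samples=50, missing_rate=0.05, with_aux=False):
    vals = rng.random((n_sites, n_samples))
    if missing_rate:
        vals = np.where(rng.random(vals.shape) < missing_rate, np.nan, vals)
    frame = pd.DataFrame(
        vals,
        index=[f"cg{i:04d}" for i in range(n_sites)],
        columns=[f"S{j:03d}" for j in range(n_samples)],
    )
    aux = None
    if with_aux:
        aux = pd.DataFrame(
            rng.random(vals.shape) * 5, index=frame.index, columns=frame.columns
        )
    return MethylationMatrix(frame, aux)
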