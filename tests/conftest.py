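import numpy as np
import pandas as pd
import pytest

from rerhythm.matrix import AbundanceMatrix


@pytest.fixture(scope="session")
def grid8() -> np.ndarray:
    """The 8-timepoint, 3-h circadian sampling grid."""
    return np.arange(0.0, 24.0, 3.0)


@pytest.fixture(scope="session")
def grid8x3(grid8) -> np.ndarray:
    """8 timepoints x 3 replicates, replicates adjacent."""
    return np.repeat(grid8, 3)


def make_matrix(values: np.ndarray, times: np.ndarray, condition="STD",
                compartment="RNA", series_ids=None, **meta) -> AbundanceMatrix:
    """Build a minimal AbundanceMatrix around a value array."""
    values = np.atleast_2d(values)
    n_series, n_samples = values.shape
    if series_ids is None:
        series_ids = [f"s{i}" for i in range(n_series)]
    reps = np.ones(n_samples, dtype=int)
    seen: dict = {}
    for i, t in enumerate(times):
        seen[t] = seen.get(t, 0) + 1
        reps[i] = seen[t]
    sample_ids = [f"{condition}_CT{t:04.1f}_r{r}" for t, r in zip(times, reps)]
    samples = pd.DataFrame(
        {"condition": condition, "ct_hours": times, "replicate": reps,
         "compartment": compartment, **meta},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return AbundanceMatrix(
        pd.DataFrame(values, index=pd.Index(series_ids, name="series_id"),
                     columns=sample_ids),
        samples,
    )


@pytest.fixture
def toy_matrix(grid8x3) -> AbundanceMatrix:
    rng = np.random.default_rng(7)
    vals = rng.integers(0, 200, size=(5, len(grid8x3))).astype(float)
    return make_matrix(vals, grid8x3)
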