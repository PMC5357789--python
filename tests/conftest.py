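import numpy as np
import pandas as pd
import pytest

from exopair import (CtDataset, generate_ct_dataset, screening_scenario,
                     validation_scenario)


@pytest.fixture(scope="session")
def screening_dataset():
    """One realization of the 20/20/20/5 screening cohort with its truth."""
    ds, truth = generate_ct_dataset(screening_scenario(seed=11))
    return ds, truth


@pytest.fixture(scope="session")
def validation_dataset():
    """One realization of the two-centre validation cohort with its truth."""
    ds, truth = generate_ct_dataset(validation_scenario(seed=7))
    return ds, truth


def make_ct_dataset(values: np.ndarray, groups: list[str],
                    mirnas: list[str] | None = None,
                    centres: list[str] | None = None) -> CtDataset:
    """Hand-build a small CtDataset from a plain array."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    samples = [f"s{i + 1}" for i in range(n)]
    mirnas = mirnas or [f"m{j + 1}" for j in range(m)]
    centres = centres or ["C1"] * n
    idx = pd.Index(samples, name="sample_id")
    return CtDataset(values=pd.DataFrame(values, index=idx, columns=mirnas),
                     groups=pd.Series(groups, index=idx, name="group"),
                     centres=pd.Series(centres, index=idx, name="centre"))
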