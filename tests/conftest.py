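import numpy as np
import pandas as pd
import pytest

from mozzage import (
    SpectraDataset,
    SplitSpec,
    SyntheticSpec,
    WavelengthGrid,
    generate_study,
    split_train_val_test,
)

#: Coarse analysis grid used throughout the suite; 216 columns keeps PLS
#: fits fast while spanning the full instrument range.
COARSE_GRID = WavelengthGrid(350.0, 2500.0, 10.0)


@pytest.fixture(scope="session")
def coarse_grid():
    return COARSE_GRID


@pytest.fixture(scope="session")
def study_ds():
    """One Study-A-sized synthetic study on the coarse grid."""
    return generate_study(SyntheticSpec(grid=COARSE_GRID, seed=11))


@pytest.fixture(scope="session")
def study_split(study_ds):
    return split_train_val_test(study_ds, SplitSpec(seed=7))


def toy_dataset(n=12, p=5, seed=0, ages=None):
    """Tiny hand-sized dataset for loader/split plumbing tests."""
    rng = np.random.default_rng(seed)
    grid = WavelengthGrid(400.0, 400.0 + 10.0 * (p - 1), 10.0)
    if ages is None:
        ages = rng.uniform(1, 20, n)
    meta = pd.DataFrame(
        {
            "study": "T",
            "species": "An. arabiensis",
            "sex": "female",
            "preservation": "fresh",
            "age_days": np.asarray(ages, dtype=float),
        }
    )
    return SpectraDataset(grid, rng.normal(size=(n, p)), meta)
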