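import numpy as np
import pandas as pd
import pytest

from driftfa import (
    ReferenceTable, SpectraSet, WavenumberGrid, preprocess_pipeline,
    simulate_dataset,
)


@pytest.fixture
def default_grid():
    return WavenumberGrid.default()


@pytest.fixture
def small_spectra():
    """3 samples on a 5-point grid with metadata."""
    grid = WavenumberGrid(np.array([800.0, 804.0, 808.0, 812.0, 816.0]))
    absorbance = np.array(
        [
            [0.10, 0.20, 0.50, 0.20, 0.10],
            [0.05, 0.15, 0.30, 0.15, 0.05],
            [0.20, 0.25, 0.40, 0.25, 0.20],
        ]
    )
    meta = pd.DataFrame(
        {"culture_type": ["monoculture", "monoculture", "polyculture"]},
        index=["s1", "s2", "s3"],
    )
    return SpectraSet(grid, absorbance, ["s1", "s2", "s3"], meta)


@pytest.fixture
def small_reference():
    return ReferenceTable(pd.Series({"s1": 1.32, "s2": 22.46, "s3": 5.0}))


@pytest.fixture(scope="session")
def combined_dataset():
    """Default two-regime synthetic dataset (n=101), seed 1."""
    return simulate_dataset(44, 57, seed=1)


@pytest.fixture(scope="session")
def processed_combined(combined_dataset):
    spectra, ref, _ = combined_dataset
    return preprocess_pipeline(spectra), ref
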