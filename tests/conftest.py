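import numpy as np
import pandas as pd
import pytest

import twinvar as tv


@pytest.fixture(scope="session")
def study_design() -> tv.CohortDesign:
    """The canonical cohort layout: 56 MZ + 21 DZ pairs, 34 MZ revisit
    pairs, 24 MZ pairs with duplicated visit-1 samples, three 96-well
    plates with 6 reference wells each."""
    return tv.generate_design(56, 21, 34, 24, seed=20260101)


@pytest.fixture(scope="session")
def small_mixed_design() -> tv.CohortDesign:
    """2 MZ + 1 DZ pairs, one revisit and one duplicated MZ pair: 10
    aliquots on 2 small plates — small enough for dense-matrix oracles."""
    return tv.generate_design(
        2, 1, 1, 1, plate_capacity=6, n_reference_wells_per_plate=0, seed=5
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def intensity_table(values, index=None, columns=None, stage="raw") -> tv.IntensityTable:
    df = pd.DataFrame(
        np.asarray(values, float),
        index=index or [f"a{i}" for i in range(len(values))],
        columns=columns or [f"ab{j}" for j in range(len(values[0]))],
    )
    return tv.IntensityTable(df, stage=stage)
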