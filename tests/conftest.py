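import logging

import numpy as np
import pandas as pd
import pytest

import pairmnar as pm

# silence the K_i = 0 warning spam in simulation-heavy tests
logging.getLogger("pairmnar").setLevel(logging.ERROR)


@pytest.fixture
def toy_subjects():
    return [
        pm.Subject("A", "control", 40.0, 1, 35.0, 200.0),
        pm.Subject("B", "lottery", 60.0, 0, 38.0, 180.0),
    ]


@pytest.fixture
def toy_dataset(toy_subjects):
    """2 subjects, 3 scheduled days, one missing report for subject B."""
    series = pd.DataFrame(
        {
            "subject_id": ["A", "A", "A", "B", "B", "B"],
            "day": [0, 1, 2, 0, 1, 2],
            "observed": [True, True, True, True, False, True],
            "weight": [200.0, 198.5, 195.0, 181.0, np.nan, 179.0],
        }
    )
    return pm.LongitudinalDataset(
        subjects=toy_subjects, series=series, schedule_length=3
    )


@pytest.fixture
def small_spec():
    return pm.ModelSpec(
        covariate_names=("sex", "time"), center_list=(), time_unit=1.0
    )


def make_table(y, X, subject_index, columns):
    """Hand-build an AnalysisTable for estimator unit tests."""
    subject_index = np.asarray(subject_index, dtype=np.intp)
    n_subj = int(subject_index.max()) + 1
    return pm.AnalysisTable(
        y=np.asarray(y, dtype=float),
        X=np.asarray(X, dtype=float),
        columns=tuple(columns),
        subject_index=subject_index,
        day=np.zeros(len(y), dtype=np.intp),
        subject_ids=tuple(f"S{i}" for i in range(n_subj)),
        K=np.bincount(subject_index, minlength=n_subj).astype(np.intp),
    )


@pytest.fixture
def pair_fixture_table():
    """3 subjects with K = (3, 2, 2): small enough for brute-force oracles."""
    rng = np.random.default_rng(42)
    subject_index = np.array([0, 0, 0, 1, 1, 2, 2])
    X = np.column_stack(
        [
            np.ones(7),                         # constant column
            rng.normal(size=7),
            np.array([0, 0, 0, 1, 1, 1, 1.0]),  # subject-level covariate
        ]
    )
    y = rng.normal(size=7)
    return make_table(y, X, subject_index, ("intercept", "x1", "x2"))
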