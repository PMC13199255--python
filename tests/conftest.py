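import numpy as np
import pandas as pd
import pytest

import twinmatch as tm
from twinmatch.cohort_io import OUTCOMES, PARTICIPANT_COLUMNS


def make_participant_rows(n, rng=None, exposed=None):
    """Small well-formed participant table for I/O and matching fixtures."""
    rng = rng or np.random.default_rng(0)
    if exposed is None:
        exposed = (np.arange(n) < max(1, n // 5)).astype(int)
    df = pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(n)],
            "exposed": exposed,
            "age": rng.uniform(45, 75, n).round(1),
            "bmi": rng.uniform(20, 35, n).round(1),
            "townsend": rng.normal(-2, 2, n).round(2),
            "ethnicity": rng.choice([1, 2, 9], n),
            "sex": rng.integers(0, 2, n),
            "smoking": rng.integers(0, 2, n),
            "diabetes": rng.integers(0, 2, n),
            "hypertension": rng.integers(0, 2, n),
            "hyperlipidemia": rng.integers(0, 2, n),
            "cardiac_disease": rng.integers(0, 2, n),
            "stroke": rng.integers(0, 2, n),
            "t1": rng.normal(925, 45, n).round(1),
        }
    )
    return df[list(PARTICIPANT_COLUMNS)]


def add_outcome_columns(df, rng=None):
    rng = rng or np.random.default_rng(1)
    out = df.copy()
    for o in OUTCOMES:
        out[f"time_{o}"] = rng.uniform(0.5, 6.0, len(df)).round(3)
        out[f"event_{o}"] = rng.integers(0, 2, len(df))
    return out


@pytest.fixture
def small_cohort_csv(tmp_path):
    df = add_outcome_columns(make_participant_rows(10))
    path = tmp_path / "cohort.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def paper_cohort():
    """Mid-size paper-calibrated synthetic cohort shared across tests."""
    cfg = tm.default_paper_config(n_total=20_000, seed=0)
    return tm.generate_cohort(cfg)


@pytest.fixture(scope="session")
def matched_paper_cohort(paper_cohort):
    cases, pool = paper_cohort.split_by_exposure()
    result = tm.match_cases(cases, pool, tm.MatchSpec(seed=0))
    return paper_cohort, result
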