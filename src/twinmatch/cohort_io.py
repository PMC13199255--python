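"""Participant-level data model and tidy-CSV input/output.

The analysis operates on two tables:

* a *participant* table — one row per participant, carrying the exposure flag
  (chronic kidney disease yes/no), the matching covariates, and the myocardial
  biomarker (native T1, ms);
* an *outcome* table in long format — one row per (participant, outcome) with
  follow-up time in years and an event indicator (0 censored, 1 event,
  2 competing event; code 2 is permitted only for cardiovascular death, where
  death from other causes competes).

On disk both live in a single wide CSV: per-outcome ``time_<outcome>`` /
``event_<outcome>`` column pairs next to the participant columns.  Booleans are
0/1, missing values are empty cells, header row mandatory.  A schema map lets
external files use different column names; the canonical names below are used
everywhere in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("twinmatch")

# ---------------------------------------------------------------------------
# canonical schema
# ---------------------------------------------------------------------------

ID_COL = "participant_id"
EXPOSURE_COL = "exposed"
BIOMARKER_COL = "t1"

#: continuous matching covariates; townsend is distributed pre-standardized
CONTINUOUS_COVARIATES = ("age", "bmi", "townsend")

#: categorical covariates matched exactly
BINARY_COVARIATES = (
    "sex",
    "smoking",
    "diabetes",
    "hypertension",
    "hyperlipidemia",
    "cardiac_disease",
    "stroke",
)
CATEGORICAL_COVARIATES = BINARY_COVARIATES + ("ethnicity",)

MATCHING_COVARIATES = CONTINUOUS_COVARIATES + CATEGORICAL_COVARIATES

#: outcomes tracked per participant; cv_death admits a competing-event code
OUTCOMES = ("all_cause_death", "cv_death", "mi", "hf", "af")
COMPETING_RISK_OUTCOMES = ("cv_death",)

#: ethnic Q-risk style category codes accepted by default
DEFAULT_ETHNICITY_CATEGORIES = frozenset(range(1, 10))

PARTICIPANT_COLUMNS = (
    (ID_COL, EXPOSURE_COL)
    + CONTINUOUS_COVARIATES
    + CATEGORICAL_COVARIATES
    + (BIOMARKER_COL,)
)


def outcome_columns() -> list[str]:
    """Wide-CSV column names for the per-outcome time/event pairs."""
    cols: list[str] = []
    for o in OUTCOMES:
        cols += [f"time_{o}", f"event_{o}"]
    return cols


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


class SchemaError(ValueError):
    """A required column is absent or the schema map is malformed."""


class ValidationError(ValueError):
    """A cell violates the data model (reports the offending row index)."""


@dataclass
class Cohort:
    """Validated cohort: participant table + long outcome table + exclusion log.

    ``participants`` is indexed by position with ``participant_id`` as a column;
    ``outcomes`` has columns (participant_id, outcome, time, event).
    ``exclusions`` records participants dropped on read, with the reason.
    """

    participants: pd.DataFrame
    outcomes: pd.DataFrame
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["participant_id", "reason"])
    )

    @property
    def n(self) -> int:
        return len(self.participants)

    def split_by_exposure(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(exposed, unexposed) participant tables."""
        p = self.participants
        return p[p[EXPOSURE_COL] == 1], p[p[EXPOSURE_COL] == 0]


@dataclass(frozen=True)
class MatchedPair:
    pair_id: int
    case_id: str
    control_id: str
    distance: float


@dataclass
class MatchResult:
    """1:1 pairing produced by the matching engine.

    ``twin_pairs`` holds the optional control–control stage; control ids are
    unique across both stages (matching is without replacement throughout).
    """

    pairs: list[MatchedPair]
    unmatched_cases: list[str]
    twin_pairs: list[MatchedPair] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def pairs_frame(self, stage: str = "case") -> pd.DataFrame:
        src = self.pairs if stage == "case" else self.twin_pairs
        return pd.DataFrame(
            [(p.pair_id, p.case_id, p.control_id, p.distance) for p in src],
            columns=["pair_id", "case_id", "control_id", "distance"],
        )


# ---------------------------------------------------------------------------
# schema maps
# ---------------------------------------------------------------------------


def load_schema(path: str | Path) -> dict[str, str]:
    """Read a YAML/JSON column map {canonical_name: file_column_name}."""
    with open(path) as fh:
        schema = yaml.safe_load(fh)
    if not isinstance(schema, Mapping):
        raise SchemaError(f"schema file {path} must contain a mapping")
    return dict(schema)


def _rename_to_canonical(df: pd.DataFrame, schema: Mapping[str, str] | None) -> pd.DataFrame:
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    return df


# ---------------------------------------------------------------------------
# reading & validation
# ---------------------------------------------------------------------------


def _check_binary(df: pd.DataFrame, col: str) -> None:
    vals = df[col].dropna()
    bad = vals[~vals.isin([0, 1])]
    if len(bad):
        raise ValidationError(
            f"column {col!r} must be 0/1; offending row index {bad.index[0]} "
            f"(value {bad.iloc[0]!r})"
        )


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    ethnicity_categories: frozenset[int] = DEFAULT_ETHNICITY_CATEGORIES,
) -> Cohort:
    """Read and validate a wide cohort CSV.

    Participants with any missing matching covariate or missing biomarker are
    excluded (complete-case construction) and listed in ``Cohort.exclusions``
    with a logged count.  Missing outcome columns are treated as censored at
    time 0 and logged.  Structural violations raise :class:`SchemaError` /
    :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    raw = _rename_to_canonical(raw, schema)

    missing_cols = [c for c in PARTICIPANT_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing required columns: {missing_cols}")

    if raw[ID_COL].duplicated().any():
        dup = raw[ID_COL][raw[ID_COL].duplicated()].iloc[0]
        raise ValidationError(f"duplicate participant_id {dup!r}")
    raw[ID_COL] = raw[ID_COL].astype(str)

    for col in (EXPOSURE_COL,) + BINARY_COVARIATES:
        _check_binary(raw, col)

    eth = raw["ethnicity"].dropna()
    bad_eth = eth[~eth.isin(list(ethnicity_categories))]
    if len(bad_eth):
        raise ValidationError(
            f"ethnicity code {bad_eth.iloc[0]!r} at row {bad_eth.index[0]} not in "
            f"declared category set"
        )

    for col, lo in (("age", 0.0), ("bmi", 0.0), (BIOMARKER_COL, 0.0)):
        vals = raw[col].dropna()
        if (vals <= lo).any():
            idx = vals[vals <= lo].index[0]
            raise ValidationError(f"column {col!r} must be > {lo}; row {idx}")

    # complete-case exclusion on matching covariates + biomarker
    needed = list(MATCHING_COVARIATES) + [BIOMARKER_COL, EXPOSURE_COL]
    incomplete = raw[needed].isna().any(axis=1)
    excl = pd.DataFrame(
        {
            "participant_id": raw.loc[incomplete, ID_COL].to_numpy(),
            "reason": "missing matching covariate or biomarker",
        }
    )
    kept = raw[~incomplete].reset_index(drop=True)
    if len(excl):
        logger.info(
            "read_cohort: excluded %d of %d participants with missing matching "
            "covariates or biomarker", len(excl), len(raw)
        )

    participants = kept[list(PARTICIPANT_COLUMNS)].copy()
    for col in (EXPOSURE_COL,) + BINARY_COVARIATES + ("ethnicity",):
        participants[col] = participants[col].astype(int)

    outcomes = _extract_outcomes(kept)
    return Cohort(participants=participants, outcomes=outcomes, exclusions=excl)


def _extract_outcomes(kept: pd.DataFrame) -> pd.DataFrame:
    records = []
    n_imputed = 0
    for o in OUTCOMES:
        tcol, ecol = f"time_{o}", f"event_{o}"
        if tcol not in kept.columns or ecol not in kept.columns:
            # absent outcome linkage: censored at 0, logged
            n_imputed += len(kept)
            t = np.zeros(len(kept))
            e = np.zeros(len(kept), dtype=int)
        else:
            t = kept[tcol].to_numpy(dtype=float)
            e_raw = kept[ecol].to_numpy()
            miss = np.isnan(t) | pd.isna(e_raw)
            n_imputed += int(miss.sum())
            t = np.where(miss, 0.0, t)
            e = np.where(miss, 0, e_raw).astype(int)
        if (t < 0).any():
            raise ValidationError(f"negative follow-up time for outcome {o}")
        if not np.isin(e, [0, 1, 2]).all():
            raise ValidationError(f"event code outside {{0,1,2}} for outcome {o}")
        if o not in COMPETING_RISK_OUTCOMES and (e == 2).any():
            idx = int(np.where(e == 2)[0][0])
            raise ValidationError(
                f"event=2 (competing) only permitted for cv_death; found on "
                f"outcome {o!r} at row {idx}"
            )
        records.append(
            pd.DataFrame(
                {
                    "participant_id": kept[ID_COL].to_numpy(),
                    "outcome": o,
                    "time": t,
                    "event": e,
                }
            )
        )
    if n_imputed:
        logger.info(
            "read_cohort: %d missing outcome records treated as censored at 0",
            n_imputed,
        )
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a :class:`Cohort` back to the wide CSV layout (round-trip safe)."""
    wide = cohort.participants.copy()
    for o in OUTCOMES:
        sub = cohort.outcomes[cohort.outcomes["outcome"] == o].set_index("participant_id")
        wide[f"time_{o}"] = sub["time"].reindex(wide[ID_COL]).to_numpy()
        wide[f"event_{o}"] = sub["event"].reindex(wide[ID_COL]).to_numpy()
    wide.to_csv(path, index=False)


def write_pairs(match_result: MatchResult, path: str | Path, stage: str = "case") -> None:
    """Write matched pairs as CSV (pair_id, case_id, control_id, distance)."""
    match_result.pairs_frame(stage=stage).to_csv(path, index=False)


def read_pairs(path: str | Path) -> list[MatchedPair]:
    df = pd.read_csv(path)
    required = {"pair_id", "case_id", "control_id", "distance"}
    if not required.issubset(df.columns):
        raise SchemaError(f"pairs file missing columns {required - set(df.columns)}")
    return [
        MatchedPair(int(r.pair_id), str(r.case_id), str(r.control_id), float(r.distance))
        for r in df.itertuples()
    ]
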