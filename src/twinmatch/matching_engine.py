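"""Virtual-twin 1:1 matching.

Each exposed case is paired with the most phenotypically similar unexposed
control: categorical covariates must agree exactly, continuous covariates are
standardized to z-scores and compared by Euclidean distance, with a per-variable
caliper (default ±1 SD on the z-scale) gating eligibility.  Matching is greedy
nearest-neighbour, 1:1 and without replacement.  A second "twin" stage pairs
each selected control with another unexposed participant from the remaining
pool under the same criteria, giving a control–control reference set.

Processing order is not prescribed by the design itself; the default here is
hardest-first (cases ordered by ascending eligible-control count) with a seeded
random tie-break, and distance ties resolved toward the lexicographically
smaller control id.  Both choices are recorded in the result metadata so runs
are reproducible and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import (
    CONTINUOUS_COVARIATES,
    CATEGORICAL_COVARIATES,
    ID_COL,
    MatchResult,
    MatchedPair,
)

#: sentinel for a control outside the caliper / exact-stratum constraints
INELIGIBLE = float("inf")


@dataclass(frozen=True)
class StandardizationParams:
    """Per-variable location/scale fitted on a declared reference sample.

    Variables flagged pre-standardized (the Townsend deprivation index is
    already a z-composite) pass through with mu=0, sigma=1.
    """

    mu: dict[str, float]
    sigma: dict[str, float]

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        cols = list(self.mu)
        z = np.empty((len(df), len(cols)))
        for j, c in enumerate(cols):
            z[:, j] = (df[c].to_numpy(dtype=float) - self.mu[c]) / self.sigma[c]
        return z

    @property
    def variables(self) -> list[str]:
        return list(self.mu)


@dataclass
class MatchSpec:
    exact_vars: list[str] = field(default_factory=lambda: list(CATEGORICAL_COVARIATES))
    continuous_vars: list[str] = field(default_factory=lambda: list(CONTINUOUS_COVARIATES))
    prestandardized: list[str] = field(default_factory=lambda: ["townsend"])
    caliper: float = 1.0
    ordering_policy: str = "hardest_first"  # or "as_given"
    standardization_reference: str = "pooled"  # or "cases"
    seed: int = 0

    def validate(self) -> None:
        if self.caliper <= 0:
            raise ValueError("caliper must be positive")
        if not self.exact_vars or not self.continuous_vars:
            raise ValueError("exact_vars and continuous_vars must be non-empty")
        if set(self.exact_vars) & set(self.continuous_vars):
            raise ValueError("exact_vars and continuous_vars must be disjoint")
        if self.ordering_policy not in ("hardest_first", "as_given"):
            raise ValueError(f"unknown ordering_policy {self.ordering_policy!r}")


def fit_standardization(
    reference: pd.DataFrame,
    continuous_vars: list[str],
    prestandardized: list[str] = (),
) -> StandardizationParams:
    """Fit z-score parameters (sample SD) on the reference sample.

    Raises on zero variance, naming the variable.  Pre-standardized variables
    get the identity transform.
    """
    mu: dict[str, float] = {}
    sigma: dict[str, float] = {}
    for v in continuous_vars:
        if v in prestandardized:
            mu[v], sigma[v] = 0.0, 1.0
            continue
        x = reference[v].to_numpy(dtype=float)
        if len(np.unique(x)) < 2:
            raise ValueError(f"variable {v!r} has zero variance in reference sample")
        mu[v] = float(x.mean())
        s = float(x.std(ddof=1))
        if s <= 0:
            raise ValueError(f"variable {v!r} has zero variance in reference sample")
        sigma[v] = s
    return StandardizationParams(mu=mu, sigma=sigma)


def pair_distance(case_z: np.ndarray, control_z: np.ndarray, caliper: float) -> float:
    """Euclidean distance on the z-scale, or INELIGIBLE if any per-variable
    absolute difference exceeds the caliper (boundary counts as eligible)."""
    case_z = np.asarray(case_z, dtype=float)
    control_z = np.asarray(control_z, dtype=float)
    if case_z.shape != control_z.shape:
        raise ValueError("z-vectors must have equal length")
    d = case_z - control_z
    if np.any(np.abs(d) > caliper):
        return INELIGIBLE
    return float(np.sqrt(np.sum(d * d)))


def _stratum_key(df: pd.DataFrame, exact_vars: list[str]) -> pd.Series:
    if len(df) == 0:
        return pd.Series([], dtype=object)
    return df[exact_vars].astype(str).agg("|".join, axis=1)


def _greedy_match(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    spec: MatchSpec,
    params: StandardizationParams,
    pair_id_start: int = 0,
) -> tuple[list[MatchedPair], list[str]]:
    """Greedy sequential nearest-neighbour assignment without replacement."""
    rng = np.random.default_rng(spec.seed)
    case_ids = cases[ID_COL].to_numpy(dtype=object)
    pool_ids = pool[ID_COL].to_numpy(dtype=object)
    case_z = params.transform(cases)
    pool_z = params.transform(pool)
    case_strata = _stratum_key(cases, spec.exact_vars).to_numpy(dtype=object)
    pool_strata = _stratum_key(pool, spec.exact_vars).to_numpy(dtype=object)

    # per-case eligibility mask over the pool
    elig: list[np.ndarray] = []
    for i in range(len(cases)):
        same = pool_strata == case_strata[i]
        within = np.all(np.abs(pool_z - case_z[i]) <= spec.caliper, axis=1)
        elig.append(same & within)

    order = np.arange(len(cases))
    if spec.ordering_policy == "hardest_first":
        counts = np.array([m.sum() for m in elig])
        jitter = rng.random(len(cases))  # seeded tie-break among equal counts
        order = np.lexsort((jitter, counts))

    used = np.zeros(len(pool), dtype=bool)
    pairs: list[MatchedPair] = []
    unmatched: list[str] = []
    next_id = pair_id_start
    for i in order:
        avail = elig[i] & ~used
        if not avail.any():
            unmatched.append(str(case_ids[i]))
            continue
        idx = np.flatnonzero(avail)
        d = np.sqrt(np.sum((pool_z[idx] - case_z[i]) ** 2, axis=1))
        best = d.min()
        tied = idx[np.isclose(d, best, rtol=0.0, atol=1e-12)]
        # deterministic distance tie-break: smallest control id
        chosen = tied[np.argsort(pool_ids[tied].astype(str))[0]]
        used[chosen] = True
        pairs.append(
            MatchedPair(next_id, str(case_ids[i]), str(pool_ids[chosen]), float(best))
        )
        next_id += 1
    return pairs, unmatched


def match_cases(cases: pd.DataFrame, control_pool: pd.DataFrame, spec: MatchSpec) -> MatchResult:
    """Stage-1 matching: exposed cases against the unexposed pool.

    Returns the pairing plus unmatched case ids; ``|pairs| + |unmatched|``
    always equals the number of cases.  Standardization is fitted on the
    combined cases + pool sample by default (``spec.standardization_reference``
    switches to case-only).
    """
    spec.validate()
    ref = (
        cases
        if spec.standardization_reference == "cases"
        else pd.concat([cases, control_pool], ignore_index=True)
    )
    params = fit_standardization(ref, spec.continuous_vars, spec.prestandardized)
    pairs, unmatched = _greedy_match(cases, control_pool, spec, params)
    return MatchResult(
        pairs=pairs,
        unmatched_cases=unmatched,
        metadata={
            "ordering_policy": spec.ordering_policy,
            "caliper": spec.caliper,
            "seed": spec.seed,
            "standardization_reference": spec.standardization_reference,
            "standardization": {"mu": params.mu, "sigma": params.sigma},
            "n_cases": len(cases),
            "n_pool": len(control_pool),
        },
    )


def twin_controls(
    matched_controls: pd.DataFrame,
    remaining_pool: pd.DataFrame,
    spec: MatchSpec,
    result: MatchResult | None = None,
) -> list[MatchedPair]:
    """Stage-2 control–control twin matching.

    The stage-1 controls play the case role against the pool of still-unused
    unexposed participants, under identical criteria.  If ``result`` is given,
    the twin pairs are stored on it and checked for control-id disjointness
    with stage 1.
    """
    spec.validate()
    used_ids = set()
    if result is not None:
        used_ids = {p.control_id for p in result.pairs} | {p.case_id for p in result.pairs}
    overlap = set(remaining_pool[ID_COL].astype(str)) & used_ids
    if overlap:
        raise ValueError(f"remaining_pool reuses stage-1 participants: {sorted(overlap)[:5]}")
    if len(remaining_pool) == 0:
        if result is not None:
            result.twin_pairs = []
        return []
    ref = pd.concat([matched_controls, remaining_pool], ignore_index=True)
    params = fit_standardization(ref, spec.continuous_vars, spec.prestandardized)
    start = len(result.pairs) if result is not None else 0
    twin_pairs, _ = _greedy_match(matched_controls, remaining_pool, spec, params, pair_id_start=start)
    if result is not None:
        result.twin_pairs = twin_pairs
    return twin_pairs
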