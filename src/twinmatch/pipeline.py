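"""End-to-end orchestration: simulate → match → twin → balance → paired → survival.

All computation lives in the stage modules; this layer wires them together,
fans the global seed out to per-stage child seeds (counter-based, so a stage
can be rerun in isolation), writes the report artifacts, and logs the
attrition ladder (eligible cases → matched pairs).  Re-running with the same
configuration and seed reproduces every artifact byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import balance_diagnostics, cohort_io, matching_engine, paired_analysis, survival_models
from .cohort_io import EXPOSURE_COL, ID_COL, OUTCOMES, Cohort, MatchResult
from .matching_engine import MatchSpec
from .synthetic_cohort import SimulationConfig, default_paper_config, generate_cohort

logger = logging.getLogger("twinmatch")

#: outcomes with fewer events than this refit with the Firth penalty
SPARSE_EVENT_THRESHOLD = 10


def child_seed(seed: int, stage: int) -> int:
    """Counter-based per-stage seed below 2^31."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    cohort_path: str | None = None            # read a cohort instead of simulating
    simulation: SimulationConfig | None = None
    match_spec: MatchSpec = field(default_factory=MatchSpec)
    twin_stage: bool = True
    truncation: float | None = None           # person-time truncation, years
    scaling: str = "within_group"             # per-SD scaling reference
    ci_level: float = 0.95

    def digest(self) -> str:
        """Hash of the analysis parameters (paths excluded, so reruns into a
        different directory keep the same configuration identity)."""
        payload = json.dumps(
            {k: str(v) for k, v in asdict(self).items()
             if k not in ("out_dir", "cohort_path")},
            sort_keys=True,
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _survival_for_group(cohort: Cohort, ids: list[str], outcome: str,
                        scaling_z: np.ndarray, id_order: list[str],
                        ci_level: float) -> dict:
    sub = cohort.outcomes[
        (cohort.outcomes["outcome"] == outcome)
        & (cohort.outcomes["participant_id"].isin(ids))
    ].set_index("participant_id").loc[ids]
    time = sub["time"].to_numpy()
    event = sub["event"].to_numpy()
    z = pd.Series(scaling_z, index=id_order).loc[ids].to_numpy()

    n_events = int((event == 1).sum())
    e_count, py = survival_models.person_time(time, event)
    entry: dict = {
        "n": len(ids),
        "n_events": n_events,
        "incidence_per_1000py": None,
        "cox": None,
        "firth": None,
        "fine_gray": None,
    }
    if py > 0:
        inc = survival_models.incidence_rate(e_count, py, ci_level)
        entry["incidence_per_1000py"] = {
            "rate": inc.rate, "ci_low": inc.ci_low, "ci_high": inc.ci_high,
        }
    if n_events == 0:
        return entry
    try:
        est = survival_models.cox_ph(time, event, z)
        entry["cox"] = asdict(est)
    except survival_models.MonotoneLikelihoodError:
        logger.warning("monotone likelihood for %s; Cox estimate unavailable", outcome)
    if n_events < SPARSE_EVENT_THRESHOLD:
        entry["firth"] = asdict(survival_models.firth_cox(time, event, z))
    if outcome in cohort_io.COMPETING_RISK_OUTCOMES:
        entry["fine_gray"] = asdict(survival_models.fine_gray(time, event, z))
    return entry


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the artifact paths and summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        stage = "cohort"
        if config.cohort_path:
            cohort = cohort_io.read_cohort(config.cohort_path)
        else:
            sim = config.simulation or default_paper_config()
            cohort = generate_cohort(sim, seed=child_seed(config.seed, 0))
            cohort_io.write_cohort(cohort, out / "cohort.csv")
        cases, pool = cohort.split_by_exposure()
        logger.info("attrition: %d participants read, %d excluded, %d eligible cases, "
                    "%d eligible controls", cohort.n + len(cohort.exclusions),
                    len(cohort.exclusions), len(cases), len(pool))

        stage = "match"
        spec = config.match_spec
        spec.seed = child_seed(config.seed, 1)
        result = matching_engine.match_cases(cases, pool, spec)
        logger.info("attrition: %d cases -> %d matched pairs (%d unmatched)",
                    len(cases), len(result.pairs), len(result.unmatched_cases))
        cohort_io.write_pairs(result, out / "pairs.csv")

        stage = "twin"
        if config.twin_stage:
            used = {p.control_id for p in result.pairs}
            matched_controls = pool[pool[ID_COL].isin(used)]
            remaining = pool[~pool[ID_COL].isin(used)]
            matching_engine.twin_controls(matched_controls, remaining, spec, result)
            logger.info("twin stage: %d of %d controls twinned",
                        len(result.twin_pairs), len(result.pairs))
            cohort_io.write_pairs(result, out / "twin_pairs.csv", stage="twin")

        stage = "balance"
        bal = balance_diagnostics.balance_table(cases, pool, result.pairs)
        bal.to_csv(out / "balance.csv", index=False)
        corr = balance_diagnostics.prepost_correlation(
            bal["p_pre"].to_numpy(), bal["p_post"].to_numpy()
        )

        stage = "paired"
        table2 = paired_analysis.paired_outcome_table(
            result.pairs, cohort.participants, cohort.outcomes, level=config.ci_level
        )
        table2.to_csv(out / "paired_diffs.csv", index=False)
        overall = paired_analysis.summarize_diffs_median(
            paired_analysis.pair_differences(result.pairs, cohort.participants).to_numpy(),
            level=config.ci_level,
        )

        stage = "survival"
        case_ids = [p.case_id for p in result.pairs]
        ctrl_ids = [p.control_id for p in result.pairs]
        all_ids = case_ids + ctrl_ids
        part = cohort.participants.set_index(ID_COL).loc[all_ids]
        grp = np.array([1] * len(case_ids) + [0] * len(ctrl_ids))
        z, scale_meta = survival_models.standardize_exposure(
            part["t1"].to_numpy(), grp,
            reference="pooled" if config.scaling == "pooled" else "within_group",
        )
        surv: dict = {"scaling": {"mode": config.scaling, "meta": str(scale_meta)},
                      "outcomes": {}}
        for o in OUTCOMES:
            surv["outcomes"][o] = {
                "exposed": _survival_for_group(cohort, case_ids, o, z, all_ids, config.ci_level),
                "control": _survival_for_group(cohort, ctrl_ids, o, z, all_ids, config.ci_level),
            }
            # effect modification: pair-stratified interaction model
            sub = cohort.outcomes[
                (cohort.outcomes["outcome"] == o)
                & (cohort.outcomes["participant_id"].isin(all_ids))
            ].set_index("participant_id").loc[all_ids]
            pair_ids = np.array([p.pair_id for p in result.pairs] * 2)
            try:
                surv["outcomes"][o]["interaction"] = survival_models.interaction_model(
                    sub["time"].to_numpy(), sub["event"].to_numpy(), z, grp, pair_ids
                )
            except (ValueError, survival_models.MonotoneLikelihoodError) as exc:
                surv["outcomes"][o]["interaction"] = {"error": str(exc)}

        meta = {
            "seed": config.seed,
            "config_hash": config.digest(),
            "n_pairs": len(result.pairs),
            "unmatched_cases": result.unmatched_cases,
            "prepost_correlation": corr,
            "overall_paired_median": {
                "median": overall.median, "iqr": [overall.iqr_low, overall.iqr_high],
                "ci": [overall.median_ci_low, overall.median_ci_high],
                "p": overall.sign_p,
            },
        }
        surv["meta"] = meta
        with open(out / "survival.json", "w") as fh:
            json.dump(surv, fh, indent=2, sort_keys=True, default=float)
        with open(out / "run_meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True, default=float)
        return {"out_dir": str(out), "meta": meta}
    except Exception as exc:
        if isinstance(exc, StageError):
            raise
        logger.error("stage %s failed: %s", stage, exc)
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
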