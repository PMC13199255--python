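"""Within-pair biomarker difference analysis.

For each matched pair the native T1 difference (case minus control) is the unit
of analysis.  The overall matched cohort is summarized by the median difference
with an exact signed-rank (Hodges–Lehmann) confidence interval; outcome-based
subgroups (pairs in which the designated member experienced a given event) are
summarized by the mean difference with a one-sample t confidence interval and
two-sided t-test against zero — the construction that reproduces the published
table arithmetic from (mean, SD, n).  Reverse-pair analysis is the same
machinery with the control in the event-defining role.  Report tables round to
the nearest integer millisecond, half away from zero; raw values are retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import BIOMARKER_COL, ID_COL, OUTCOMES, MatchedPair
from .balance_diagnostics import paired_wilcoxon

logger = logging.getLogger("twinmatch")


@dataclass
class DiffSummary:
    n: int
    mean: float | None = None
    sd: float | None = None
    df: int | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p: float | None = None
    median: float | None = None
    iqr_low: float | None = None
    iqr_high: float | None = None
    median_ci_low: float | None = None
    median_ci_high: float | None = None
    median_ci_available: bool = False
    sign_p: float | None = None
    level: float = 0.95


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (report-table convention)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def pair_differences(
    pairs: list[MatchedPair],
    participants: pd.DataFrame,
    biomarker: str = BIOMARKER_COL,
) -> pd.Series:
    """Case-minus-control biomarker difference per pair (ms), indexed by pair_id.

    Pairs with a missing biomarker in either member are dropped with a log
    entry.  The count of positive differences is logged.
    """
    ix = participants.set_index(ID_COL)[biomarker]
    vals, idx, dropped = [], [], 0
    for p in pairs:
        xc = ix.get(p.case_id, np.nan)
        x0 = ix.get(p.control_id, np.nan)
        if pd.isna(xc) or pd.isna(x0):
            dropped += 1
            continue
        vals.append(float(xc) - float(x0))
        idx.append(p.pair_id)
    if dropped:
        logger.info("pair_differences: dropped %d pairs with missing biomarker", dropped)
    d = pd.Series(vals, index=pd.Index(idx, name="pair_id"), name="difference")
    logger.info(
        "pair_differences: %d/%d pairs with positive (case > control) difference",
        int((d > 0).sum()), len(d),
    )
    return d


def t_confidence_interval(m: float, s: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """One-sample t interval m ± t_{1-a/2, n-1} * s / sqrt(n) (raw, unrounded)."""
    if n < 2:
        raise ValueError("need n >= 2 for a t interval")
    if s < 0:
        raise ValueError("SD must be non-negative")
    half = stats.t.ppf(0.5 + level / 2, n - 1) * s / math.sqrt(n)
    return (m - half, m + half)


def summarize_diffs_mean(differences: np.ndarray, level: float = 0.95) -> DiffSummary:
    """Mean/SD/t-CI/one-sample-t summary of paired differences."""
    d = np.asarray(differences, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need n >= 2")
    m = float(d.mean())
    s = float(d.std(ddof=1))
    lo, hi = t_confidence_interval(m, s, n, level)
    if s == 0:
        p = 1.0 if m == 0 else 0.0
    else:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    return DiffSummary(n=n, mean=m, sd=s, df=n - 1, ci_low=lo, ci_high=hi, p=p, level=level)


def _signed_rank_null_cdf(n: int) -> np.ndarray:
    """Exact null distribution of the signed-rank statistic W+ (no ties).

    Returns P(W+ = w) for w = 0..n(n+1)/2 via the generating-function recursion.
    """
    max_w = n * (n + 1) // 2
    p = np.zeros(max_w + 1)
    p[0] = 1.0
    for i in range(1, n + 1):
        p[i:] = 0.5 * (p[i:] + p[:-i])
        p[:i] *= 0.5
    return p


def hodges_lehmann_ci(differences: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Exact signed-rank confidence interval for the pseudomedian.

    Order the M = n(n+1)/2 Walsh averages; with k the largest integer such that
    P(W+ <= k) <= alpha/2 under the exact null, the interval is
    (W_(k+1), W_(M-k)).
    """
    d = np.sort(np.asarray(differences, dtype=float))
    n = len(d)
    if n < 6:
        raise ValueError("need n >= 6 for the signed-rank interval")
    walsh = np.sort(((d[:, None] + d[None, :]) / 2.0)[np.triu_indices(n)])
    pmf = _signed_rank_null_cdf(n)
    cdf = np.cumsum(pmf)
    alpha = 1 - level
    below = np.flatnonzero(cdf <= alpha / 2)
    # critical value C: largest c with P(W+ <= c) <= alpha/2; CI is the
    # 1-based Walsh order statistics (W_{C+1}, W_{M-C}), full range if none
    k = int(below[-1]) if len(below) else 0
    m_tot = len(walsh)
    return (float(walsh[k]), float(walsh[m_tot - 1 - k]))


def summarize_diffs_median(differences: np.ndarray, level: float = 0.95) -> DiffSummary:
    """Median/IQR summary with exact signed-rank CI and signed-rank p.

    For n < 6 the CI is flagged unavailable and point estimates are returned.
    """
    d = np.asarray(differences, dtype=float)
    n = len(d)
    if n < 1:
        raise ValueError("need n >= 1")
    med = float(np.median(d))
    q1, q3 = (float(q) for q in np.percentile(d, [25, 75]))
    sign_p = paired_wilcoxon(d).p_value
    out = DiffSummary(
        n=n, median=med, iqr_low=q1, iqr_high=q3, sign_p=sign_p, level=level
    )
    if n >= 6:
        lo, hi = hodges_lehmann_ci(d, level)
        out.median_ci_low, out.median_ci_high = lo, hi
        out.median_ci_available = True
    return out


def outcome_subset_pairs(
    pairs: list[MatchedPair],
    outcomes: pd.DataFrame,
    outcome: str,
    role: str = "case_event",
    exclude_concordant: bool = False,
) -> list[MatchedPair]:
    """Pairs in which the designated member experienced the outcome.

    role 'case_event' selects pairs whose case had event=1 for ``outcome``
    during follow-up; 'control_event' is the reverse-pair analysis.  With
    ``exclude_concordant`` pairs where both members had the event are dropped
    (discordant-pair analysis).
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    if role not in ("case_event", "control_event"):
        raise ValueError(f"unknown role {role!r}")
    sub = outcomes[outcomes["outcome"] == outcome].set_index("participant_id")["event"]
    selected = []
    for p in pairs:
        e_case = int(sub.get(p.case_id, 0)) == 1
        e_ctrl = int(sub.get(p.control_id, 0)) == 1
        designated = e_case if role == "case_event" else e_ctrl
        if not designated:
            continue
        if exclude_concordant and e_case and e_ctrl:
            continue
        selected.append(p)
    return selected


def paired_outcome_table(
    pairs: list[MatchedPair],
    participants: pd.DataFrame,
    outcomes: pd.DataFrame,
    outcome_list: tuple[str, ...] = OUTCOMES,
    level: float = 0.95,
) -> pd.DataFrame:
    """Outcome-stratified mean-difference table (report-table layout).

    One row per outcome: pair count, mean difference with t-based CI, SD and p,
    all in ms with CI bounds additionally given rounded to integer ms.
    """
    rows = []
    for o in outcome_list:
        sel = outcome_subset_pairs(pairs, outcomes, o, role="case_event")
        if len(sel) < 2:
            rows.append({"outcome": o, "n_pairs": len(sel), "mean_diff": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "sd": np.nan, "p": np.nan,
                         "ci_low_rounded": np.nan, "ci_high_rounded": np.nan})
            continue
        d = pair_differences(sel, participants).to_numpy()
        s = summarize_diffs_mean(d, level)
        rows.append({
            "outcome": o, "n_pairs": s.n, "mean_diff": s.mean,
            "ci_low": s.ci_low, "ci_high": s.ci_high, "sd": s.sd, "p": s.p,
            "ci_low_rounded": round_half_away(s.ci_low),
            "ci_high_rounded": round_half_away(s.ci_high),
        })
    return pd.DataFrame(rows)
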