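"""Covariate balance diagnostics for the matched cohort.

Standardized mean differences (SMD, reported as absolute values against the
conventional 0.1 threshold), unpaired group tests for the pre-matching
comparison (Wilcoxon rank-sum for continuous covariates, Fisher's exact test
for binaries), paired tests for the post-matching comparison (Wilcoxon
signed-rank, McNemar), and the pre/post p-value correlation diagnostic on
-log10 p (Spearman's rho and Kendall's tau; correlation coefficients are
invariant to the log base).

Degenerate inputs follow p = 1 conventions rather than raising, so balance
tables never fail on perfectly matched covariates: all-zero paired differences
and zero discordant counts both report p = 1 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import (
    BINARY_COVARIATES,
    CONTINUOUS_COVARIATES,
    ID_COL,
    MatchedPair,
)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_effective: int


@dataclass(frozen=True)
class BalanceRow:
    covariate: str
    smd_pre: float
    smd_post: float
    p_pre: float
    p_post: float
    test_pre: str
    test_post: str


# ---------------------------------------------------------------------------
# standardized mean differences
# ---------------------------------------------------------------------------


def smd_continuous(x_case: np.ndarray, x_control: np.ndarray) -> float:
    """|m1 - m0| / sqrt((s1^2 + s0^2)/2) with sample SDs; scale-invariant."""
    x1 = np.asarray(x_case, dtype=float)
    x0 = np.asarray(x_control, dtype=float)
    if len(x1) < 2 or len(x0) < 2:
        raise ValueError("each sample needs n >= 2")
    s2 = (x1.var(ddof=1) + x0.var(ddof=1)) / 2.0
    diff = abs(x1.mean() - x0.mean())
    if s2 == 0:
        if diff == 0:
            return 0.0
        raise ValueError("zero pooled variance with unequal means")
    return float(diff / np.sqrt(s2))


def smd_binary(p_case: float, p_control: float) -> float:
    """SMD for proportions: |p1 - p0| / sqrt((p1(1-p1) + p0(1-p0))/2)."""
    p1, p0 = float(p_case), float(p_control)
    if not (0 <= p1 <= 1 and 0 <= p0 <= 1):
        raise ValueError("proportions must be in [0, 1]")
    if p1 == p0:
        return 0.0
    s2 = (p1 * (1 - p1) + p0 * (1 - p0)) / 2.0
    if s2 == 0:
        raise ValueError("both proportions degenerate and unequal")
    return float(abs(p1 - p0) / np.sqrt(s2))


# ---------------------------------------------------------------------------
# paired tests
# ---------------------------------------------------------------------------


def _signed_rank_exact_p(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided sign-flip p-value for the signed-rank statistic.

    Enumerates the 2^n sign-flip distribution of W+ (midranks under ties) by
    dynamic programming on doubled ranks, and returns
    P(|W - mu| >= |w_obs - mu|) — the genuinely exact permutation p-value,
    which under ties differs from the classical tie-free tabulation.
    """
    ranks = stats.rankdata(np.abs(d))
    r2 = np.rint(2 * ranks).astype(int)     # doubled midranks are integers
    w_obs2 = int(np.rint(2 * ranks[d > 0].sum()))
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        pmf[r:] = 0.5 * (pmf[r:] + pmf[:-r])
        pmf[:r] *= 0.5
    dev = np.abs(np.arange(total + 1) - total / 2)
    p = float(pmf[dev >= abs(w_obs2 - total / 2) - 1e-9].sum())
    return ranks[d > 0].sum(), min(p, 1.0)


def paired_wilcoxon(differences: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zeros are removed first; for n <= 25 the exact sign-flip permutation
    distribution is used (tie-aware), otherwise the Normal approximation with
    tie correction.  All-zero input gives p = 1.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero; p = 1 by convention")
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank", 0)
    if len(d) <= 25:
        w, p = _signed_rank_exact_p(d)
        return TestResult(float(w), p, "wilcoxon_signed_rank_exact", len(d))
    res = stats.wilcoxon(d, zero_method="wilcox", correction=False, method="approx")
    return TestResult(float(res.statistic), float(res.pvalue),
                      "wilcoxon_signed_rank_approx", len(d))


def mcnemar(b: int, c: int) -> TestResult:
    """McNemar's test from the two discordant counts.

    Exact binomial (b ~ Bin(b+c, 1/2), two-sided) for b + c < 25; chi-square
    (b-c)^2/(b+c) without continuity correction otherwise.  b + c = 0 gives
    p = 1 with a warning.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        warnings.warn("no discordant pairs; McNemar p = 1 by convention")
        return TestResult(0.0, 1.0, "mcnemar_exact", 0)
    if n < 25:
        p = stats.binomtest(b, n, 0.5).pvalue
        return TestResult(float(b), float(min(p, 1.0)), "mcnemar_exact", n)
    chi2 = (b - c) ** 2 / n
    p = stats.chi2.sf(chi2, df=1)
    return TestResult(float(chi2), float(p), "mcnemar_chi2", n)


# ---------------------------------------------------------------------------
# unpaired group tests
# ---------------------------------------------------------------------------


def group_tests(case_sample: np.ndarray, control_sample: np.ndarray, var_type: str) -> TestResult:
    """Pre-matching group comparison.

    var_type 'continuous': two-sided Wilcoxon rank-sum (Mann-Whitney);
    var_type 'binary': Fisher's exact test on the 2x2 table of 0/1 counts.
    Degenerate 2x2 margins give p = 1.
    """
    x1 = np.asarray(case_sample)
    x0 = np.asarray(control_sample)
    if len(x1) == 0 or len(x0) == 0:
        raise ValueError("both samples must be non-empty")
    if var_type == "continuous":
        res = stats.mannwhitneyu(x1, x0, alternative="two-sided")
        return TestResult(float(res.statistic), float(res.pvalue),
                          "wilcoxon_rank_sum", len(x1) + len(x0))
    if var_type == "binary":
        a, b_ = int((x1 == 1).sum()), int((x1 == 0).sum())
        c_, d = int((x0 == 1).sum()), int((x0 == 0).sum())
        if (a + c_ == 0) or (b_ + d == 0):
            return TestResult(np.nan, 1.0, "fisher_exact", len(x1) + len(x0))
        stat, p = stats.fisher_exact([[a, b_], [c_, d]], alternative="two-sided")
        return TestResult(float(stat), float(p), "fisher_exact", len(x1) + len(x0))
    raise ValueError(f"unknown var_type {var_type!r}")


# ---------------------------------------------------------------------------
# pre/post p-value correlation
# ---------------------------------------------------------------------------


def prepost_correlation(p_pre: np.ndarray, p_post: np.ndarray) -> dict[str, float]:
    """Spearman/Kendall correlation between -log10 pre- and post-match p-values."""
    lp_pre = -np.log10(np.asarray(p_pre, dtype=float))
    lp_post = -np.log10(np.asarray(p_post, dtype=float))
    if lp_pre.shape != lp_post.shape:
        raise ValueError("p-value vectors must have equal length")
    if len(lp_pre) < 3:
        raise ValueError("need at least 3 covariates")
    if np.ptp(lp_pre) == 0 or np.ptp(lp_post) == 0:
        warnings.warn("constant -log10(p) vector; correlation undefined")
        return {"spearman_rho": np.nan, "spearman_p": np.nan,
                "kendall_tau": np.nan, "kendall_p": np.nan}
    rho, p_rho = stats.spearmanr(lp_pre, lp_post)
    tau, p_tau = stats.kendalltau(lp_pre, lp_post)
    return {"spearman_rho": float(rho), "spearman_p": float(p_rho),
            "kendall_tau": float(tau), "kendall_p": float(p_tau)}


# ---------------------------------------------------------------------------
# table builder
# ---------------------------------------------------------------------------


def balance_table(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    pairs: list[MatchedPair],
    continuous_vars: tuple[str, ...] = CONTINUOUS_COVARIATES,
    binary_vars: tuple[str, ...] = BINARY_COVARIATES,
) -> pd.DataFrame:
    """Per-covariate pre/post balance table.

    Pre-matching: all cases vs the full control pool (SMD + group test).
    Post-matching: the matched sets (SMD) with paired tests within pairs.
    """
    case_ix = cases.set_index(ID_COL)
    ctrl_ix = controls.set_index(ID_COL)
    m_case = case_ix.loc[[p.case_id for p in pairs]]
    m_ctrl = ctrl_ix.loc[[p.control_id for p in pairs]]

    rows = []
    for v in continuous_vars:
        pre = group_tests(cases[v].to_numpy(), controls[v].to_numpy(), "continuous")
        diffs = m_case[v].to_numpy() - m_ctrl[v].to_numpy()
        post = paired_wilcoxon(diffs)
        rows.append(BalanceRow(
            v,
            smd_continuous(cases[v].to_numpy(), controls[v].to_numpy()),
            smd_continuous(m_case[v].to_numpy(), m_ctrl[v].to_numpy()),
            pre.p_value, post.p_value, pre.method, post.method,
        ))
    for v in binary_vars:
        pre = group_tests(cases[v].to_numpy(), controls[v].to_numpy(), "binary")
        b = int(((m_case[v].to_numpy() == 1) & (m_ctrl[v].to_numpy() == 0)).sum())
        c = int(((m_case[v].to_numpy() == 0) & (m_ctrl[v].to_numpy() == 1)).sum())
        post = mcnemar(b, c)
        rows.append(BalanceRow(
            v,
            smd_binary(cases[v].mean(), controls[v].mean()),
            smd_binary(m_case[v].mean(), m_ctrl[v].mean()),
            pre.p_value, post.p_value, pre.method, post.method,
        ))
    return pd.DataFrame([r.__dict__ for r in rows])
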