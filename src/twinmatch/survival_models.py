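"""Time-to-event machinery for the matched-cohort analysis.

Person-time incidence with exact Poisson (Garwood) intervals, Kaplan–Meier /
Aalen–Johansen cumulative incidence and the log-rank test (via lifelines), and
a partial-likelihood engine supporting:

* Cox proportional hazards (Newton–Raphson, Efron ties, optional strata) for
  the per-1-SD biomarker hazard ratios;
* Firth-penalized Cox for sparse-event outcomes — penalized partial
  log-likelihood l(b) + 0.5*log|I(b)|, profile penalized-likelihood CI (Wald
  intervals are anti-conservative exactly in the sparse-event setting this
  method exists for), always finite even under complete separation;
* Fine–Gray subdistribution hazard regression for outcomes with a competing
  event — subjects with competing events stay in later risk sets with
  inverse-probability-of-censoring weights from the Kaplan–Meier estimate of
  the censoring distribution (pooled across groups), Breslow ties, sandwich
  (robust) standard errors with the weights treated as fixed;
* pair-stratified Cox with a biomarker-by-group interaction term.

Event coding: 0 censored, 1 event of interest, 2 competing event.

Numerical conventions: Newton–Raphson with step-halving on likelihood
decrease, gradient-norm tolerance 1e-9, at most 100 iterations; monotone
(diverging) likelihood declared at |beta| > 20 and reported as
:class:`MonotoneLikelihoodError` directing the caller to ``firth_cox``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from lifelines import AalenJohansenFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .balance_diagnostics import TestResult

_CHI2_95 = stats.chi2.ppf(0.95, 1)


class MonotoneLikelihoodError(RuntimeError):
    """Partial-likelihood maximum at infinity (e.g. complete separation).

    The maximum-likelihood hazard ratio does not exist; refit with
    :func:`firth_cox`, which is finite by construction.
    """


@dataclass(frozen=True)
class HazardEstimate:
    beta: float
    hr: float
    se: float
    ci_low: float        # HR scale
    ci_high: float       # HR scale
    p: float
    method: str
    n_events: int


@dataclass(frozen=True)
class IncidenceEstimate:
    events: int
    person_years: float
    rate: float          # per 1,000 person-years
    ci_low: float
    ci_high: float
    level: float


# ---------------------------------------------------------------------------
# person-time and incidence
# ---------------------------------------------------------------------------


def person_time(time: np.ndarray, event: np.ndarray, truncation: float | None = None) -> tuple[int, float]:
    """(number of events of interest, total person-years).

    ``truncation`` caps each follow-up time (used for curves truncated at the
    median follow-up).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event)
    if (t < 0).any():
        raise ValueError("negative follow-up time")
    if truncation is not None:
        t = np.minimum(t, truncation)
    return int((e == 1).sum()), float(t.sum())


def incidence_rate(events: int, person_years: float, level: float = 0.95) -> IncidenceEstimate:
    """Incidence per 1,000 person-years with the exact (Garwood) Poisson CI."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    alpha = 1 - level
    lo = 0.0 if events == 0 else stats.chi2.ppf(alpha / 2, 2 * events) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * events + 2) / 2
    scale = 1000.0 / person_years
    return IncidenceEstimate(
        events=int(events), person_years=float(person_years),
        rate=1000.0 * events / person_years,
        ci_low=lo * scale, ci_high=hi * scale, level=level,
    )


# ---------------------------------------------------------------------------
# curves and log-rank (lifelines-backed)
# ---------------------------------------------------------------------------


def km_cumulative_incidence(time: np.ndarray, event: np.ndarray,
                            estimator: str = "auto") -> pd.DataFrame:
    """Cumulative incidence curve for the event of interest.

    Single-event data: 1 - Kaplan-Meier survival.  When competing events
    (code 2) are present: Aalen-Johansen estimator.  ``estimator`` forces
    'km' / 'aalen_johansen' instead of 'auto' dispatch.  Returns a
    (time, cif) step-function table.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if estimator not in ("auto", "km", "aalen_johansen"):
        raise ValueError(f"unknown estimator {estimator!r}")
    use_aj = estimator == "aalen_johansen" or (estimator == "auto" and (e == 2).any())
    if use_aj:
        ajf = AalenJohansenFitter(calculate_variance=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ajf.fit(t, e, event_of_interest=1)
        cif = ajf.cumulative_density_
        return pd.DataFrame({"time": cif.index.to_numpy(dtype=float),
                             "cif": cif.iloc[:, 0].to_numpy(dtype=float)})
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "cif": 1.0 - sf.iloc[:, 0].to_numpy(dtype=float)})


def logrank_test(time_a, event_a, time_b, event_b) -> TestResult:
    """Two-group log-rank test (1 df)."""
    ta, ea = np.asarray(time_a, dtype=float), np.asarray(event_a, dtype=int)
    tb, eb = np.asarray(time_b, dtype=float), np.asarray(event_b, dtype=int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if (ea == 1).sum() + (eb == 1).sum() == 0:
        warnings.warn("no events in either group; log-rank p = 1 by convention")
        return TestResult(0.0, 1.0, "logrank", len(ta) + len(tb))
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return TestResult(float(res.test_statistic), float(res.p_value),
                      "logrank", len(ta) + len(tb))


# ---------------------------------------------------------------------------
# exposure scaling
# ---------------------------------------------------------------------------


def standardize_exposure(x: np.ndarray, group: np.ndarray | None = None,
                         reference: str = "within_group") -> tuple[np.ndarray, dict]:
    """Mean-centre and scale the biomarker to per-1-SD units.

    reference 'within_group': each level of ``group`` is scaled by its own
    sample SD (the per-SD hazard ratio is then group-specific in scale);
    'pooled': one overall mean/SD.  Returns (z, metadata with the SDs used).
    """
    x = np.asarray(x, dtype=float)
    if reference not in ("within_group", "pooled"):
        raise ValueError(f"unknown reference {reference!r}")
    if reference == "pooled" or group is None:
        sd = float(x.std(ddof=1))
        if sd <= 0:
            raise ValueError("zero SD in reference sample")
        return (x - x.mean()) / sd, {"reference": "pooled", "sd": sd}
    g = np.asarray(group)
    z = np.empty_like(x)
    sds: dict = {}
    for lev in np.unique(g):
        m = g == lev
        sd = float(x[m].std(ddof=1))
        if sd <= 0:
            raise ValueError(f"zero SD in group {lev!r}")
        z[m] = (x[m] - x[m].mean()) / sd
        sds[lev] = sd
    return z, {"reference": "within_group", "sd": sds}


# ---------------------------------------------------------------------------
# partial-likelihood engine
# ---------------------------------------------------------------------------


def _stratum_nll(beta: np.ndarray, t: np.ndarray, e: np.ndarray, X: np.ndarray,
                 ties: str) -> tuple[float, np.ndarray, np.ndarray]:
    """Negative partial log-likelihood, gradient and Hessian for one stratum.

    Arrays must be sorted by ascending time.  With no tied event times the
    Efron and Breslow likelihoods coincide and a fully vectorized path is used.
    """
    p = X.shape[1]
    eta = X @ beta
    # guard against overflow far from the optimum
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    # suffix sums over the risk sets (risk set at t_j = indices with time >= t_j)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    s2 = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1], axis=0)[::-1]

    ev = np.flatnonzero(e == 1)
    if len(ev) == 0:
        return 0.0, np.zeros(p), np.zeros((p, p))
    t_ev = t[ev]
    # first index with time >= each event time (risk-set entry point)
    first = np.searchsorted(t, t_ev, side="left")
    tied = len(np.unique(t_ev)) != len(t_ev)

    if not tied:
        S0 = s0[first]
        S1 = s1[first]
        S2 = s2[first]
        xbar = S1 / S0[:, None]
        nll = -(eta[ev].sum() - np.log(S0).sum())
        grad = -(X[ev] - xbar).sum(axis=0)
        hess = (S2 / S0[:, None, None] - xbar[:, :, None] * xbar[:, None, :]).sum(axis=0)
        return nll, grad, hess

    # tie-aware path (Efron or Breslow), looping unique event times
    nll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for tj in np.unique(t_ev):
        dj_idx = ev[t_ev == tj]
        d = len(dj_idx)
        i0 = np.searchsorted(t, tj, side="left")
        S0, S1, S2 = s0[i0], s1[i0], s2[i0]
        nll -= eta[dj_idx].sum()
        grad -= X[dj_idx].sum(axis=0)
        if ties == "breslow":
            fracs = np.zeros(d)
        else:
            fracs = np.arange(d) / d
        s0d = w[dj_idx].sum()
        s1d = (w[dj_idx, None] * X[dj_idx]).sum(axis=0)
        s2d = (w[dj_idx, None, None] * (X[dj_idx][:, :, None] * X[dj_idx][:, None, :])).sum(axis=0)
        for f in fracs:
            phi = S0 - f * s0d
            psi = S1 - f * s1d
            xi = S2 - f * s2d
            nll += math.log(phi)
            grad += psi / phi
            hess += xi / phi - np.outer(psi, psi) / phi**2
    return nll, grad, hess


def _cox_objective(beta, groups, ties):
    nll, p = 0.0, len(beta)
    grad, hess = np.zeros(p), np.zeros((p, p))
    for t, e, X in groups:
        a, b, c = _stratum_nll(beta, t, e, X, ties)
        nll += a
        grad += b
        hess += c
    return nll, grad, hess


def _split_strata(time, event, X, strata):
    """Sort within strata; returns list of (t, e, X) plus informative-event count."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    groups = []
    if strata is None:
        order = np.argsort(time, kind="stable")
        groups.append((time[order], event[order], X[order]))
    else:
        strata = np.asarray(strata)
        for s in pd.unique(strata):
            m = strata == s
            order = np.argsort(time[m], kind="stable")
            groups.append((time[m][order], event[m][order], X[m][order]))
    return groups


def _newton(groups, p, ties, tol=1e-9, max_iter=100, divergence_at=20.0):
    beta = np.zeros(p)
    nll, grad, hess = _cox_objective(beta, groups, ties)
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            raise MonotoneLikelihoodError("singular information matrix")
        # step-halving on likelihood decrease
        factor = 1.0
        for _ in range(40):
            cand = beta - factor * step
            nll_c, grad_c, hess_c = _cox_objective(cand, groups, ties)
            if nll_c <= nll + 1e-12:
                break
            factor /= 2.0
        beta, nll, grad, hess = cand, nll_c, grad_c, hess_c
        if np.abs(beta).max() > divergence_at:
            raise MonotoneLikelihoodError(
                "coefficient diverging (|beta| > 20); partial-likelihood maximum "
                "at infinity — use firth_cox"
            )
    return beta, nll, grad, hess


def _fit_cox(time, event, X, strata=None, ties="efron"):
    """Full multivariate fit; returns (beta, covariance, n_events, nll)."""
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    groups = _split_strata(time, event, X, strata)
    p = groups[0][2].shape[1]
    n_events = int(sum((g[1] == 1).sum() for g in groups))
    if n_events == 0:
        raise ValueError("no events of interest")
    beta, nll, grad, hess = _newton(groups, p, ties)
    cov = np.linalg.inv(hess)
    return beta, cov, n_events, nll


def _wald_estimate(beta, var, n_events, method, level=0.95) -> HazardEstimate:
    se = math.sqrt(var)
    zq = stats.norm.ppf(0.5 + level / 2)
    z = beta / se if se > 0 else math.inf
    return HazardEstimate(
        beta=float(beta), hr=math.exp(beta), se=se,
        ci_low=math.exp(beta - zq * se), ci_high=math.exp(beta + zq * se),
        p=float(2 * stats.norm.sf(abs(z))), method=method, n_events=n_events,
    )


def cox_ph(time, event, x, strata=None, ties: str = "efron") -> HazardEstimate:
    """Cox proportional-hazards fit for a single (standardized) covariate.

    Competing-event codes (2) are treated as censoring for the event of
    interest (cause-specific hazard).  Monotone likelihood raises
    :class:`MonotoneLikelihoodError`.
    """
    e = np.where(np.asarray(event, dtype=int) == 1, 1, 0)
    X = np.asarray(x, dtype=float).reshape(-1, 1)
    beta, cov, n_events, _ = _fit_cox(time, e, X, strata=strata, ties=ties)
    return _wald_estimate(beta[0], cov[0, 0], n_events, f"cox_{ties}")


def cox_score_test(time, event, x, strata=None) -> TestResult:
    """Score (Rao) test of beta = 0 for a single covariate, Breslow ties.

    On two-group data without tied event times this is algebraically the
    log-rank test.
    """
    e = np.where(np.asarray(event, dtype=int) == 1, 1, 0)
    X = np.asarray(x, dtype=float).reshape(-1, 1)
    groups = _split_strata(time, e, X, strata)
    _, grad, hess = _cox_objective(np.zeros(1), groups, "breslow")
    chi2 = float(grad[0] ** 2 / hess[0, 0])
    return TestResult(chi2, float(stats.chi2.sf(chi2, 1)), "cox_score", len(np.asarray(time)))


# ---------------------------------------------------------------------------
# Firth-penalized Cox
# ---------------------------------------------------------------------------


def firth_cox(time, event, x, ties: str = "efron", level: float = 0.95) -> HazardEstimate:
    """Firth-penalized Cox fit for a single covariate.

    Maximizes l(b) + 0.5*log I(b); the estimate is finite even under complete
    separation.  The CI is the profile penalized-likelihood interval and the
    p-value the penalized likelihood-ratio test against b = 0.
    """
    e = np.where(np.asarray(event, dtype=int) == 1, 1, 0)
    X = np.asarray(x, dtype=float).reshape(-1, 1)
    groups = _split_strata(time, e, X, None)
    n_events = int((e == 1).sum())
    if n_events == 0:
        raise ValueError("no events of interest")

    def pnll(b: float) -> float:
        nll, _, hess = _cox_objective(np.array([b]), groups, ties)
        info = hess[0, 0]
        if info <= 0:
            return math.inf
        return nll - 0.5 * math.log(info)

    res = optimize.minimize_scalar(pnll, bounds=(-20, 20), method="bounded",
                                   options={"xatol": 1e-10})
    bhat = float(res.x)
    pnll_hat = float(res.fun)

    # curvature of the penalized objective for a reported SE
    h = 1e-4
    d2 = (pnll(bhat + h) - 2 * pnll_hat + pnll(bhat - h)) / h**2
    se = 1.0 / math.sqrt(d2) if d2 > 0 else math.nan

    # profile penalized-likelihood CI: pnll(b) = pnll_hat + chi2_{1,level}/2
    drop = stats.chi2.ppf(level, 1) / 2.0

    def edge(sign: int) -> float:
        f = lambda b: pnll(b) - pnll_hat - drop
        lo, hi = bhat, bhat + sign * max(4 * se if se == se else 1.0, 0.5)
        for _ in range(60):
            if f(hi) > 0:
                break
            hi += sign * 1.0
            if abs(hi) > 25:
                return sign * 25.0
        a, b = sorted((lo, hi))
        return float(optimize.brentq(f, a, b, xtol=1e-8))

    ci_lo_b, ci_hi_b = edge(-1), edge(+1)
    lr = 2 * (pnll(0.0) - pnll_hat)
    p = float(stats.chi2.sf(max(lr, 0.0), 1))
    return HazardEstimate(
        beta=bhat, hr=math.exp(bhat), se=se,
        ci_low=math.exp(ci_lo_b), ci_high=math.exp(ci_hi_b),
        p=p, method="firth", n_events=n_events,
    )


def firth_penalty(information: float) -> float:
    """Firth penalty at scalar information I: 0.5 * log(I)."""
    if information <= 0:
        raise ValueError("information must be positive")
    return 0.5 * math.log(information)


# ---------------------------------------------------------------------------
# Fine-Gray subdistribution hazard
# ---------------------------------------------------------------------------


def _censoring_survival(time, event):
    """Kaplan-Meier estimate of the censoring distribution G, pooled.

    Returns a left-continuous lookup G(t-) as (times, values) step function.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, dtype=float), np.asarray(event, dtype=int) == 0)
    sf = kmf.survival_function_
    ts = sf.index.to_numpy(dtype=float)
    vs = sf.iloc[:, 0].to_numpy(dtype=float)

    def G_left(q: np.ndarray) -> np.ndarray:
        # value just before q: last step strictly below q
        idx = np.searchsorted(ts, q, side="left") - 1
        out = np.where(idx >= 0, vs[np.clip(idx, 0, None)], 1.0)
        return np.maximum(out, 1e-12)

    return G_left


def fine_gray(time, event, x, level: float = 0.95) -> HazardEstimate:
    """Fine-Gray subdistribution hazard regression (single covariate).

    Subjects with competing events (code 2) remain in later risk sets with
    weight G(t-)/G(s_i-), G the pooled Kaplan-Meier censoring-survival
    estimate.  Breslow ties; sandwich standard errors from per-subject score
    residuals (censoring weights treated as fixed).  With zero competing
    events this reduces exactly to the Cox model.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    X = np.asarray(x, dtype=float).reshape(-1, 1)
    n = len(t)
    n_events = int((e == 1).sum())
    if n_events == 0:
        raise ValueError("no primary events")

    G = _censoring_survival(t, e)
    ev_times = np.unique(t[e == 1])
    g_at_ev = G(ev_times)          # G(t_j-)
    g_at_own = G(t)                # G(s_i-)

    def weights_at(j: int) -> np.ndarray:
        tj = ev_times[j]
        w = np.zeros(n)
        at_risk = t >= tj
        w[at_risk] = 1.0
        late = (e == 2) & (t < tj)
        w[late] = g_at_ev[j] / g_at_own[late]
        return w

    def objective(beta_arr):
        beta = beta_arr[0]
        eta = np.clip(X[:, 0] * beta, -500, 500)
        ex = np.exp(eta)
        nll, grad, hess = 0.0, 0.0, 0.0
        for j, tj in enumerate(ev_times):
            w = weights_at(j)
            s0 = float(np.sum(w * ex))
            s1 = float(np.sum(w * ex * X[:, 0]))
            s2 = float(np.sum(w * ex * X[:, 0] ** 2))
            dj = np.flatnonzero((e == 1) & (t == tj))
            d = len(dj)
            nll += -eta[dj].sum() + d * math.log(s0)
            xbar = s1 / s0
            grad += -X[dj, 0].sum() + d * xbar
            hess += d * (s2 / s0 - xbar**2)
        return nll, np.array([grad]), np.array([[hess]])

    beta, nll, grad, hess = _newton_custom(objective)
    info = hess[0, 0]

    # sandwich variance from score residuals
    eta = np.clip(X[:, 0] * beta[0], -500, 500)
    ex = np.exp(eta)
    U = np.zeros(n)
    for j, tj in enumerate(ev_times):
        w = weights_at(j)
        s0 = float(np.sum(w * ex))
        xbar = float(np.sum(w * ex * X[:, 0])) / s0
        dj = np.flatnonzero((e == 1) & (t == tj))
        d = len(dj)
        U[dj] += X[dj, 0] - xbar
        U -= w * ex * (X[:, 0] - xbar) * (d / s0)
    var = float((U @ U) / info**2)
    est = _wald_estimate(beta[0], var, n_events, "fine_gray", level)
    return est


def _newton_custom(objective, tol=1e-9, max_iter=100, divergence_at=20.0):
    beta = np.zeros(1)
    nll, grad, hess = objective(beta)
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            break
        step = np.linalg.solve(hess, grad)
        factor = 1.0
        for _ in range(40):
            cand = beta - factor * step
            nll_c, grad_c, hess_c = objective(cand)
            if nll_c <= nll + 1e-12:
                break
            factor /= 2.0
        beta, nll, grad, hess = cand, nll_c, grad_c, hess_c
        if np.abs(beta).max() > divergence_at:
            raise MonotoneLikelihoodError("subdistribution coefficient diverging")
    return beta, nll, grad, hess


# ---------------------------------------------------------------------------
# pair-stratified interaction model
# ---------------------------------------------------------------------------


def interaction_model(time, event, biomarker_z, group, pair_id,
                      ties: str = "efron") -> dict[str, float]:
    """Pair-stratified Cox with biomarker main effect and biomarker-by-group term.

    Within a matched pair the group main effect is absorbed by the stratum, so
    the model is h_s(t) * exp(b1*z + b2*z*g); the Wald p for b2 tests effect
    modification by exposure.  Raises if the group indicator is constant or no
    pair contributes events.
    """
    g = np.asarray(group, dtype=float)
    if len(np.unique(g)) < 2:
        raise ValueError("group indicator is constant")
    z = np.asarray(biomarker_z, dtype=float)
    e = np.where(np.asarray(event, dtype=int) == 1, 1, 0)
    if e.sum() == 0:
        raise ValueError("no informative (event-containing) pairs")
    X = np.column_stack([z, z * g])
    beta, cov, n_events, _ = _fit_cox(time, e, X, strata=pair_id, ties=ties)
    se2 = math.sqrt(cov[1, 1])
    zstat = beta[1] / se2
    return {
        "beta_t1": float(beta[0]),
        "beta_interaction": float(beta[1]),
        "se_interaction": se2,
        "p_interaction": float(2 * stats.norm.sf(abs(zstat))),
        "n_events": n_events,
    }
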