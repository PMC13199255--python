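import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import twinmatch as tm
from twinmatch.survival_models import _fit_cox


def _ph_sample(n, beta, rate=0.15, seed=0, censor=(2.0, 8.0)):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    t = rng.exponential(1.0 / (rate * np.exp(beta * x)))
    c = rng.uniform(*censor, n)
    return np.minimum(t, c), (t <= c).astype(int), x


class TestPersonTime:
    def test_hand_arithmetic(self):
        e, py = tm.person_time([1, 2, 3], [1, 0, 0])
        assert (e, py) == (1, 6.0)

    def test_truncation_caps_follow_up(self):
        e, py = tm.person_time([1, 2, 3], [1, 0, 0], truncation=2)
        assert (e, py) == (1, 5.0)

    def test_matches_independent_sum(self, paper_cohort):
        hf = paper_cohort.outcomes[paper_cohort.outcomes["outcome"] == "hf"]
        e, py = tm.person_time(hf["time"].to_numpy(), hf["event"].to_numpy())
        assert e == int((hf["event"] == 1).sum())
        assert py == pytest.approx(float(hf["time"].sum()))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            tm.person_time([-1.0], [0])


class TestIncidenceRate:
    def test_zero_events(self):
        est = tm.incidence_rate(0, 100.0)
        assert est.rate == 0.0 and est.ci_low == 0.0 and est.ci_high > 0

    def test_garwood_interval_value(self):
        est = tm.incidence_rate(5, 1000.0)
        assert est.rate == pytest.approx(5.0)
        assert est.ci_low == pytest.approx(1.6235, abs=1e-3)
        assert est.ci_high == pytest.approx(11.668, abs=1e-3)

    @pytest.mark.parametrize("e,py", [(1, 50.0), (7, 300.0), (40, 2500.0)])
    def test_interval_contains_rate(self, e, py):
        est = tm.incidence_rate(e, py)
        assert est.ci_low <= est.rate <= est.ci_high

    def test_zero_person_years_rejected(self):
        with pytest.raises(ValueError):
            tm.incidence_rate(1, 0.0)


class TestCumulativeIncidence:
    def test_no_events_flat_zero(self):
        curve = tm.km_cumulative_incidence([1.0, 2.0, 3.0], [0, 0, 0])
        assert (curve["cif"] == 0).all()

    def test_hand_product_limit(self):
        """times {1,2,3,4}, events {1,1,0,1}: CIF = 1/4, then 1/2, then 1."""
        curve = tm.km_cumulative_incidence([1, 2, 3, 4], [1, 1, 0, 1])
        lookup = dict(zip(curve["time"], curve["cif"]))
        assert lookup[1.0] == pytest.approx(0.25)
        assert lookup[2.0] == pytest.approx(0.5)
        assert lookup[4.0] == pytest.approx(1.0)

    def test_aalen_johansen_reduces_to_km_without_competing_events(self):
        # continuous (tie-free) times: the competing-risk fitter jitters ties
        rng = np.random.default_rng(3)
        t = rng.exponential(2, 60)
        e = rng.integers(0, 2, 60)
        e[0] = 1
        km = tm.km_cumulative_incidence(t, e, estimator="km")
        # route the same data through the competing-risk estimator
        aj = tm.km_cumulative_incidence(t, e, estimator="aalen_johansen")
        km_l = km.set_index("time")["cif"]
        aj_l = aj.set_index("time")["cif"]
        common = sorted(set(km_l.index) & set(aj_l.index))
        np.testing.assert_allclose(km_l.loc[common], aj_l.loc[common], atol=1e-10)

    def test_cif_monotone_and_bounded(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(2, 200)
        e = rng.choice([0, 1, 2], 200, p=[0.3, 0.4, 0.3])
        curve = tm.km_cumulative_incidence(t, e)
        assert (np.diff(curve["cif"]) >= -1e-12).all()
        assert (curve["cif"] <= 1.0 + 1e-12).all()


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 1, 0])
        res = tm.logrank_test(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_six_subjects(self):
        """O-E hand computation: A={1+,2,4}, B={3,5+,6} (+ = censored).

        Event times 2,3,4,6; observed-in-A = 2;
        E_A = 2/5 + 1/4 + 1/3 + 0 = 59/60;
        V = 24/100 + 9/48 + 4/18 + 0 = 0.6497;
        chi2 = (2 - 59/60)^2 / 0.6497 = 1.5908.
        """
        res = tm.logrank_test([1, 2, 4], [0, 1, 1], [3, 5, 6], [1, 0, 1])
        v = 24 / 100 + 9 / 48 + 4 / 18
        assert res.statistic == pytest.approx((2 - 59 / 60) ** 2 / v, abs=1e-10)

    def test_no_events_p_one(self):
        with pytest.warns(UserWarning):
            res = tm.logrank_test([1.0, 2.0], [0, 0], [1.5], [0])
        assert res.p_value == 1.0

    def test_equals_cox_score_test_without_ties(self):
        rng = np.random.default_rng(10)
        n = 300
        g = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.2 * np.exp(0.4 * g)))
        c = rng.uniform(1, 7, n)
        T, E = np.minimum(t, c), (t <= c).astype(int)
        lr = tm.logrank_test(T[g == 1], E[g == 1], T[g == 0], E[g == 0])
        sc = tm.cox_score_test(T, E, g)
        assert sc.statistic == pytest.approx(lr.statistic, abs=1e-8)


class TestStandardizeExposure:
    def test_constant_exposure_rejected(self):
        with pytest.raises(ValueError):
            tm.standardize_exposure(np.full(10, 930.0))

    def test_unit_sd_after_scaling(self):
        rng = np.random.default_rng(0)
        x = rng.normal(900, 50, 500)
        z, meta = tm.standardize_exposure(x, reference="pooled")
        assert z.std(ddof=1) == pytest.approx(1.0)
        assert meta["sd"] == pytest.approx(x.std(ddof=1))

    def test_within_group_scaling_per_group_unit_sd(self):
        rng = np.random.default_rng(1)
        g = np.repeat([0, 1], 300)
        x = np.where(g == 1, rng.normal(930, 60, 600), rng.normal(920, 40, 600))
        z, meta = tm.standardize_exposure(x, g, reference="within_group")
        for lev in (0, 1):
            assert z[g == lev].std(ddof=1) == pytest.approx(1.0)

    def test_hr_scale_change_matches_sd_ratio(self):
        """Rescaling the covariate by c rescales beta by exactly 1/c."""
        T, E, x = _ph_sample(2000, beta=0.5, seed=6)
        b1 = tm.cox_ph(T, E, x).beta
        b2 = tm.cox_ph(T, E, x / 2.0).beta
        assert b2 == pytest.approx(2.0 * b1, rel=1e-6)


class TestCoxPH:
    def test_null_simulation_unbiased(self):
        T, E, x = _ph_sample(5000, beta=0.0, seed=1)
        est = tm.cox_ph(T, E, x)
        assert abs(est.beta) < 3 * est.se

    def test_two_group_exponential_rate_ratio_recovered(self):
        rng = np.random.default_rng(2)
        n = 10_000
        g = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.1 * np.exp(math.log(2.0) * g)))
        est = tm.cox_ph(t, np.ones(n, dtype=int), g)
        assert 1.85 <= est.hr <= 2.15

    def test_partial_likelihood_maximum_on_grid(self):
        """Returned beta beats every beta on a fine grid (8-subject fixture)."""
        T = np.array([1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        E = np.array([1, 1, 0, 1, 1, 0, 1, 0])
        x = np.array([0.5, -0.2, 1.0, 0.3, -1.0, 0.8, -0.4, 0.1])

        def nll(beta):
            # direct partial-likelihood evaluation, no ties
            ll = 0.0
            for i in np.flatnonzero(E == 1):
                risk = T >= T[i]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return -ll

        est = tm.cox_ph(T, E, x)
        grid = np.arange(-3, 3, 1e-3)
        assert nll(est.beta) <= min(nll(b) for b in grid) + 1e-9

    def test_agrees_with_lifelines(self):
        from lifelines import CoxPHFitter

        T, E, x = _ph_sample(1500, beta=0.6, seed=3)
        est = tm.cox_ph(T, E, x)
        cf = CoxPHFitter().fit(pd.DataFrame({"T": T, "E": E, "x": x}), "T", "E")
        assert est.beta == pytest.approx(float(cf.params_["x"]), abs=1e-5)
        assert est.se == pytest.approx(float(cf.standard_errors_["x"]), abs=1e-5)

    def test_efron_ties_agree_with_lifelines(self):
        from lifelines import CoxPHFitter

        T, E, x = _ph_sample(800, beta=0.5, seed=4)
        T = np.round(T, 1)  # induce heavy ties
        est = tm.cox_ph(T, E, x)
        cf = CoxPHFitter().fit(pd.DataFrame({"T": T, "E": E, "x": x}), "T", "E")
        assert est.beta == pytest.approx(float(cf.params_["x"]), abs=1e-5)

    def test_monotone_likelihood_flagged(self):
        T = np.arange(1.0, 9.0)
        E = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        x = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])
        with pytest.raises(tm.MonotoneLikelihoodError):
            tm.cox_ph(T, E, x)


class TestFirth:
    SEP = (
        np.arange(1.0, 9.0),
        np.array([1, 1, 1, 1, 0, 0, 0, 0]),
        np.array([1.0, 1, 1, 1, 0, 0, 0, 0]),
    )

    def test_finite_under_complete_separation(self):
        est = tm.firth_cox(*self.SEP)
        assert np.isfinite(est.beta) and est.hr > 1
        assert est.ci_low < est.hr < est.ci_high

    def test_large_n_agreement_with_mle(self):
        T, E, x = _ph_sample(4000, beta=0.5, seed=5)
        mle = tm.cox_ph(T, E, x)
        fir = tm.firth_cox(T, E, x)
        assert abs(fir.beta - mle.beta) < 0.01

    def test_shrinks_toward_zero_when_mle_exists(self):
        T, E, x = _ph_sample(60, beta=1.2, seed=7)
        mle = tm.cox_ph(T, E, x)
        fir = tm.firth_cox(T, E, x)
        assert abs(fir.beta) < abs(mle.beta)

    def test_penalty_definition(self):
        from twinmatch.survival_models import firth_penalty

        assert firth_penalty(4.0) == pytest.approx(0.5 * math.log(4.0))
        with pytest.raises(ValueError):
            firth_penalty(0.0)


class TestFineGray:
    def test_reduces_to_cox_without_competing_events(self):
        T, E, x = _ph_sample(600, beta=0.5, seed=8)
        cox = tm.cox_ph(T, E, x)
        fg = tm.fine_gray(T, E, x)
        assert fg.beta == pytest.approx(cox.beta, abs=1e-6)

    def test_subdistribution_beta_recovery(self):
        """Direct subdistribution simulation: true beta in the 95% CI for
        >= 90% of 50 replicates."""
        beta_true = 0.6
        p_mix = 0.45
        hits = 0
        reps = 50
        for s in range(reps):
            rng = np.random.default_rng(1000 + s)
            n = 500
            x = rng.normal(size=n)
            # P(cause 1 | x) = 1 - (1 - p_mix)^exp(beta x); conditional time
            # from the unit-exponential mixture (Fine-Gray generating model)
            p1 = 1 - (1 - p_mix) ** np.exp(beta_true * x)
            cause1 = rng.random(n) < p1
            u = rng.random(n)
            expb = np.exp(beta_true * x)
            t = np.where(
                cause1,
                -np.log(1 - (1 - (1 - u * p1) ** (1 / expb)) / p_mix),
                rng.exponential(0.8, n),
            )
            c = rng.uniform(0.5, 4.0, n)
            time = np.minimum(t, c)
            event = np.where(t <= c, np.where(cause1, 1, 2), 0)
            est = tm.fine_gray(time, event, x)
            hits += math.log(est.ci_low) <= beta_true <= math.log(est.ci_high)
        assert hits >= 0.9 * reps

    def test_all_competing_rejected(self):
        with pytest.raises(ValueError):
            tm.fine_gray([1.0, 2.0], [2, 2], [0.1, 0.2])


class TestInteractionModel:
    @staticmethod
    def _paired_sample(n_pairs, beta_exposed, beta_control, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=2 * n_pairs)
        g = np.array([1] * n_pairs + [0] * n_pairs)
        beta = np.where(g == 1, beta_exposed, beta_control)
        t = rng.exponential(1.0 / (0.3 * np.exp(beta * z)))
        c = rng.uniform(1, 5, 2 * n_pairs)
        pid = np.concatenate([np.arange(n_pairs)] * 2)
        return np.minimum(t, c), (t <= c).astype(int), z, g, pid

    def test_null_interaction_p_calibrated(self):
        """Equal effects in both groups: p<0.05 in ~5% of replicates."""
        sig = 0
        reps = 100
        for s in range(reps):
            T, E, z, g, pid = self._paired_sample(250, 0.5, 0.5, 2_000 + s)
            res = tm.interaction_model(T, E, z, g, pid)
            sig += res["p_interaction"] < 0.05
        # binomial(100, 0.05) 99.9% envelope
        assert sig <= 13

    def test_exposed_only_effect_detected(self):
        detected = 0
        reps = 20
        for s in range(reps):
            T, E, z, g, pid = self._paired_sample(500, math.log(2.0), 0.0, 3_000 + s)
            res = tm.interaction_model(T, E, z, g, pid)
            detected += res["p_interaction"] < 0.05
        assert detected > reps / 2

    def test_constant_group_rejected(self):
        T, E, z, g, pid = self._paired_sample(50, 0.3, 0.3, 1)
        with pytest.raises(ValueError, match="constant"):
            tm.interaction_model(T, E, z, np.ones_like(g), pid)

    def test_stratified_fit_matches_lifelines(self):
        from lifelines import CoxPHFitter

        T, E, z, g, pid = self._paired_sample(300, 0.6, 0.1, 11)
        res = tm.interaction_model(T, E, z, g, pid)
        df = pd.DataFrame({"T": T, "E": E, "z": z, "zg": z * g, "pid": pid})
        cf = CoxPHFitter().fit(df, "T", "E", strata=["pid"])
        assert res["beta_t1"] == pytest.approx(float(cf.params_["z"]), abs=1e-4)
        assert res["beta_interaction"] == pytest.approx(float(cf.params_["zg"]), abs=1e-4)
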