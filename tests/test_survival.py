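"""Tests for endpoints, Kaplan-Meier estimation, the Cox fitter (against
independent oracles and lifelines), the interaction analysis, and the
Schoenfeld proportionality check."""

import math

import numpy as np
import pandas as pd
import pytest

import brcalike as bl
from brcalike import study
from brcalike.survival import schoenfeld_check


def records_frame(rec, death, fup):
    return pd.DataFrame({
        "time_to_recurrence": rec, "time_to_death": death, "followup_time": fup,
    })


def breslow_loglik_by_enumeration(beta, time, event, x):
    """Independent Breslow partial likelihood: direct risk-set enumeration."""
    ll = 0.0
    for i in range(len(time)):
        if not event[i]:
            continue
        risk = [j for j in range(len(time)) if time[j] >= time[i]]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


class TestEndpoints:
    def test_recurrence_before_death(self):
        ep = bl.derive_endpoints(records_frame([2.0], [5.0], [10.0]))
        assert (ep["rfs_time"].iloc[0], ep["rfs_event"].iloc[0]) == (2.0, 1)
        assert (ep["os_time"].iloc[0], ep["os_event"].iloc[0]) == (5.0, 1)

    def test_censoring_without_events(self):
        ep = bl.derive_endpoints(records_frame([np.nan], [np.nan], [10.0]))
        assert (ep["rfs_time"].iloc[0], ep["rfs_event"].iloc[0]) == (10.0, 0)
        assert (ep["os_time"].iloc[0], ep["os_event"].iloc[0]) == (10.0, 0)

    def test_death_without_recurrence_counts_for_rfs(self):
        ep = bl.derive_endpoints(records_frame([np.nan], [3.0], [10.0]))
        assert (ep["rfs_time"].iloc[0], ep["rfs_event"].iloc[0]) == (3.0, 1)

    def test_event_after_followup_rejected(self):
        with pytest.raises(ValueError, match="after end of follow-up"):
            bl.derive_endpoints(records_frame([12.0], [np.nan], [10.0]))


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        curve, _ = bl.km_estimate(times, np.ones(4, dtype=int))
        surv = curve.set_index("time")["survival"]
        assert surv[2.0] == pytest.approx(0.5)
        assert surv[4.0] == pytest.approx(0.0)

    def test_single_censored_patient(self):
        curve, risk = bl.km_estimate([5.0], [0], risk_times=[0, 4, 5])
        assert (curve["survival"] == 1.0).all()
        assert risk["n_at_risk"].tolist() == [1, 1, 1]

    def test_hand_computed_product_limit(self):
        """Events at 1..10: S(5.5) = prod_{k=1..5} (1 - 1/(11-k)) = 0.5."""
        times = np.arange(1.0, 11.0)
        curve, risk = bl.km_estimate(times, np.ones(10, dtype=int), risk_times=[5.5])
        assert risk["survival"].iloc[0] == pytest.approx(0.5)
        expected = np.prod([1 - 1 / (11 - k) for k in range(1, 6)])
        assert risk["survival"].iloc[0] == pytest.approx(expected)


class TestReverseKM:
    def test_point_mass_censoring(self):
        times = np.full(20, 10.7)
        assert bl.reverse_km_median_followup(times, np.zeros(20, dtype=int)) == 10.7

    def test_all_events_is_not_reached(self):
        assert bl.reverse_km_median_followup([1.0, 2.0, 3.0], [1, 1, 1]) == math.inf

    def test_six_record_brute_force(self):
        """Hand-computed reverse product-limit on a mixed toy set."""
        time = np.array([2.0, 3.0, 4.0, 6.0, 8.0, 9.0])
        event = np.array([1, 0, 1, 0, 0, 1])
        # flipped indicators: censorings at 3, 6, 8 are the 'events'
        # S_c(3) = 1 - 1/5 = 0.8 ; S_c(6) = 0.8 * (1 - 1/3) = 0.5333
        # S_c(8) = 0.5333 * (1 - 1/2) = 0.2667 -> first <= 0.5 at t = 8
        assert bl.reverse_km_median_followup(time, event) == 8.0


class TestCoxFitter:
    def test_symmetric_groups_give_unit_hazard_ratio(self):
        time = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        event = np.ones(6, dtype=int)
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        fit = bl.fit_cox(time, event, x[:, None], ties="efron")
        assert fit.hr[0] == pytest.approx(1.0, abs=1e-8)

    def test_breslow_grid_search_oracle(self):
        """Toy two-event fit matches a 1-D grid maximizer of an independently
        enumerated Breslow partial likelihood."""
        time = np.array([1.0, 5.0, 2.0, 5.0])
        event = np.array([1, 0, 1, 0])
        x = np.array([1.0, 1.0, 0.0, 0.0])
        grid = np.arange(-5.0, 5.0, 1e-4)
        lls = [breslow_loglik_by_enumeration(b, time, event, x) for b in grid]
        oracle = grid[int(np.argmax(lls))]
        fit = bl.fit_cox(time, event, x[:, None], ties="breslow")
        assert fit.coef[0] == pytest.approx(oracle, abs=1e-4)

    def test_matches_lifelines_efron(self):
        from lifelines import CoxPHFitter

        cohort = bl.simulate_cohort(study.reference_survival_config(
            n_per_cell=150, seed=21))
        ep = bl.derive_endpoints(cohort)
        df = ep[["rfs_time", "rfs_event"]].copy()
        df["treat"] = (cohort["arm"] == bl.ARM_CAPECITABINE).astype(float)
        df["marker"] = (cohort["marker"] == bl.BRCA1_LIKE).astype(float)
        cph = CoxPHFitter().fit(df, duration_col="rfs_time", event_col="rfs_event")
        fit = bl.fit_cox(ep["rfs_time"], ep["rfs_event"], df[["treat", "marker"]])
        np.testing.assert_allclose(fit.coef, cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-5)

    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(22)
        n = 2000
        x = np.repeat([0.0, 1.0], n)
        t = rng.exponential(1.0 / np.where(x == 1, 0.05, 0.1))
        event = (t <= 10.0).astype(int)
        t = np.minimum(t, 10.0)
        fit = bl.fit_cox(t, event, x[:, None])
        assert 0.45 <= fit.hr[0] <= 0.55

    def test_local_optimality_audit(self):
        """Partial likelihood at the fit dominates a surrounding grid."""
        rng = np.random.default_rng(23)
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.7 * x))
        event = (t <= 2.0).astype(int)
        t = np.minimum(t, 2.0)
        for ties in ("efron", "breslow"):
            fit = bl.fit_cox(t, event, x[:, None], ties=ties)
            ll_hat = bl.cox_loglik(fit.coef, t, event, x[:, None], ties=ties)
            for db in np.arange(-0.01, 0.0101, 0.002):
                if db == 0:
                    continue
                assert ll_hat >= bl.cox_loglik(fit.coef + db, t, event,
                                               x[:, None], ties=ties)

    def test_ci_definition(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 1, 0, 1, 0])
        x = np.array([1.0, 0.0, 1.0, 0.0, 0.0, 1.0])
        fit = bl.fit_cox(time, event, x[:, None])
        assert fit.ci_lower[0] == pytest.approx(math.exp(fit.coef[0] - 1.96 * fit.se[0]))
        assert fit.ci_upper[0] == pytest.approx(math.exp(fit.coef[0] + 1.96 * fit.se[0]))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            bl.fit_cox([1.0, 2.0], [0, 0], np.array([[0.0], [1.0]]))

    def test_constant_term_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            bl.fit_cox([1.0, 2.0], [1, 1], np.array([[1.0], [1.0]]))


@pytest.fixture(scope="module")
def cohort():
    return bl.simulate_cohort(study.reference_survival_config(n_per_cell=250, seed=31))


class TestInteractionAnalysis:

    def test_stratum_hr_equals_restricted_fit(self, cohort):
        res = bl.interaction_analysis(cohort, endpoint="rfs")
        ep = bl.derive_endpoints(cohort)
        for marker_val, reported in [
            (bl.NON_BRCA1_LIKE, res.hr_treatment_marker_neg),
            (bl.BRCA1_LIKE, res.hr_treatment_marker_pos),
        ]:
            sel = (cohort["marker"] == marker_val).to_numpy()
            treat = (cohort["arm"] == bl.ARM_CAPECITABINE).astype(float).to_numpy()
            restricted = bl.fit_cox(ep["rfs_time"][sel], ep["rfs_event"][sel],
                                    treat[sel][:, None])
            assert reported == pytest.approx(restricted.hr[0], abs=1e-6)

    def test_interaction_reparameterization_identity(self, cohort):
        res = bl.interaction_analysis(cohort, endpoint="rfs")
        assert res.hr_treatment_marker_pos == pytest.approx(
            math.exp(res.fit.coef[0] + res.fit.coef[1]), abs=1e-9)

    def test_cell_table_layout(self, cohort):
        res = bl.interaction_analysis(cohort, endpoint="rfs")
        assert len(res.cell_table) == 4
        assert res.cell_table["n"].sum() == len(cohort)

    def test_empty_cell_rejected(self):
        cohort = bl.simulate_cohort(study.reference_survival_config(
            n_per_cell=50, seed=32))
        broken = cohort[~((cohort["arm"] == bl.ARM_CONTROL)
                          & (cohort["marker"] == bl.BRCA1_LIKE))]
        with pytest.raises(ValueError, match="cells"):
            bl.interaction_analysis(broken, endpoint="rfs")

    def test_adjustment_one_covariate_at_a_time(self, cohort):
        pvals = bl.adjusted_interaction_pvalues(
            cohort, endpoint="rfs", covariates=["age", "grade", "nodes"])
        assert set(pvals.index) == {"unadjusted", "age", "grade", "nodes"}
        assert ((pvals > 0) & (pvals <= 1)).all()

    def test_os_endpoint_runs(self, cohort):
        res = bl.interaction_analysis(cohort, endpoint="os")
        assert res.endpoint == "os"
        assert res.hr_treatment_marker_neg > 0


class TestSchoenfeld:
    def test_single_event_rejected(self):
        fit = bl.fit_cox([1.0, 2.0, 3.0], [1, 1, 0], np.array([[0.0], [1.0], [1.0]]))
        with pytest.raises(ValueError, match="2 events"):
            schoenfeld_check(fit, [1.0, 2.0], [1, 0], np.array([[0.0], [1.0]]))

    def test_size_under_proportional_hazards(self):
        """Rejection rate stays near the nominal 5% when PH holds."""
        rng = np.random.default_rng(33)
        rejections = 0
        n_rep = 100
        for _ in range(n_rep):
            n = 200
            x = rng.integers(0, 2, size=n).astype(float)
            t = rng.exponential(1.0 / (0.1 * np.exp(-0.5 * x)))
            event = (t <= 10.0).astype(int)
            t = np.minimum(t, 10.0)
            fit = bl.fit_cox(t, event, x[:, None])
            p = schoenfeld_check(fit, t, event, x[:, None])["p"].iloc[0]
            rejections += p < 0.05
        assert 0.01 <= rejections / n_rep <= 0.11

    def test_power_against_sign_flipping_effect(self):
        """A coefficient that reverses sign mid-study is flagged."""
        rng = np.random.default_rng(34)
        rejections = 0
        n_rep = 40
        for _ in range(n_rep):
            n = 1000
            x = rng.integers(0, 2, size=n).astype(float)
            # piecewise hazard: beta = +1.2 before t=1, -1.2 after
            h0 = 0.5
            t_flip = 1.0
            u = rng.uniform(size=n)
            h1 = h0 * np.exp(1.2 * x)
            t = -np.log(u) / h1
            late = t > t_flip
            h2 = h0 * np.exp(-1.2 * x[late])
            t[late] = t_flip + (t[late] - t_flip) * h1[late] / h2
            event = (t <= 6.0).astype(int)
            t = np.minimum(t, 6.0)
            fit = bl.fit_cox(t, event, x[:, None])
            p = schoenfeld_check(fit, t, event, x[:, None])["p"].iloc[0]
            rejections += p < 0.05
        assert rejections / n_rep > 0.8
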