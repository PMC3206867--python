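"""Demand-parameter estimation from recent-onset autopsy records."""

import dataclasses

import numpy as np
import pytest

from ebcm.curves import AgeKnots, fit_cubic_spline
from ebcm.datasets import default_model
from ebcm.fitting import (
    AlphaDemandModel,
    AutopsyRecord,
    fit_alpha,
    linear_trendline,
    recent_onset_filter,
)
from ebcm.synthetic_data import SyntheticCohortConfig, generate_autopsy_cohort


def _record(age, t=0.1, ebcm=0.5, pid=None):
    return AutopsyRecord(
        patient_id=pid or f"p{age}-{t}",
        age=age,
        time_since_diagnosis=t,
        observed_ebcm=ebcm,
    )


def _noiseless_cohort(model, alpha0, n=20, seed=3):
    rng = np.random.default_rng(seed)
    ages = rng.uniform(0.5, 19.5, n)
    gen = model.with_alpha(alpha0)
    return [
        _record(a, t=0.2, ebcm=float(np.clip(gen.excess_bcm(a).ebcm, 0, 1)), pid=f"p{i}")
        for i, a in enumerate(ages)
    ]


class TestRecentOnsetFilter:
    def test_within_cutoff_kept_beyond_dropped(self):
        records = [_record(5, t=0.5, pid="keep"), _record(6, t=2.0, pid="drop")]
        kept = recent_onset_filter(records, cutoff=0.75)
        assert [r.patient_id for r in kept] == ["keep"]

    def test_order_preserved(self):
        records = [_record(5, t=0.7, pid="b"), _record(6, t=0.1, pid="a")]
        assert [r.patient_id for r in recent_onset_filter(records)] == ["b", "a"]

    def test_default_cohort_yields_sixty_under_twenty(self, model):
        cohort = generate_autopsy_cohort(SyntheticCohortConfig(seed=0), model)
        sub = [r for r in recent_onset_filter(cohort) if r.age < 20]
        assert len(sub) == 60

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            recent_onset_filter([], cutoff=0.0)


class TestAutopsyRecord:
    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            _record(5, ebcm=1.2)

    def test_counts_must_match_fraction(self):
        with pytest.raises(ValueError, match="inconsistent"):
            AutopsyRecord(
                patient_id="x",
                age=5,
                time_since_diagnosis=0.1,
                observed_ebcm=0.5,
                islets_insulin_deficient=9,
                islets_total=10,
            )


class TestFitAlpha:
    def test_noiseless_records_recover_alpha_exactly(self, model):
        records = _noiseless_cohort(model, alpha0=300.0)
        est = fit_alpha(records, model, method="wls")
        assert est.alpha_hat == pytest.approx(300.0, rel=1e-6)
        assert est.ci_low <= est.alpha_hat <= est.ci_high

    def test_synthetic_cohort_recovery_within_five_percent(self, model):
        cohort = generate_autopsy_cohort(SyntheticCohortConfig(seed=42), model)
        est = fit_alpha(cohort, model, method="wls")
        assert est.n_used == 60
        assert est.alpha_hat == pytest.approx(499.0, rel=0.05)

    def test_single_age_unidentifiable(self, model):
        records = [_record(10.0, pid=f"p{i}", ebcm=0.5 + 0.01 * i) for i in range(5)]
        with pytest.raises(ValueError, match="identifiable"):
            fit_alpha(records, model)

    def test_too_few_records_rejected(self, model):
        with pytest.raises(ValueError, match=">=3"):
            fit_alpha([_record(5), _record(10)], model)

    def test_scale_equivariance(self, model):
        # scaling the BCM curve by c rescales alpha_hat by c, residuals unchanged
        c = 3.0
        records = _noiseless_cohort(model, alpha0=499.0)
        knots = model.bcm_curve.knots
        scaled_bcm = fit_cubic_spline(AgeKnots(knots.ages, knots.values * c))
        base = AlphaDemandModel(records, model.weight_curve, model.bcm_curve).fit()
        scaled = AlphaDemandModel(records, model.weight_curve, scaled_bcm).fit()
        assert scaled.alpha_hat == pytest.approx(c * base.alpha_hat, rel=1e-9)
        assert np.allclose(scaled.resid, base.resid, atol=1e-9)

    def test_wls_and_mcmc_agree_on_well_conditioned_data(self, model):
        cohort = generate_autopsy_cohort(SyntheticCohortConfig(seed=5), model)
        wls = fit_alpha(cohort, model, method="wls")
        mcmc = fit_alpha(cohort, model, method="mcmc", seed=5)
        ci_width = wls.ci_high - wls.ci_low
        assert abs(mcmc.alpha_hat - wls.alpha_hat) < ci_width
        assert mcmc.ci_low < wls.alpha_hat < mcmc.ci_high

    @pytest.mark.parametrize("alpha0", [300.0, 499.0, 700.0])
    def test_interval_coverage_across_replicates(self, model, alpha0):
        covered = 0
        n_rep = 30
        for rep in range(n_rep):
            cfg = SyntheticCohortConfig(
                n_patients=60, n_recent_onset_under20=60, seed=10_000 + rep
            )
            cohort = generate_autopsy_cohort(cfg, model.with_alpha(alpha0))
            est = fit_alpha(cohort, model)
            covered += est.ci_low <= alpha0 <= est.ci_high
        assert covered / n_rep >= 0.9

    def test_bias_shrinks_with_noise(self, model):
        mean_abs_err = []
        for sd in (0.16, 0.08, 0.02):
            errs = []
            for rep in range(40):
                cfg = SyntheticCohortConfig(
                    n_patients=60,
                    n_recent_onset_under20=60,
                    ebcm_noise_sd=sd,
                    seed=20_000 + rep,
                )
                cohort = generate_autopsy_cohort(cfg, model)
                errs.append(abs(fit_alpha(cohort, model).alpha_hat - 499.0))
            mean_abs_err.append(np.mean(errs))
        assert mean_abs_err[0] > mean_abs_err[1] > mean_abs_err[2]


class TestLinearTrendline:
    def test_two_point_slope(self):
        records = [_record(0.0, ebcm=0.8, pid="a"), _record(20.0, ebcm=0.4, pid="b")]
        slope, intercept = linear_trendline(records)
        assert slope == pytest.approx(-0.02)
        assert intercept == pytest.approx(0.8)

    def test_constant_ebcm_gives_zero_slope(self):
        records = [_record(a, ebcm=0.6, pid=f"p{a}") for a in (1.0, 5.0, 9.0)]
        slope, _ = linear_trendline(records)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        ages = rng.uniform(0, 25, 50)
        obs = np.clip(rng.uniform(0.2, 0.9, 50), 0, 1)
        records = [
            _record(float(a), ebcm=float(o), pid=f"p{i}")
            for i, (a, o) in enumerate(zip(ages, obs))
        ]
        slope, intercept = linear_trendline(records)
        # closed-form normal equations
        xbar, ybar = ages.mean(), obs.mean()
        slope_ref = float(((ages - xbar) @ (obs - ybar)) / ((ages - xbar) @ (ages - xbar)))
        assert slope == pytest.approx(slope_ref, abs=1e-10)
        assert intercept == pytest.approx(ybar - slope_ref * xbar, abs=1e-10)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            linear_trendline([_record(5.0, pid="a"), _record(5.0, pid="b")])
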