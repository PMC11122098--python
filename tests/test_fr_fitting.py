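"""Likelihood, MLE fitting, model selection and bootstrap machinery."""

import math

import numpy as np
import pytest

from frfit import (
    FitError,
    FRModelSpec,
    FRParameters,
    PredationTrial,
    TrialSet,
    bootstrap_ci,
    fit_fr,
    neg_log_likelihood,
    select_model,
    wald_stats,
)


class TestWaldStats:
    def test_null_estimate(self):
        z, p = wald_stats(0.0, 1.0)
        assert z == 0.0 and p == 1.0

    def test_borderline_significance(self):
        _, p = wald_stats(1.959964, 1.0)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_stats(1.0, 0.0)


class TestNegLogLikelihood:
    def test_single_trial_closed_form(self):
        # holling2 with h=0, a=0.5, N=2, T=1 predicts exactly 1 eaten of 2
        spec = FRModelSpec("holling2", FRParameters(a=0.5, h=0.0, T=1.0))
        ts = TrialSet([PredationTrial(n0=2, ne=1)])
        # -log C(2,1) 0.5 * 0.5 = -log(1/2)
        assert neg_log_likelihood(spec, ts) == pytest.approx(math.log(2), abs=1e-12)

    def test_zero_attack_boundary_clipped(self):
        spec = FRModelSpec("rogers2", FRParameters(a=0.0, h=0.1, T=1.0))
        ts = TrialSet([PredationTrial(n0=5, ne=0)])
        assert neg_log_likelihood(spec, ts) == pytest.approx(0.0, abs=1e-6)

    def test_additivity_over_trials(self, make_experiment, noap2_params):
        ts = make_experiment(seed=21)
        spec = FRModelSpec("rogers2", noap2_params)
        total = neg_log_likelihood(spec, ts)
        per_trial = sum(
            neg_log_likelihood(spec, TrialSet([tr])) for tr in ts
        )
        assert total == pytest.approx(per_trial, rel=1e-12)

    def test_invalid_parameters_give_inf_not_exception(self, make_experiment):
        ts = make_experiment(seed=21)
        spec = FRModelSpec("rogers2", FRParameters(a=-1.0, h=0.01, T=1.0))
        assert neg_log_likelihood(spec, ts) == float("inf")

    def test_infinite_attack_rate_limit_stays_finite(self, make_experiment):
        # b N0^q overflows: the limiting prediction is "all prey eaten that
        # handling permits", and probability clipping keeps the NLL finite
        ts = make_experiment(seed=21)
        spec = FRModelSpec("flexq", FRParameters(b=1.0, q=500.0, h=0.01, T=1.0))
        val = neg_log_likelihood(spec, ts)
        assert np.isfinite(val) and val > 1e3


class TestFitFr:
    def test_recovers_generating_parameters(self, make_experiment, noap2_params):
        ts = make_experiment(reps=60, seed=8)
        fit = fit_fr(ts, "rogers2")
        assert fit.converged
        assert fit.estimates["a"] == pytest.approx(noap2_params.a, rel=0.15)
        assert fit.estimates["h"] == pytest.approx(noap2_params.h, rel=0.25)
        # internal consistency of the reported surfaces
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik, abs=1e-12)
        assert fit.mfr == pytest.approx(1.0 / (fit.estimates["h"] * 1.0))
        spec = FRModelSpec(
            "rogers2",
            FRParameters(a=fit.estimates["a"], h=fit.estimates["h"], T=1.0),
        )
        assert -fit.loglik == pytest.approx(neg_log_likelihood(spec, ts), abs=1e-6)

    def test_fix_q_zero_reports_type_ii(self, make_experiment):
        fit = fit_fr(make_experiment(seed=4), "flexq", fix_q=0.0)
        assert fit.family == "rogers2"
        assert set(fit.estimates) == {"a", "h"}

    def test_starting_handling_time_is_reciprocal_fmax(self):
        trials = [
            PredationTrial(n0=n0, ne=ne, replicate=str(i))
            for i, (n0, ne) in enumerate(
                [(5, 2), (10, 5), (25, 15), (50, 30), (80, 40), (80, 40)]
            )
        ]
        fit = fit_fr(TrialSet(trials), "rogers2")
        assert fit.starts_used[0]["h"] == pytest.approx(1 / 40)
        assert fit.starts_used[0]["a"] == 1.0

    def test_deterministic_given_data_and_seed(self, make_experiment):
        ts = make_experiment(seed=14)
        f1 = fit_fr(ts, "rogers2", seed=0)
        f2 = fit_fr(ts, "rogers2", seed=0)
        assert f1.estimates == f2.estimates
        assert f1.se == f2.se
        assert f1.loglik == f2.loglik

    def test_flexq_needs_three_densities(self):
        trials = [
            PredationTrial(n0=n0, ne=1, replicate=str(i))
            for i, n0 in enumerate([5, 5, 50, 50])
        ]
        with pytest.raises(FitError):
            fit_fr(TrialSet(trials), "flexq")

    def test_nested_flexible_fit_attains_fixed_likelihood(self, make_experiment):
        ts = make_experiment(seed=33)
        flex = fit_fr(ts, "flexq")
        fixed = fit_fr(ts, "flexq", fix_q=0.0)
        assert flex.loglik >= fixed.loglik - 1e-6


class TestSelectModel:
    def test_type_ii_truth_selects_type_ii(self, make_experiment, noap2_params):
        ts = make_experiment(reps=20, seed=71)
        sel = select_model(ts, seed=0)
        assert sel.chosen == "rogers2"
        assert sel.final is sel.fits["rogers2"]
        assert sel.evidence

    def test_generalized_truth_selects_flexq(self, make_experiment):
        ts = make_experiment(
            family="flexq",
            params=FRParameters(b=0.0028, q=2.1645, h=0.0228, T=1.0),
            reps=20,
            seed=72,
        )
        sel = select_model(ts, seed=0)
        assert sel.chosen == "flexq"
        assert "hassell3" in sel.fits  # step 3 ran
        assert sel.fits["flexq"].aic < sel.fits["hassell3"].aic

    def test_density_independent_noise_yields_no_evidence(self):
        rng = np.random.default_rng(3)
        trials = [
            PredationTrial(
                n0=n0, ne=int(min(n0, rng.integers(0, 5))),
                treatment="25_AP", replicate=str(rep),
            )
            for rep in range(6)
            for n0 in (5, 10, 25, 50, 80)
        ]
        sel = select_model(TrialSet(trials), seed=0)
        assert not sel.evidence

    def test_aic_table_lists_every_candidate(self, make_experiment):
        sel = select_model(make_experiment(seed=5), seed=0)
        assert set(sel.aic_table["family"]) == set(sel.fits)


class TestBootstrap:
    def test_invalid_iteration_count(self, make_experiment):
        with pytest.raises(ValueError):
            bootstrap_ci(make_experiment(seed=2), "rogers2", n_boot=0)

    def test_zero_variance_data_gives_degenerate_ci(self):
        trials = [
            PredationTrial(n0=n0, ne=ne, replicate=str(i))
            for n0, ne in [(25, 10), (80, 25)]
            for i in range(6)
        ]
        ts = TrialSet(trials)
        fit = fit_fr(ts, "rogers2")
        boot = bootstrap_ci(ts, "rogers2", n_boot=50, seed=0, point=fit)
        for name in ("a", "h"):
            width = boot.ci_upper[name] - boot.ci_lower[name]
            assert width <= 1e-6 * max(boot.ci_upper[name], 1e-12)

    def test_interval_brackets_estimate_and_is_deterministic(
        self, make_experiment
    ):
        ts = make_experiment(seed=19)
        fit = fit_fr(ts, "rogers2")
        b1 = bootstrap_ci(ts, "rogers2", n_boot=150, seed=9, point=fit)
        b2 = bootstrap_ci(ts, "rogers2", n_boot=150, seed=9, point=fit)
        assert b1.ci_lower == b2.ci_lower and b1.ci_upper == b2.ci_upper
        for name in ("a", "h"):
            assert b1.ci_lower[name] <= fit.estimates[name] <= b1.ci_upper[name]
        assert not b1.unreliable

    def test_bca_option_produces_finite_interval(self, make_experiment):
        ts = make_experiment(seed=23)
        fit = fit_fr(ts, "rogers2")
        boot = bootstrap_ci(
            ts, "rogers2", n_boot=100, seed=1, point=fit, method="bca"
        )
        for name in ("a", "h"):
            assert np.isfinite(boot.ci_lower[name])
            assert boot.ci_lower[name] < boot.ci_upper[name]
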