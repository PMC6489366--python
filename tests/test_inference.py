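"""Hierarchical Bayesian inference: likelihood oracle, fits, diagnostics."""

import math

import numpy as np
import pytest
from scipy import stats

from pskstab import (
    LossCurve,
    Mechanism,
    PassagingProtocol,
    PSKParams,
    fit_competition,
    fit_hierarchical,
    log_likelihood,
    posterior_predictive,
    predict_competition,
    simulate_loss_curve,
)
from pskstab.inference import PosteriorSummary, PriorSpec, SamplerSettings

FAST = SamplerSettings(n_chains=4, n_steps=400, n_burn=200)


def termwise_reference(curve, params, protocol, phi):
    """Brute-force re-implementation: score each passage with scipy.stats.beta.

    Observations within eps = 1/(2 n) of a boundary are censored at it.
    """
    sim = simulate_loss_curve(params, protocol)
    total = 0.0
    for p, obs, n in zip(curve.passage, curve.fraction, curve.n_events):
        f = min(max(sim.fraction[int(p)], 1e-12), 1 - 1e-12)
        a, b = f * phi, (1 - f) * phi
        eps = 1.0 / (2.0 * n)
        if obs <= eps:
            total += stats.beta.logcdf(eps, a, b)
        elif obs >= 1 - eps:
            total += stats.beta.logsf(1 - eps, a, b)
        else:
            total += stats.beta.logpdf(obs, a, b)
    return total


class TestLogLikelihood:
    def test_termwise_oracle_equivalence(self):
        protocol = PassagingProtocol(n_passages=3)
        params = PSKParams(0.05, 0.9, 0.3, Mechanism.TA)
        curve = LossCurve(
            "r1", [0, 1, 2, 3], [1.0, 0.62, 0.31, 0.00001],
            n_events=[1000, 1000, 1000, 1000],
        )
        got = log_likelihood([curve], [params], protocol, noise_precision=200.0)
        ref = termwise_reference(curve, params, protocol, 200.0)
        assert got == pytest.approx(ref, abs=1e-10)

    def test_additivity_over_replicates(self):
        protocol = PassagingProtocol(n_passages=3)
        params = PSKParams(0.02, 0.95, 0.0, Mechanism.TA)
        curve = LossCurve("r", [0, 1, 2, 3], [1.0, 0.8, 0.6, 0.4],
                          n_events=[500] * 4)
        single = log_likelihood([curve], [params], protocol, 100.0)
        double = log_likelihood([curve, curve], [params, params], protocol, 100.0)
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_observed_equal_to_model_is_the_mode(self):
        protocol = PassagingProtocol(n_passages=4)
        params = PSKParams(0.05, 0.9, 0.0, Mechanism.TA)
        model = simulate_loss_curve(params, protocol)
        n = np.full(len(model), 10_000)
        exact = LossCurve("r", model.passage, model.fraction, n_events=n)
        ll_exact = log_likelihood([exact], [params], protocol, 500.0)
        for delta in (0.01, -0.01):
            shifted = np.clip(model.fraction + delta, 0.0, 1.0)
            pert = LossCurve("r", model.passage, shifted, n_events=n)
            assert log_likelihood([pert], [params], protocol, 500.0) < ll_exact

    def test_length_mismatch(self):
        protocol = PassagingProtocol(n_passages=2)
        curve = LossCurve("r", [0, 1], [1.0, 0.9])
        with pytest.raises(ValueError):
            log_likelihood([curve], [], protocol, 100.0)


class TestFitHierarchical:
    def test_draws_respect_bounds_and_summary_shape(self, recovery_dataset):
        _, protocol, curves, _ = recovery_dataset
        fit = fit_hierarchical(curves[:2], protocol, settings=FAST, seed=5)
        assert np.all((fit.draws["lambda_loss"] > 0) & (fit.draws["lambda_loss"] < 1))
        assert np.all((fit.draws["omega"] > 0) & (fit.draws["omega"] < 1))
        assert np.all(fit.draws["gamma"] > 0)
        s = fit.summary
        assert (s["q2.5"] <= s["median"]).all() and (s["median"] <= s["q97.5"]).all()
        assert {"rhat", "ess_bulk", "prior_posterior_overlap"} <= set(s.columns)
        assert len(fit.replicate_summary) == 2
        # the reported survival probability is the complement of omega
        np.testing.assert_allclose(
            fit.draws["survival_prob"], 1.0 - fit.draws["omega"]
        )

    def test_single_replicate_degrades_gracefully(self, recovery_dataset):
        _, protocol, curves, _ = recovery_dataset
        fit = fit_hierarchical(curves[:1], protocol, settings=FAST, seed=6)
        assert fit.n_replicates == 1
        assert len(fit.replicate_summary) == 1
        assert np.isfinite(fit.median("lambda_loss"))

    def test_requires_curves(self):
        with pytest.raises(ValueError):
            fit_hierarchical([], PassagingProtocol())

    def test_omega_inert_without_killing(self):
        # with no killing in truth, NONE and TA fits agree on lambda/gamma
        protocol = PassagingProtocol(n_passages=12)
        from pskstab import HierarchicalTruth, generate_loss_curves

        truth = HierarchicalTruth(
            lambda_loss=0.02, gamma=0.9, omega=0.0, mechanism=Mechanism.NONE,
            sd_logit_lambda=0.1, sd_log_gamma=0.02,
        )
        curves, _ = generate_loss_curves(
            truth, protocol, n_replicates=3, noise="beta",
            noise_precision=500.0, seed=17,
        )
        slow = SamplerSettings(n_chains=4, n_steps=700, n_burn=350)
        f_none = fit_hierarchical(
            curves, protocol, mechanism=Mechanism.NONE, settings=slow, seed=1
        )
        f_ta = fit_hierarchical(
            curves, protocol, mechanism=Mechanism.TA, settings=slow, seed=2
        )
        lo, hi = f_ta.credible_interval("gamma")
        assert lo - 0.02 <= f_none.median("gamma") <= hi + 0.02
        # lambda agrees on the log scale within the (ridge-widened) interval
        lo, hi = np.log10(f_ta.credible_interval("lambda_loss"))
        assert lo - 0.2 <= np.log10(f_none.median("lambda_loss")) <= hi + 0.2


class TestPosteriorPredictive:
    def _degenerate_summary(self, lam=0.01, gam=0.9, om=0.5, n=200):
        draws = {
            "lambda_loss": np.full((1, n), lam),
            "gamma": np.full((1, n), gam),
            "omega": np.full((1, n), om),
            "survival_prob": np.full((1, n), 1 - om),
        }
        import pandas as pd

        return PosteriorSummary(
            mechanism=Mechanism.TA, n_replicates=0, draws=draws,
            summary=pd.DataFrame({"parameter": [], "rhat": []}),
            replicate_summary=pd.DataFrame(), converged=True, max_rhat=1.0,
            seed=0, settings=FAST, priors=PriorSpec(),
        )

    def test_degenerate_posterior_zero_width(self):
        s = self._degenerate_summary()
        env = posterior_predictive(
            s, PassagingProtocol(n_passages=6), n_draws=100, seed=1,
            include_noise=False,
        )
        np.testing.assert_allclose(env["lo2.5"], env["hi97.5"], atol=1e-12)

    def test_envelope_contains_median_curve(self, recovery_dataset):
        _, protocol, curves, _ = recovery_dataset
        fit = fit_hierarchical(curves[:3], protocol, settings=FAST, seed=7)
        env = posterior_predictive(fit, protocol, n_draws=200, seed=2, force=True)
        assert ((env["lo2.5"] - 1e-12 <= env["median"])
                & (env["median"] <= env["hi97.5"] + 1e-12)).all()

    def test_too_many_draws_rejected(self):
        s = self._degenerate_summary(n=50)
        with pytest.raises(ValueError):
            posterior_predictive(s, PassagingProtocol(n_passages=3), n_draws=500)


class TestFitCompetition:
    def test_omega_recovered_for_bacteriocin_series(self):
        true = PSKParams(1e-4, 0.9, 0.9, Mechanism.BACTERIOCIN)
        f0 = np.array([0.05, 0.1, 0.2, 0.4, 0.6, 0.8])
        f1 = predict_competition(true, f0, math.log(1000))
        rng = np.random.default_rng(11)
        obs = rng.beta(np.clip(f1, 1e-9, 1 - 1e-9) * 500,
                       np.clip(1 - f1, 1e-9, 1) * 500)
        fit = fit_competition(
            np.column_stack([f0, obs]), mechanism=Mechanism.BACTERIOCIN,
            tau=math.log(1000), seed=3,
            settings=SamplerSettings(n_chains=4, n_steps=700, n_burn=350),
        )
        lo, hi = fit.credible_interval("omega")
        assert lo <= 0.9 <= hi

    def test_identity_data_concentrates_at_boundary(self):
        # outputs equal inputs: no loss, no burden; lambda pushed to 0
        f0 = np.array([0.2, 0.4, 0.6, 0.8])
        fit = fit_competition(
            np.column_stack([f0, f0]), mechanism=Mechanism.TA, tau=math.log(1000),
            seed=4, settings=SamplerSettings(n_chains=4, n_steps=500, n_burn=250),
        )
        assert fit.median("lambda_loss") < 1e-3
        assert "lambda_loss" in fit.non_identifiable() or fit.median("lambda_loss") < 1e-4

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            fit_competition(np.array([[0.5, 0.4]]))

    def test_fraction_bounds_checked(self):
        with pytest.raises(ValueError):
            fit_competition(np.array([[0.5, 1.4], [0.2, 0.1], [0.3, 0.2]]))
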