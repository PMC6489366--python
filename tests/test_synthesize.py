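"""Synthetic-data generators: reproducibility, truth bookkeeping, noise limits."""

import numpy as np
import pytest

from pskstab import (
    HierarchicalTruth,
    Mechanism,
    PassagingProtocol,
    generate_events,
    generate_growth_curve,
    generate_loss_curves,
    simulate_loss_curve,
)


class TestLossCurveGenerator:
    def test_seed_reproducibility(self, short_protocol):
        truth = HierarchicalTruth()
        a, ta = generate_loss_curves(truth, short_protocol, n_replicates=3, seed=1)
        b, tb = generate_loss_curves(truth, short_protocol, n_replicates=3, seed=1)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.fraction, cb.fraction)
        assert ta.equals(tb)

    def test_truth_table_accompanies_curves(self, short_protocol):
        curves, table = generate_loss_curves(
            HierarchicalTruth(), short_protocol, n_replicates=4, seed=2
        )
        assert len(curves) == 4
        assert set(table.columns) >= {"replicate_id", "lambda_loss", "gamma", "omega"}
        assert list(table["replicate_id"]) == [c.replicate_id for c in curves]

    def test_no_loss_binomial_gives_all_ones(self, short_protocol):
        truth = HierarchicalTruth(lambda_loss=1e-300, sd_logit_lambda=0.0)
        curves, _ = generate_loss_curves(
            truth, short_protocol, n_replicates=2, noise="binomial", seed=3
        )
        for c in curves:
            assert np.all(c.fraction == 1.0)

    def test_noise_free_limit_matches_deterministic_curve(self):
        # huge event counts and beta precision recover the latent curve
        truth = HierarchicalTruth(
            lambda_loss=0.01, gamma=0.9, omega=0.5, mechanism=Mechanism.TA,
            sd_logit_lambda=0.0, sd_log_gamma=0.0, sd_logit_omega=0.0,
        )
        protocol = PassagingProtocol(n_passages=8)
        curves, table = generate_loss_curves(
            truth, protocol, n_replicates=1, n_events=10**8,
            noise="beta", noise_precision=1e8, seed=4,
        )
        params = [
            __import__("pskstab").PSKParams(
                row.lambda_loss, row.gamma, row.omega, Mechanism.TA
            )
            for row in table.itertuples()
        ]
        det = simulate_loss_curve(params[0], protocol)
        np.testing.assert_allclose(curves[0].fraction, det.fraction, atol=1e-3)

    def test_unknown_noise_model(self, short_protocol):
        with pytest.raises(ValueError):
            generate_loss_curves(HierarchicalTruth(), short_protocol, noise="poisson")

    def test_hierarchy_draws_respect_bounds(self, short_protocol):
        truth = HierarchicalTruth(sd_logit_lambda=3.0, sd_logit_omega=3.0)
        _, table = generate_loss_curves(truth, short_protocol, n_replicates=50, seed=5)
        assert table["lambda_loss"].between(0, 1).all()
        assert table["omega"].between(0, 1).all()
        assert (table["gamma"] > 0).all()

    def test_bottleneck_adds_drift(self, short_protocol):
        truth = HierarchicalTruth(lambda_loss=0.01, omega=0.0, sd_logit_lambda=0.0)
        a, _ = generate_loss_curves(
            truth, short_protocol, n_replicates=1, seed=6, bottleneck=True,
            noise="binomial",
        )
        assert np.all((a[0].fraction >= 0) & (a[0].fraction <= 1))


class TestEventGenerator:
    def test_pure_bearing_no_debris(self):
        ev = generate_events(1.0, n_events=500, debris_fraction=0.0, seed=1)
        assert set(ev.label) == {"bearing"}

    def test_label_counts_near_binomial(self):
        n, f = 10_000, 0.7
        ev = generate_events(f, n_events=n, debris_fraction=0.0, seed=2)
        n_bearing = int(np.sum(ev.label == "bearing"))
        sigma = np.sqrt(n * f * (1 - f))
        assert abs(n_bearing - n * f) < 3 * sigma

    def test_seed_reproducibility(self):
        a = generate_events(0.4, n_events=200, seed=3)
        b = generate_events(0.4, n_events=200, seed=3)
        np.testing.assert_array_equal(a.fl1, b.fl1)
        np.testing.assert_array_equal(a.label, b.label)

    def test_channels_positive(self):
        ev = generate_events(0.5, n_events=1000, debris_fraction=0.1, seed=4)
        assert (ev.fsc > 0).all() and (ev.ssc > 0).all() and (ev.fl1 > 0).all()

    def test_separation_moves_bearing_mode(self):
        ev = generate_events(0.5, n_events=5000, separation_decades=3.0, seed=5,
                             debris_fraction=0.0)
        hi = np.log10(ev.fl1[ev.label == "bearing"]).mean()
        lo = np.log10(ev.fl1[ev.label == "free"]).mean()
        assert hi - lo == pytest.approx(3.0, abs=0.05)


class TestGrowthGenerator:
    def test_noiseless_curve_is_deterministic_and_sigmoid(self):
        g = generate_growth_curve(mu_max=0.01, noise_sd=0.0, seed=1)
        h = generate_growth_curve(mu_max=0.01, noise_sd=0.0, seed=99)
        np.testing.assert_array_equal(g.od, h.od)  # noise-free: seed-independent
        assert np.all(np.diff(g.od) >= -1e-12)
        assert g.od[-1] == pytest.approx(1.2, rel=0.05)

    def test_exponential_window_slope_matches_mu_max(self):
        # with effectively unbounded capacity, the max log-OD slope is mu_max
        g = generate_growth_curve(
            mu_max=0.01, capacity=1e9, od0=1e-4, noise_sd=0.0, duration=1500.0
        )
        slope = np.diff(np.log(g.od)) / np.diff(g.time)
        assert slope.max() == pytest.approx(0.01, rel=0.01)

    def test_seed_reproducibility(self):
        a = generate_growth_curve(noise_sd=0.02, seed=7)
        b = generate_growth_curve(noise_sd=0.02, seed=7)
        np.testing.assert_array_equal(a.od, b.od)

    def test_invalid_mu(self):
        with pytest.raises(ValueError):
            generate_growth_curve(mu_max=0.0)
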