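"""Synthetic geography, covariates, latent fields, and observation processes."""

import numpy as np
import pandas as pd
import pytest

import hurdlemap as hm
from hurdlemap.covariates import DEPRIVATION_INDICATORS


class TestGenerateTracts:
    def test_single_tract_fills_the_extent(self):
        tf = hm.generate_tracts(1, 1000.0, seed=0)
        assert tf.geometry[0].area == pytest.approx(1000.0**2)

    def test_deterministic_given_seed(self):
        a = hm.generate_tracts(50, 10_000.0, seed=7)
        b = hm.generate_tracts(50, 10_000.0, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert all(g1.equals(g2) for g1, g2 in zip(a.geometry, b.geometry))

    def test_distinct_centroids(self):
        tf = hm.generate_tracts(50, 10_000.0, seed=7)
        pts = tf.centroids
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        assert d[~np.eye(50, dtype=bool)].min() > 0

    def test_voronoi_cells_partition_the_extent(self):
        tf = hm.generate_tracts(30, 5000.0, seed=3)
        assert sum(g.area for g in tf.geometry) == pytest.approx(5000.0**2, rel=1e-9)

    def test_populations_within_bounds(self):
        tf = hm.generate_tracts(200, 10_000.0, seed=1)
        pops = tf.table["population"]
        assert pops.between(499, 3001).all()

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            hm.generate_tracts(0, 1000.0, seed=0)
        with pytest.raises(ValueError):
            hm.generate_tracts(5, -1.0, seed=0)


class TestGenerateCovariates:
    def test_foreign_subgroups_bounded_by_total(self, small_tracts):
        t = small_tracts.table
        total = t["foreign_africa"] + t["foreign_south_america"] + t["foreign_asia"]
        assert (total <= t["foreign"] + 1e-9).all()

    def test_percentages_in_range(self):
        tf = hm.generate_covariates(hm.generate_tracts(500, 10_000.0, seed=2), seed=3)
        cols = DEPRIVATION_INDICATORS + [
            "housing45", "housing4560", "foreign",
            "foreign_africa", "foreign_south_america", "foreign_asia",
        ]
        vals = tf.table[cols].to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 100.0

    def test_unemployment_marginal_matches_target(self):
        tf = hm.generate_covariates(hm.generate_tracts(10_000, 50_000.0, seed=0), seed=1)
        assert tf.table["unemployment"].mean() == pytest.approx(24.46, abs=1.0)
        assert tf.table["unemployment"].std() == pytest.approx(9.47, abs=1.0)

    def test_indicators_share_a_common_factor(self, small_tracts):
        corr = small_tracts.table[DEPRIVATION_INDICATORS].corr().to_numpy()
        off = corr[~np.eye(6, dtype=bool)]
        assert off.mean() > 0.2

    def test_empty_input_rejected(self):
        empty = hm.TractFrame(
            pd.DataFrame(columns=["x", "y", "population"]), []
        )
        with pytest.raises(ValueError):
            hm.generate_covariates(empty, seed=0)


class TestLatentFields:
    def test_zero_variances_give_exact_zeros(self, small_tracts):
        eff = hm.simulate_latent_fields(
            small_tracts, 7, hm.MaternParams(0.1, 1.0, 1e-3), 0.0, 0.0, seed=0
        )
        assert np.all(eff.eta == 0.0) and np.all(eff.tau == 0.0)

    def test_tau_sums_to_zero(self, small_tracts):
        eff = hm.simulate_latent_fields(
            small_tracts, 9, hm.MaternParams(0.1, 1.0, 1e-3), 0.1, 0.5, seed=1
        )
        assert abs(eff.tau.sum()) < 1e-10

    def test_deterministic(self, small_tracts):
        args = (small_tracts, 7, hm.MaternParams(0.1, 1.0, 1e-3), 0.1, 0.1)
        a = hm.simulate_latent_fields(*args, seed=5)
        b = hm.simulate_latent_fields(*args, seed=5)
        assert np.array_equal(a.S, b.S) and np.array_equal(a.eta, b.eta)

    def test_negative_variance_rejected(self, small_tracts):
        with pytest.raises(ValueError):
            hm.simulate_latent_fields(
                small_tracts, 7, hm.MaternParams(0.1, 1.0, 1e-3), -0.1, 0.0, seed=0
            )


class TestSimulateObservations:
    def scenario(self, **kw):
        base = dict(
            n_tracts=20,
            n_periods=7,
            true_betas_binomial={"intercept": 1.0},
            true_betas_poisson={"intercept": 1.0},
            matern=hm.MaternParams(1e-10, 1.0, 1e-3),
            var_eta=0.0,
            var_tau=0.0,
            seed=0,
            missing_fraction=0.0,
        )
        base.update(kw)
        return hm.SyntheticScenario(**base)

    def test_closed_gate_yields_all_zeros(self, small_tracts):
        sc = self.scenario(true_betas_binomial={"intercept": -50.0})
        eff = hm.simulate_latent_fields(small_tracts, 7, sc.matern, 0.0, 0.0, seed=0)
        panel = hm.simulate_observations(small_tracts, eff, sc)
        assert (panel.counts == 0).all()

    def test_open_gate_unit_rate_poisson_mean(self):
        # gate forced open, log-rate 0: counts are Poisson(1); check the mean
        # over ~1e5 tract-periods
        tracts = hm.generate_covariates(hm.generate_tracts(1000, 50_000.0, seed=4), seed=5)
        sc = self.scenario(
            n_tracts=1000,
            n_periods=100,
            true_betas_binomial={"intercept": 50.0},
            true_betas_poisson={"intercept": 0.0},
        )
        eff = hm.simulate_latent_fields(tracts, 100, sc.matern, 0.0, 0.0, seed=0)
        panel = hm.simulate_observations(tracts, eff, sc)
        assert len(panel.obs) == 100_000
        assert panel.counts.mean() == pytest.approx(1.0, abs=0.02)

    def test_determinism(self, small_tracts):
        sc = self.scenario(missing_fraction=0.1)
        eff = hm.simulate_latent_fields(small_tracts, 7, sc.matern, 0.0, 0.0, seed=0)
        a = hm.simulate_observations(small_tracts, eff, sc)
        b = hm.simulate_observations(small_tracts, eff, sc)
        pd.testing.assert_frame_equal(a.obs, b.obs)

    def test_hurdle_mode_induces_overdispersion(self):
        # gate-then-count selection leaves excess zeros relative to a Poisson
        # with the same mean: the dispersion index is well above 1
        tracts = hm.generate_covariates(hm.generate_tracts(500, 30_000.0, seed=6), seed=7)
        sc = self.scenario(
            n_tracts=500,
            n_periods=20,
            true_betas_binomial={"intercept": 0.0},  # gate open half the time
            true_betas_poisson={"intercept": np.log(5.0)},
        )
        eff = hm.simulate_latent_fields(tracts, 20, sc.matern, 0.0, 0.0, seed=1)
        panel = hm.simulate_observations(tracts, eff, sc)
        y = panel.counts
        assert y.var() / y.mean() > 1.5
        assert (y == 0).mean() > np.exp(-y.mean())

    def test_missingness_makes_panel_unbalanced(self, small_tracts):
        sc = self.scenario(missing_fraction=0.3)
        eff = hm.simulate_latent_fields(small_tracts, 7, sc.matern, 0.0, 0.0, seed=0)
        panel = hm.simulate_observations(small_tracts, eff, sc)
        assert len(panel.obs) < 20 * 7
        assert panel.n_periods == 7

    def test_drop_zero_rows_flag(self, small_tracts):
        sc = self.scenario(
            true_betas_binomial={"intercept": 0.0}, drop_zero_rows=True
        )
        eff = hm.simulate_latent_fields(small_tracts, 7, sc.matern, 0.0, 0.0, seed=0)
        panel = hm.simulate_observations(small_tracts, eff, sc)
        assert (panel.counts > 0).all()

    def test_rate_overflow_instructs_rescaling(self, small_tracts):
        sc = self.scenario(true_betas_poisson={"intercept": 40.0})
        eff = hm.simulate_latent_fields(small_tracts, 7, sc.matern, 0.0, 0.0, seed=0)
        with pytest.raises(FloatingPointError, match="rescale"):
            hm.simulate_observations(small_tracts, eff, sc)

    def test_binomial_mode_draws_from_reporting_law(self, small_tracts):
        sc = self.scenario(
            obs_mode="binomial", true_betas_binomial={"intercept": -6.0}
        )
        eff = hm.simulate_latent_fields(small_tracts, 7, sc.matern, 0.0, 0.0, seed=0)
        panel = hm.simulate_observations(small_tracts, eff, sc)
        p = 1 / (1 + np.exp(6.0))
        expected = (panel.trials * p).mean()
        assert panel.counts.mean() == pytest.approx(expected, rel=0.25)


class TestScenarioValidation:
    def test_too_few_tracts_rejected(self):
        with pytest.raises(ValueError):
            hm.SyntheticScenario(n_tracts=3)

    def test_few_tracts_warn(self):
        with pytest.warns(UserWarning, match="quintile"):
            hm.SyntheticScenario(n_tracts=6)

    def test_unknown_coefficient_name_rejected(self, small_tracts):
        sc = hm.SyntheticScenario(
            n_tracts=20, true_betas_binomial={"nope": 1.0}, seed=0
        )
        eff = hm.simulate_latent_fields(small_tracts, 7, sc.matern, 0.0, 0.0, seed=0)
        with pytest.raises(ValueError, match="nope"):
            hm.simulate_observations(small_tracts, eff, sc)
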