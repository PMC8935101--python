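"""Two-part likelihood: predictors, pmf oracles, and the joint density."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hurdlemap as hm
from hurdlemap.model import linear_predictors, rw1_logpdf, spatial_logpdf


class TestLinearPredictor:
    def test_all_zero_is_zero(self):
        latents = hm.LatentEffects.zeros(2, 2)
        assert hm.linear_predictor([0.0], np.zeros(2), latents, 0, 0) == 0.0

    def test_hand_sum(self):
        latents = hm.LatentEffects(
            eta=np.array([0.1]), tau=np.array([0.0]), S=np.array([-0.1])
        )
        val = hm.linear_predictor([2.0], np.array([1.0, 0.5]), latents, 0, 0)
        assert val == pytest.approx(2.0)

    def test_intercept_eta_confounding_identity(self, toy_panel, toy_latents):
        """Adding c to the intercept and subtracting it from eta is invisible."""
        beta = np.array([-1.0, 0.4, 0.2])
        base = linear_predictors(toy_panel, beta, toy_latents)
        c = 0.77
        shifted_beta = beta.copy()
        shifted_beta[0] += c
        shifted = hm.LatentEffects(
            eta=toy_latents.eta - c, tau=toy_latents.tau, S=toy_latents.S
        )
        np.testing.assert_allclose(
            base, linear_predictors(toy_panel, shifted_beta, shifted), atol=1e-12
        )

    def test_index_out_of_range(self, toy_latents):
        with pytest.raises(IndexError):
            hm.linear_predictor([1.0], np.zeros(2), toy_latents, 5, 0)


class TestBinomialLoglik:
    def test_half_probability_example(self):
        assert hm.binomial_loglik(1, 2, 0.0) == pytest.approx(np.log(0.5))

    def test_extreme_predictor_near_certain_zero(self):
        assert hm.binomial_loglik(0, 10, -50.0) == pytest.approx(0.0, abs=1e-18)
        assert np.isfinite(hm.binomial_loglik(3, 10, 700.0))

    @pytest.mark.parametrize("count,n,pred", [(3, 7, 0.4), (0, 5, -1.2), (9, 9, 2.0)])
    def test_matches_scipy_pmf(self, count, n, pred):
        p = 1 / (1 + np.exp(-pred))
        assert hm.binomial_loglik(count, n, pred) == pytest.approx(
            stats.binom.logpmf(count, n, p), rel=1e-12
        )

    def test_count_above_trials_rejected(self):
        with pytest.raises(ValueError):
            hm.binomial_loglik(5, 3, 0.0)


class TestPoissonLoglik:
    def test_zero_count_unit_rate(self):
        assert hm.poisson_loglik(0, 0.0) == pytest.approx(-1.0)

    def test_hand_evaluation(self):
        assert hm.poisson_loglik(2, np.log(2.0)) == pytest.approx(np.log(2.0) - 2.0)

    def test_matches_scipy_pmf(self):
        for y, ell in [(0, -2.0), (4, 1.3), (100, 4.0)]:
            assert hm.poisson_loglik(y, ell) == pytest.approx(
                stats.poisson.logpmf(y, np.exp(ell)), rel=1e-12
            )

    def test_normalisation_sums_to_one(self):
        theta = 3.0
        total = sum(np.exp(hm.poisson_loglik(y, np.log(theta))) for y in range(60))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            hm.poisson_loglik(-1, 0.0)
        with pytest.raises(ValueError):
            hm.poisson_loglik(1.5, 0.0)


class TestJointLoglik:
    def brute_force(self, panel, params, latents):
        """Per-observation oracle built from scipy pmfs and Gaussian densities."""
        X = panel.design.to_numpy(dtype=float)
        total = 0.0
        for _, row in panel.obs.iterrows():
            i = list(panel.design.index).index(row["tract_id"])
            t = int(row["period"]) - 1
            x = X[i]
            l1 = hm.linear_predictor(x, params.beta_binomial, latents, i, t)
            l2 = hm.linear_predictor(
                x, params.beta_poisson, latents, i, t, alpha=params.alpha_share
            )
            n = panel.n_trials.loc[row["tract_id"]]
            p = 1 / (1 + np.exp(-l1))
            total += stats.binom.logpmf(row["count"], n, p)
            total += stats.poisson.logpmf(row["count"], np.exp(l2))
        total += stats.norm.logpdf(latents.eta, scale=np.sqrt(params.var_eta)).sum()
        total += stats.norm.logpdf(np.diff(latents.tau), scale=np.sqrt(params.var_tau)).sum()
        cov = hm.covariance_matrix(panel.centroids, params.matern)
        total += stats.multivariate_normal.logpdf(latents.S, cov=cov)
        return float(total)

    def test_matches_brute_force_on_toy_panel(self, toy_panel, toy_params, toy_latents):
        val = hm.joint_loglik(toy_panel, toy_params, toy_latents)
        assert val == pytest.approx(
            self.brute_force(toy_panel, toy_params, toy_latents), abs=1e-8
        )

    def test_empty_panel_reduces_to_latent_priors(self, toy_params):
        design = pd.DataFrame(
            {"x1": [0.0, 1.0], "x2": [0.5, -0.5]}, index=pd.Index([1, 2], name="tract_id")
        )
        panel = hm.PanelDataset(
            obs=pd.DataFrame(columns=["tract_id", "period", "count"]),
            n_trials=pd.Series([10, 10], index=design.index),
            design=design,
            centroids=np.array([[0.0, 0.0], [500.0, 0.0]]),
        )
        latents = hm.LatentEffects.zeros(2, 1)
        val = hm.joint_loglik(panel, toy_params, latents)
        cov = hm.covariance_matrix(panel.centroids, toy_params.matern)
        expected = (
            stats.multivariate_normal.logpdf(latents.S, cov=cov)
            + stats.norm.logpdf([0.0, 0.0], scale=np.sqrt(toy_params.var_eta)).sum()
        )
        assert val == pytest.approx(expected, abs=1e-10)

    def test_tract_relabelling_invariance(self, toy_panel, toy_params, toy_latents):
        perm = [2, 0, 1]
        ids = list(toy_panel.design.index)
        remap = {ids[k]: ids_new for ids_new, k in zip(ids, perm)}
        obs = toy_panel.obs.copy()
        obs["tract_id"] = obs["tract_id"].map(remap)
        design = toy_panel.design.iloc[perm].copy()
        design.index = pd.Index(ids, name="tract_id")
        panel2 = hm.PanelDataset(
            obs=obs.sort_values(["tract_id", "period"]).reset_index(drop=True),
            n_trials=pd.Series(
                toy_panel.n_trials.to_numpy()[perm], index=design.index
            ),
            design=design,
            centroids=toy_panel.centroids[perm],
        )
        latents2 = hm.LatentEffects(
            eta=toy_latents.eta[perm], tau=toy_latents.tau, S=toy_latents.S[perm]
        )
        assert hm.joint_loglik(panel2, toy_params, latents2) == pytest.approx(
            hm.joint_loglik(toy_panel, toy_params, toy_latents), rel=1e-12
        )

    def test_doubling_counts_decreases_poisson_terms_when_rate_below_one(
        self, toy_panel, toy_params, toy_latents
    ):
        small = hm.ModelParameters(
            beta_binomial=toy_params.beta_binomial,
            beta_poisson=np.array([-1.5, 0.0, 0.0]),  # theta < 1 everywhere
            matern=toy_params.matern,
            var_eta=toy_params.var_eta,
            var_tau=toy_params.var_tau,
        )
        l2 = linear_predictors(toy_panel, small.beta_poisson, toy_latents)
        base = hm.poisson_loglik(toy_panel.counts, l2).sum()
        doubled = hm.poisson_loglik(2 * toy_panel.counts, l2).sum()
        assert doubled < base

    def test_degenerate_variances_require_zero_latents(self, toy_panel, toy_params):
        params = hm.ModelParameters(
            beta_binomial=toy_params.beta_binomial,
            beta_poisson=toy_params.beta_poisson,
            matern=toy_params.matern,
            var_eta=0.0,
            var_tau=0.0,
        )
        ok = hm.LatentEffects(np.zeros(3), np.zeros(2), np.array([0.1, -0.2, 0.3]))
        assert np.isfinite(hm.joint_loglik(toy_panel, params, ok))
        bad = hm.LatentEffects(np.array([0.1, 0, 0]), np.zeros(2), np.zeros(3))
        assert hm.joint_loglik(toy_panel, params, bad) == -np.inf

    def test_finite_over_wide_predictor_range(self, toy_panel, toy_params):
        for shift in (-30.0, 0.0, 30.0):
            params = hm.ModelParameters(
                beta_binomial=toy_params.beta_binomial + np.array([shift, 0, 0]),
                beta_poisson=toy_params.beta_poisson,
                matern=toy_params.matern,
                var_eta=toy_params.var_eta,
                var_tau=toy_params.var_tau,
            )
            latents = hm.LatentEffects.zeros(3, 2)
            assert np.isfinite(hm.joint_loglik(toy_panel, params, latents))

    def test_shape_mismatch_raises(self, toy_panel, toy_params):
        with pytest.raises(ValueError):
            hm.joint_loglik(toy_panel, toy_params, hm.LatentEffects.zeros(4, 2))


def test_rw1_density_is_increment_density():
    tau = np.array([0.2, -0.1, -0.1])
    assert rw1_logpdf(tau, 0.5) == pytest.approx(
        stats.norm.logpdf(np.diff(tau), scale=np.sqrt(0.5)).sum()
    )


def test_spatial_density_matches_scipy():
    pts = np.array([[0.0, 0.0], [300.0, 0.0], [0.0, 900.0]])
    params = hm.MaternParams(0.8, 1.0, hm.kappa_from_range(1.0, 500.0))
    S = np.array([0.3, -0.2, 0.1])
    cov = hm.covariance_matrix(pts, params)
    assert spatial_logpdf(S, pts, params) == pytest.approx(
        stats.multivariate_normal.logpdf(S, cov=cov), abs=1e-9
    )


def test_tau_sum_to_zero_enforced():
    with pytest.raises(ValueError, match="sum-to-zero"):
        hm.LatentEffects(np.zeros(2), np.array([0.5, 0.1]), np.zeros(2))
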