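import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tractmix as tm
from tractmix.mixture import (
    MCMCConfig,
    MixtureModelSpec,
    PosteriorDraws,
    classify,
    convergence_diagnostics,
    fit_mcmc,
    log_density,
    membership_probabilities,
    sensitivity_analysis,
)

I2 = np.eye(2)


def _separated_data(rng, B=30, J=5, n2=8, mu1=(0.0, 0.0), mu2=(-10.0, -10.0)):
    z = np.array([2] * n2 + [1] * (B - n2))
    mu = np.where(z[:, None] == 1, np.asarray(mu1), np.asarray(mu2))
    x = mu[:, None, :] + rng.standard_normal((B, J, 2))
    return x, z


class TestLogDensity:
    def test_degenerate_mixture_equals_single_normal(self):
        x = np.array([0.3, -1.2])
        mu1, a1 = np.array([1.0, 0.5]), np.array([-0.2, 0.1])
        val = log_density(x, 1.0, mu1, np.array([9.0, 9.0]), a1, np.zeros(2), I2)
        oracle = stats.multivariate_normal(mu1 + a1, I2).logpdf(x)
        assert val == pytest.approx(oracle, abs=1e-10)

    def test_component_swap_symmetry(self):
        x = np.array([0.5, 0.5])
        mu1, mu2 = np.array([1.0, 0.0]), np.array([-1.0, 2.0])
        a1, a2 = np.array([0.1, 0.2]), np.array([-0.3, 0.4])
        v1 = log_density(x, 0.3, mu1, mu2, a1, a2, I2)
        v2 = log_density(x, 0.7, mu2, mu1, a2, a1, I2)
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_against_independent_bivariate_normal_oracle(self):
        x = np.zeros(2)
        val = log_density(
            x, 0.5, np.array([1.0, 0.0]), np.array([-1.0, 0.0]), np.zeros(2), np.zeros(2), I2
        )
        dens = 0.5 * stats.multivariate_normal([1, 0], I2).pdf(x) + 0.5 * (
            stats.multivariate_normal([-1, 0], I2).pdf(x)
        )
        assert val == pytest.approx(np.log(dens), abs=1e-10)

    def test_singular_sigma_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            log_density(np.zeros(2), 0.5, np.zeros(2), np.ones(2), np.zeros(2),
                        np.zeros(2), np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_density_normalises(self, rng):
        # numerical quadrature of exp(log_density) over a wide grid
        for _ in range(5):
            p = rng.uniform(0.05, 0.95)
            mu1, mu2 = rng.normal(0, 2, 2), rng.normal(0, 2, 2)
            A = rng.normal(0, 0.5, (2, 2))
            Sigma = A @ A.T + 0.5 * I2
            lo, hi = -14, 14
            g = np.linspace(lo, hi, 281)
            h = g[1] - g[0]
            xx, yy = np.meshgrid(g, g)
            pts = np.column_stack([xx.ravel(), yy.ravel()])
            vals = np.exp(log_density(pts, p, mu1, mu2, np.zeros(2), np.zeros(2), Sigma))
            assert vals.sum() * h * h == pytest.approx(1.0, abs=1e-3)


class TestGibbs:
    def test_conjugate_beta_oracle(self, rng):
        # all parameters but (z, p) frozen at truth; with 10-SD separation z
        # recovers the generating labels, so p | z ~ Beta(1 + n1, 2 + n2)
        x, z_true = _separated_data(rng)
        B, n2 = 30, 8
        draws = fit_mcmc(
            x,
            mcmc=MCMCConfig(n_chains=1, n_iterations=4000, burn_in=500, seed=3),
            sample={"mu": False, "a": False, "re_var": False, "Sigma": False},
            init={
                "mu": np.array([[0.0, 0.0], [-10.0, -10.0]]),
                "a": np.zeros((B, 2)),
                "sig2": np.zeros(2),
                "Sigma": I2,
            },
        )
        post = stats.beta(1 + (B - n2), 2 + n2)
        p = draws.p.ravel()
        import arviz as az

        ess = float(az.ess(az.convert_to_dataset(draws.p))["x"])
        se_mean = p.std(ddof=1) / np.sqrt(ess)
        assert abs(p.mean() - post.mean()) < 3 * se_mean
        se_var = p.var(ddof=1) * np.sqrt(2.0 / (ess - 1))
        assert abs(p.var(ddof=1) - post.var()) < 3 * se_var

    def test_parameter_recovery_separated(self):
        cfg = tm.CohortSimConfig(
            mu1=(-1.0, -1.0), mu2=(-8.0, -8.0), sigma1=0.5, sigma2=0.5, seed=21
        )
        zs, truth = tm.simulate_zscore_cohort(cfg)
        model = tm.TractMixture(
            n_chains=2, n_iterations=2500, burn_in=500, random_state=2
        ).fit(zs)
        prob = model.prob_group2_
        assert np.all((prob > 0.9) | (prob < 0.1))
        np.testing.assert_array_equal(model.labels_, truth.z)

    def test_single_tract_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_mcmc(rng.normal(size=(1, 7, 2)))

    def test_same_seed_reproducible(self, rng):
        x, _ = _separated_data(rng)
        mcmc = MCMCConfig(n_chains=2, n_iterations=400, burn_in=100, seed=9)
        d1 = fit_mcmc(x, mcmc=mcmc)
        d2 = fit_mcmc(x, mcmc=mcmc)
        np.testing.assert_array_equal(d1.z, d2.z)
        np.testing.assert_array_equal(d1.mu, d2.mu)

    def test_ordering_constraint_holds_in_every_draw(self, fitted_model):
        mu = fitted_model.draws_.mu
        assert np.all(mu[..., 1, :].sum(-1) <= mu[..., 0, :].sum(-1) + 1e-12)

    def test_empty_tract_excluded_with_warning(self, rng):
        x, _ = _separated_data(rng, B=10)
        x[3] = np.nan
        with pytest.warns(UserWarning, match="excluded"):
            draws = fit_mcmc(
                x, mcmc=MCMCConfig(n_chains=1, n_iterations=300, burn_in=100, seed=1)
            )
        assert draws.z.shape[-1] == 9

    def test_missing_cells_dropped_as_whole_observations(self, rng):
        x, _ = _separated_data(rng, B=10)
        x[0, 0, 0] = np.nan  # FA missing -> whole (FA, MD) pair unused
        draws = fit_mcmc(
            x, mcmc=MCMCConfig(n_chains=1, n_iterations=300, burn_in=100, seed=1)
        )
        assert np.isfinite(draws.p).all()


class TestSummaries:
    def _draws(self, z):
        C, D, B = z.shape
        return PosteriorDraws(
            p=np.full((C, D), 0.5),
            mu=np.zeros((C, D, 2, 2)),
            sigma_re=np.ones((C, D, 2)),
            Sigma=np.tile(I2, (C, D, 1, 1)),
            z=z.astype(np.uint8),
            a=np.zeros((C, D, B, 2)),
            tract_names=[f"t{b}" for b in range(B)],
        )

    def test_membership_is_draw_fraction(self):
        z = np.ones((1, 1000, 2), dtype=int)
        z[0, :700, 0] = 2
        post = membership_probabilities(self._draws(z))
        assert post["prob_group2"].iloc[0] == pytest.approx(0.70)
        assert post["prob_group2"].iloc[1] == 0.0
        assert post["label"].tolist() == [2, 1]

    def test_classification_rule(self):
        labels = classify([0.693, 0.465, 0.206, 0.5, 0.501])
        assert labels.tolist() == [2, 1, 1, 1, 2]
        with pytest.raises(ValueError):
            classify([1.2])

    def test_probability_invariant_to_chain_permutation(self, fitted_model):
        d = fitted_model.draws_
        flipped = PosteriorDraws(
            p=d.p[::-1], mu=d.mu[::-1], sigma_re=d.sigma_re[::-1],
            Sigma=d.Sigma[::-1], z=d.z[::-1], a=d.a[::-1],
            tract_names=d.tract_names,
        )
        np.testing.assert_allclose(
            membership_probabilities(flipped)["prob_group2"],
            fitted_model.posterior_["prob_group2"],
        )


class TestDiagnostics:
    def test_identical_chains_have_rhat_one(self, rng):
        x, _ = _separated_data(rng)
        d = fit_mcmc(x, mcmc=MCMCConfig(n_chains=1, n_iterations=600, burn_in=100, seed=4))
        twin = PosteriorDraws(
            p=np.vstack([d.p, d.p]), mu=np.concatenate([d.mu, d.mu]),
            sigma_re=np.concatenate([d.sigma_re, d.sigma_re]),
            Sigma=np.concatenate([d.Sigma, d.Sigma]),
            z=np.concatenate([d.z, d.z]), a=np.concatenate([d.a, d.a]),
            tract_names=d.tract_names,
        )
        diag = convergence_diagnostics(twin)
        p_rhat = diag.loc[diag["parameter"] == "p", "rhat"].iloc[0]
        assert p_rhat == pytest.approx(1.0, abs=5e-3)

    def test_independent_draws_have_low_rhat(self, rng):
        arr = rng.standard_normal((2, 10_000))
        d = PosteriorDraws(
            p=arr, mu=np.zeros((2, 10_000, 2, 2)) + arr[..., None, None],
            sigma_re=np.ones((2, 10_000, 2)), Sigma=np.tile(I2, (2, 10_000, 1, 1)),
            z=np.ones((2, 10_000, 3), dtype=np.uint8), a=np.zeros((2, 10_000, 3, 2)),
            tract_names=["a", "b", "c"],
        )
        diag = convergence_diagnostics(d)
        assert diag.loc[diag["parameter"] == "p", "rhat"].iloc[0] < 1.01

    def test_constant_chain_flagged_degenerate(self):
        d = PosteriorDraws(
            p=np.full((2, 50), 0.4), mu=np.zeros((2, 50, 2, 2)),
            sigma_re=np.ones((2, 50, 2)), Sigma=np.tile(I2, (2, 50, 1, 1)),
            z=np.ones((2, 50, 3), dtype=np.uint8), a=np.zeros((2, 50, 3, 2)),
            tract_names=["a", "b", "c"],
        )
        diag = convergence_diagnostics(d)
        assert diag["degenerate"].all()
        assert diag["rhat"].isna().all()

    def test_single_chain_omits_rhat_with_warning(self, rng):
        x, _ = _separated_data(rng)
        d = fit_mcmc(x, mcmc=MCMCConfig(n_chains=1, n_iterations=400, burn_in=100, seed=4))
        with pytest.warns(UserWarning, match="single chain"):
            diag = convergence_diagnostics(d)
        assert diag["rhat"].isna().all()
        assert diag.loc[~diag["degenerate"], "ess"].notna().all()


class TestSensitivity:
    def test_baseline_only_grid_agrees_fully(self, rng):
        x, _ = _separated_data(rng)
        mcmc = MCMCConfig(n_chains=1, n_iterations=500, burn_in=100, seed=6)
        spec = MixtureModelSpec()
        out = sensitivity_analysis(x, spec, mcmc, prior_grid=[{}])
        assert out["agrees"].all()

    def test_grid_point_failure_recorded_not_raised(self, rng):
        x, _ = _separated_data(rng)
        mcmc = MCMCConfig(n_chains=1, n_iterations=300, burn_in=100, seed=6)
        out = sensitivity_analysis(
            x, MixtureModelSpec(), mcmc, prior_grid=[{"wishart_scale": -1.0}]
        )
        assert (out["error"] != "").all()
        assert not out["agrees"].any()

    def test_shape_is_tracts_by_grid_points(self, rng):
        x, _ = _separated_data(rng, B=12)
        mcmc = MCMCConfig(n_chains=1, n_iterations=300, burn_in=100, seed=6)
        grid = [{"wishart_scale": s} for s in (1e-5, 1e-3)]
        out = sensitivity_analysis(x, MixtureModelSpec(), mcmc, prior_grid=grid)
        assert len(out) == 12 * 2
        assert set(out["grid_point"]) == {0, 1}


class TestEstimatorApi:
    def test_get_set_params_roundtrip(self):
        m = tm.TractMixture(n_iterations=500)
        params = m.get_params()
        assert params["n_iterations"] == 500
        m.set_params(wishart_scale=1e-3)
        assert m.wishart_scale == 1e-3

    def test_fit_predict_returns_labels(self, rng):
        x, z_true = _separated_data(rng)
        labels = tm.TractMixture(
            n_chains=1, n_iterations=600, burn_in=200, random_state=0
        ).fit_predict(x)
        np.testing.assert_array_equal(labels, z_true)

    def test_accepts_tidy_dataframe(self, cohort48):
        _, zs, _ = cohort48
        m = tm.TractMixture(n_chains=1, n_iterations=300, burn_in=100).fit(zs)
        assert len(m.tract_names_) == 48
        assert set(m.labels_) <= {1, 2}
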