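"""Laplace inner step, evidence, and full fits on simulated data."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.integrate import dblquad, quad

from stlgcp import ModelSpec, SimulationScenario, augment_likelihood, simulate_pattern
from stlgcp.inference import (
    GaussianPseudoLikelihood,
    LGCPModel,
    PoissonAugLikelihood,
    extract_components,
    fit,
    gaussian_approx,
)


class TestGaussianApprox:
    def test_intercept_only_mode_is_log_count(self):
        """One node row (y=0, a=1) + 5 event rows: mode solves 5 = e^η."""
        B = sp.csr_matrix(np.ones((6, 1)))
        lik = PoissonAugLikelihood(
            y=np.array([0.0, 1, 1, 1, 1, 1]), a=np.array([1.0, 0, 0, 0, 0, 0])
        )
        ga = gaussian_approx(B, lik, sp.csc_matrix([[1e-10]]), gtol=1e-10)
        assert ga.mode[0] == pytest.approx(np.log(5.0), abs=1e-8)

    def test_gaussian_likelihood_single_newton_step_is_gls(self):
        rng = np.random.default_rng(0)
        B = sp.csr_matrix(rng.normal(size=(12, 3)))
        w = rng.uniform(0.5, 2.0, 12)
        yobs = rng.normal(size=12)
        Qp = sp.csc_matrix(0.5 * np.eye(3))
        ga = gaussian_approx(B, GaussianPseudoLikelihood(yobs, w), Qp)
        gls = np.linalg.solve(
            Qp.toarray() + (B.T @ sp.diags(w) @ B).toarray(), B.T @ (w * yobs)
        )
        assert ga.n_iter <= 2
        np.testing.assert_allclose(ga.mode, gls, atol=1e-12)

    def test_mode_invariant_to_latent_permutation(self):
        rng = np.random.default_rng(1)
        B = sp.csr_matrix(np.abs(rng.normal(size=(20, 4))))
        y = (rng.random(20) < 0.4).astype(float)
        a = np.where(y == 0, rng.uniform(0.5, 1.5, 20), 0.0)
        Qp = sp.csc_matrix(np.eye(4))
        perm = np.array([2, 0, 3, 1])
        ga1 = gaussian_approx(B, PoissonAugLikelihood(y, a), Qp, gtol=1e-10)
        ga2 = gaussian_approx(B[:, perm], PoissonAugLikelihood(y, a), Qp, gtol=1e-10)
        np.testing.assert_allclose(ga1.mode[perm], ga2.mode, atol=1e-8)

    def test_two_node_poisson_matches_dense_quadrature(self):
        """Data-rich 2-node toy: Laplace mean/sd within 1% of exact posterior."""
        Qp = np.array([[1.0, -0.3], [-0.3, 1.0]])
        # node exposures 1, counts 50 and 40 → posterior nearly Gaussian
        y = np.concatenate([[0.0, 0.0], np.ones(90)])
        a = np.concatenate([[1.0, 1.0], np.zeros(90)])
        rows = np.zeros((92, 2))
        rows[0, 0] = rows[1, 1] = 1.0
        rows[2:52, 0] = 1.0
        rows[52:, 1] = 1.0
        B = sp.csr_matrix(rows)
        ga = gaussian_approx(B, PoissonAugLikelihood(y, a), sp.csc_matrix(Qp), gtol=1e-12)

        def unnorm(x1, x2):
            x = np.array([x1, x2])
            eta = rows @ x
            return np.exp(y @ eta - a @ np.exp(eta) - 0.5 * x @ Qp @ x)

        lo, hi = 2.0, 6.0
        Z = dblquad(lambda b, a_: unnorm(a_, b), lo, hi, lo, hi)[0]
        m1 = dblquad(lambda b, a_: a_ * unnorm(a_, b), lo, hi, lo, hi)[0] / Z
        m2 = dblquad(lambda b, a_: b * unnorm(a_, b), lo, hi, lo, hi)[0] / Z
        s1 = np.sqrt(dblquad(lambda b, a_: a_**2 * unnorm(a_, b), lo, hi, lo, hi)[0] / Z - m1**2)
        s2 = np.sqrt(dblquad(lambda b, a_: b**2 * unnorm(a_, b), lo, hi, lo, hi)[0] / Z - m2**2)
        sd = np.sqrt(np.diag(np.linalg.inv(ga.Q_post.toarray())))
        assert ga.mode[0] == pytest.approx(m1, rel=0.01)
        assert ga.mode[1] == pytest.approx(m2, rel=0.01)
        assert sd[0] == pytest.approx(s1, rel=0.01)
        assert sd[1] == pytest.approx(s2, rel=0.01)


class TestEvidence:
    def _toy_model(self, seed=0, **spec_kw):
        scen = SimulationScenario(
            window=__import__("shapely").geometry.Polygon([(0, 0), (4, 0), (4, 4), (0, 4)]),
            T=8, max_edge_inner=1.5, extension_fraction=0.0, intercept=1.5,
            trend_path=np.linspace(1, -1, 8) ** 2, seasonal_path=np.tile([-0.2, 0.0, 0.1, 0.1], 2),
            seed=seed,
        )
        pat, truth = simulate_pattern(scen)
        spec = ModelSpec(use_cycle=False, use_field=False, **spec_kw)
        data = augment_likelihood(pat, truth["mesh"], truth["weights"])
        return LGCPModel.build(pat, truth["mesh"], truth["fem"], truth["weights"], data, spec), truth

    def test_conjugate_gaussian_evidence_closed_form(self):
        """Gaussian pseudo-likelihood, 1-D latent: Laplace is exact."""
        w = np.array([2.0, 1.0, 0.5])
        yobs = np.array([0.3, -0.2, 0.8])
        q0 = 1.7
        B = sp.csr_matrix(np.ones((3, 1)))
        lik = GaussianPseudoLikelihood(yobs, w)
        ga = gaussian_approx(B, lik, sp.csc_matrix([[q0]]), gtol=1e-12)
        laplace = (
            lik.loglik(B @ ga.mode)
            - 0.5 * ga.prior_quad
            + 0.5 * np.log(q0)
            - 0.5 * ga.logdet_post
        )
        # closed form: ∫ N(y; η1, W⁻¹) N(η; 0, 1/q0) dη
        exact = np.log(
            quad(
                lambda e: np.exp(lik.loglik(np.full(3, e)) - 0.5 * q0 * e**2)
                * np.sqrt(q0 / (2 * np.pi)),
                -10, 10,
            )[0]
        )
        assert laplace == pytest.approx(exact, abs=1e-8)

    def test_evidence_lower_for_sign_flipped_phi(self):
        """Flipping the sign of the group AR coefficient lowers the evidence."""
        from shapely.geometry import Polygon

        from stlgcp import MaternParams

        scen = SimulationScenario(
            window=Polygon([(0, 0), (6, 0), (6, 6), (0, 6)]),
            T=6, max_edge_inner=1.6, extension_fraction=0.0, intercept=1.2,
            matern=MaternParams.from_sigma_rho(1.0, 2.0), group_phi=0.8, seed=5,
        )
        pat, truth = simulate_pattern(scen)
        spec = ModelSpec(use_trend=False, use_seasonal=False, use_cycle=False)
        data = augment_likelihood(pat, truth["mesh"], truth["weights"])
        model = LGCPModel.build(
            pat, truth["mesh"], truth["fem"], truth["weights"], data, spec
        )
        z_true = np.arctanh(0.8)
        base = np.array([scen.matern.log_tau, scen.matern.log_kappa, z_true])
        flipped = base.copy()
        flipped[2] = -z_true
        lp_true, _ = model.log_marginal(base)
        lp_flip, _ = model.log_marginal(flipped)
        assert lp_flip < lp_true

    def test_deterministic_given_theta(self):
        model, _ = self._toy_model(seed=3)
        theta = model.hyper.initial(model.priors)
        lp1, _ = model.log_marginal(theta)
        lp2, _ = model.log_marginal(theta)
        assert lp1 == lp2


@pytest.fixture(scope="module")
def trend_fit():
    from shapely.geometry import Polygon

    scen = SimulationScenario(
        window=Polygon([(0, 0), (10, 0), (10, 10), (0, 10)]),
        T=16, max_edge_inner=2.5, extension_fraction=0.0, intercept=1.0,
        trend_path=-np.abs(np.arange(16) - 8.0) / 4.0,
        seasonal_path=np.tile([-0.3, -0.1, 0.2, 0.2], 4),
        cycle_pacf=(0.3, -0.35), cycle_sd=0.1, seed=3,
    )
    pat, truth = simulate_pattern(scen)
    data = augment_likelihood(pat, truth["mesh"], truth["weights"])
    model = LGCPModel.build(
        pat, truth["mesh"], truth["fem"], truth["weights"], data,
        ModelSpec(use_field=False),
    )
    return fit(model, seed=1), truth, model


class TestFit:
    def test_trend_recovered(self, trend_fit):
        res, truth, _ = trend_fit
        tr = res.components.query("component=='trend'")["mean"].to_numpy()
        assert np.corrcoef(tr, truth["mu"])[0, 1] > 0.9

    def test_trend_sum_to_zero_constraint(self, trend_fit):
        res, _, _ = trend_fit
        tr = res.components.query("component=='trend'")["mean"].to_numpy()
        assert abs(tr.sum()) < 1e-6

    def test_quantiles_ordered_and_contain_mean(self, trend_fit):
        res, _, _ = trend_fit
        for df in (res.hyperparameters, res.fixed_effects, res.components):
            assert (df["q025"] <= df["q50"]).all()
            assert (df["q50"] <= df["q975"]).all()
            assert (df["q025"] <= df["mean"]).all() and (df["mean"] <= df["q975"]).all()

    def test_predicted_totals_track_observed(self, trend_fit):
        res, _, _ = trend_fit
        t = res.totals
        inside = (t["observed"] >= t["q025"]) & (t["observed"] <= t["q975"])
        assert inside.mean() >= 0.8

    def test_refit_same_seed_bit_identical(self, trend_fit):
        res, _, model = trend_fit
        res2 = fit(model, seed=1)
        assert res.hyperparameters.equals(res2.hyperparameters)
        assert res.totals.equals(res2.totals)
        np.testing.assert_array_equal(res.latent_mean, res2.latent_mean)

    def test_extract_components_structure(self, trend_fit):
        res, _, _ = trend_fit
        out = extract_components(res)
        assert set(out["components"]["component"]) == {"trend", "seasonal", "cycle"}
        assert "field" not in out  # field disabled → absent, not an error
        assert {"observed", "mean", "q025", "q975"} <= set(out["totals"].columns)

    def test_grid_strategy_close_to_eb(self, trend_fit):
        res, _, model = trend_fit
        res_g = fit(model, strategy="grid", seed=1)
        # same mode; grid only reweights uncertainty
        np.testing.assert_allclose(res_g.theta_mode, res.theta_mode)
        assert (res_g.hyperparameters["sd"] >= 0.5 * res.hyperparameters["sd"]).all()


class TestFieldRecovery:
    def test_beta_and_phi_recovered_within_three_sd(self):
        """Simulation → fit round trip on the Amazon-like preset (field only)."""
        from stlgcp import amazon_like_scenario

        scen = amazon_like_scenario(
            seed=1, trend_path=None, seasonal_path=None, seasonal_sd=0.0,
            seasonal_init=np.zeros(4), cycle_pacf=None, cycle_sd=0.0,
        )
        pat, truth = simulate_pattern(scen)
        spec = ModelSpec(use_trend=False, use_seasonal=False, use_cycle=False)
        data = augment_likelihood(
            pat, truth["mesh"], truth["weights"], covariates=truth["covariates"]
        )
        model = LGCPModel.build(
            pat, truth["mesh"], truth["fem"], truth["weights"], data, spec,
            covariates=truth["covariates"],
        )
        res = fit(model, seed=1)
        for name, bt in zip(["cont_1", "cont_2", "dist_road"], truth["beta"]):
            row = res.fixed_effects.loc[name]
            assert abs(row["mean"] - bt) <= 3 * row["sd"]
        phi_row = res.hyperparameters.loc["group_phi"]
        assert abs(phi_row["mean"] - scen.group_phi) <= 3 * phi_row["sd"]
        # spatial field surface recovered: correlation with truth's time-average
        xi_true = truth["xi"].mean(axis=0)
        assert np.corrcoef(res.field["mean"], xi_true)[0, 1] > 0.5
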