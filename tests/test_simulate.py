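"""Synthetic-data generator: component paths, field, covariates, patterns."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from stlgcp import (
    MaternParams,
    SimulationScenario,
    amazon_like_scenario,
    build_mesh,
    simulate_components,
    simulate_covariates,
    simulate_field,
    simulate_pattern,
)
from stlgcp.errors import ResourceError, SpecError


@pytest.fixture(scope="module")
def square10():
    return Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])


@pytest.fixture(scope="module")
def mesh(square10):
    return build_mesh(square10, 2.0, extension_fraction=0.0)


def make_scenario(square10, **kw):
    defaults = dict(window=square10, T=8, max_edge_inner=2.0,
                    extension_fraction=0.0, seed=0)
    defaults.update(kw)
    return SimulationScenario(**defaults)


class TestComponents:
    def test_noiseless_rw2_with_linear_init_is_linear(self, square10):
        scen = make_scenario(square10, trend_sd=0.0, trend_init=(1.0, 0.5))
        mu, _, _ = simulate_components(scen)
        second_diff = np.diff(mu, n=2)
        np.testing.assert_allclose(second_diff, 0.0, atol=1e-12)
        assert mu.mean() == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_seasonal_repeats_initial_phases(self, square10):
        scen = make_scenario(
            square10, seasonal_phi=1.0, seasonal_sd=0.0,
            seasonal_init=np.array([1.0, -1.0, 2.0, -2.0]),
        )
        _, s, _ = simulate_components(scen)
        np.testing.assert_allclose(s[4:], s[:4], atol=1e-12)

    def test_cycle_autocorrelation_oscillates(self, square10):
        """PACF (0.308, −0.366) implies complex roots: the ACF must go negative."""
        from statsmodels.tsa.arima_process import arma_acf

        from stlgcp.temporal import ar2_from_pacf

        scen = make_scenario(
            square10, T=400, cycle_pacf=(0.308, -0.366), cycle_sd=0.5, seed=7
        )
        _, _, c = simulate_components(scen)
        sample_acf = np.array(
            [np.corrcoef(c[:-k], c[k:])[0, 1] for k in range(1, 5)]
        )
        th = ar2_from_pacf(0.308, -0.366)
        oracle = arma_acf([1, -th[0], -th[1]], [1], lags=5)[1:]
        assert sample_acf[1] < 0  # negative lag-2 region
        np.testing.assert_allclose(sample_acf, oracle, atol=0.12)

    def test_reproducible_under_seed(self, square10):
        scen = make_scenario(square10, trend_sd=0.3, seasonal_sd=0.2,
                             cycle_pacf=(0.3, -0.3), cycle_sd=0.2, seed=42)
        a = simulate_components(scen)
        b = simulate_components(scen)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestField:
    def test_phi_zero_periods_independent(self, square10, mesh):
        scen = make_scenario(square10, T=6, matern=MaternParams.from_sigma_rho(1.0, 3.0),
                             group_phi=0.0)
        cors = []
        for seed in range(60):
            xi = simulate_field(scen, mesh, rng=seed)
            cors.append(np.corrcoef(xi[0], xi[1])[0, 1])
        assert abs(np.mean(cors)) < 0.1

    def test_stationary_variance_constant_over_periods(self, square10, mesh):
        scen = make_scenario(square10, T=5, matern=MaternParams.from_sigma_rho(1.0, 3.0),
                             group_phi=0.8)
        xis = np.stack([simulate_field(scen, mesh, rng=seed) for seed in range(150)])
        per_period_var = xis.var(axis=(0, 2))
        ratio = per_period_var / per_period_var[0]
        np.testing.assert_allclose(ratio, 1.0, atol=0.15)

    def test_lag1_autocorrelation_matches_phi(self, square10, mesh):
        phi = 0.8
        scen = make_scenario(square10, T=8, matern=MaternParams.from_sigma_rho(1.0, 3.0),
                             group_phi=phi)
        num = den = 0.0
        for seed in range(100):
            xi = simulate_field(scen, mesh, rng=seed)
            num += np.sum(xi[:-1] * xi[1:])
            den += np.sum(xi[:-1] ** 2)
        assert num / den == pytest.approx(phi, abs=0.03)


class TestCovariates:
    def test_class_field_partitions_nodes(self, square10, mesh):
        scen = make_scenario(square10, n_classes=3)
        cov = simulate_covariates(scen, mesh)
        onehot = cov.node_values[0, :, :2]
        assert set(np.unique(onehot)) <= {0.0, 1.0}
        assert (onehot.sum(axis=1) <= 1).all()  # reference class is all-zero rows

    def test_continuous_fields_standardised(self, square10, mesh):
        scen = make_scenario(square10, n_continuous=2)
        cov = simulate_covariates(scen, mesh)
        for j in range(2):
            vals = cov.node_values[:, :, j]
            assert vals.mean() == pytest.approx(0.0, abs=1e-8)
            assert vals.std() == pytest.approx(1.0, abs=1e-8)

    def test_distance_zero_on_polyline_nodes(self, square10, mesh):
        node = mesh.vertices[10]
        scen = make_scenario(
            square10, polyline=np.array([node - [0.0, 1.0], node, node + [0.0, 1.0]])
        )
        cov = simulate_covariates(scen, mesh)
        j = cov.names.index("dist_road")
        assert cov.node_values[0, 10, j] == pytest.approx(0.0, abs=1e-12)
        assert cov.node_values[0, :, j].min() >= 0

    def test_single_class_rejected(self, square10, mesh):
        with pytest.raises(SpecError):
            simulate_covariates(make_scenario(square10, n_classes=1), mesh)


class TestPattern:
    def test_constant_intensity_mean_count(self, square10):
        """λ = 50/100 per km² on a 10×10 window: mean count over seeds ≈ 50."""
        scen = make_scenario(square10, T=1, intercept=np.log(0.5), seed=0)
        counts = [simulate_pattern(scen, seed=s)[0].n_events for s in range(200)]
        assert np.mean(counts) == pytest.approx(50.0, abs=1.5)

    def test_intercept_shift_doubles_expected_count(self, square10):
        base = make_scenario(square10, T=1, intercept=np.log(0.5))
        double = make_scenario(square10, T=1, intercept=np.log(1.0))
        c1 = np.mean([simulate_pattern(base, seed=s)[0].n_events for s in range(150)])
        c2 = np.mean([simulate_pattern(double, seed=s)[0].n_events for s in range(150)])
        assert c2 / c1 == pytest.approx(2.0, abs=0.15)

    def test_per_cell_counts_match_poisson_moments(self, square10):
        """Mean per-dual-cell counts over seeds ≈ α_k · exp(λ_k)."""
        from stlgcp.mesh import projection_matrix

        scen = make_scenario(square10, T=1, intercept=np.log(0.8), seed=0)
        _, truth = simulate_pattern(scen, seed=0)
        mesh, w = truth["mesh"], truth["weights"]
        expected = w * np.exp(truth["log_intensity"][0])
        counts = np.zeros(mesh.n_vertices)
        n_rep = 150
        for s in range(n_rep):
            pat, _ = simulate_pattern(scen, seed=s)
            if pat.n_events == 0:
                continue
            A = projection_matrix(mesh, np.column_stack([pat.x, pat.y]))
            # assign each event to its nearest node's cell
            counts += np.bincount(
                np.asarray(A.argmax(axis=1)).ravel(), minlength=mesh.n_vertices
            )
        mean_counts = counts / n_rep
        # aggregate over cells to damp MC noise: compare deciles of expectation
        order = np.argsort(expected)
        for chunk in np.array_split(order, 5):
            assert mean_counts[chunk].sum() == pytest.approx(
                expected[chunk].sum(), rel=0.15, abs=0.5
            )

    def test_expected_count_cap_enforced(self, square10):
        scen = make_scenario(square10, T=1, intercept=20.0, max_expected_events=1e4)
        with pytest.raises(ResourceError):
            simulate_pattern(scen)

    def test_truth_bundle_complete_and_reproducible(self, square10):
        scen = make_scenario(square10, T=8, trend_sd=0.1, seasonal_sd=0.1,
                             seasonal_init=np.zeros(4),
                             matern=MaternParams.from_sigma_rho(0.5, 3.0),
                             group_phi=0.5, n_continuous=1, beta=(0.2,), seed=9)
        pat1, truth1 = simulate_pattern(scen)
        pat2, truth2 = simulate_pattern(scen)
        np.testing.assert_array_equal(pat1.x, pat2.x)
        np.testing.assert_array_equal(truth1["xi"], truth2["xi"])
        lam = (scen.intercept + truth1["mu"][:, None] + truth1["s"][:, None]
               + truth1["c"][:, None] + truth1["xi"]
               + truth1["covariates"].node_values @ truth1["beta"])
        np.testing.assert_allclose(lam, truth1["log_intensity"], atol=1e-12)


class TestAmazonPreset:
    def test_preset_shape_and_signs(self):
        scen = amazon_like_scenario(seed=1)
        assert scen.T == 8 and scen.frequency == "quarterly"
        # V-shaped trend: decline then rise
        mu = np.asarray(scen.trend_path)
        k = mu.argmin()
        assert 0 < k < len(mu) - 1
        # dry-season peak in periods 3-4
        s = np.asarray(scen.seasonal_path[:4])
        assert s[2] > s[0] and s[3] > s[1]
        # temperature +, rainfall −, distance −
        assert scen.beta[0] > 0 and scen.beta[1] < 0 and scen.beta[2] < 0
        assert abs(scen.group_phi) < 1

    def test_preset_simulates_reasonable_pattern(self):
        pat, truth = simulate_pattern(amazon_like_scenario(seed=4))
        assert pat.T == 8
        assert 100 < pat.n_events < 20000
        assert truth["mesh"].n_vertices > 100
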