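"""Forward sensitivities, sparse-grid averaging and bifurcation scans."""

import numpy as np
import pytest
from scipy.special import roots_legendre

import pymt_tme as pt
from pymt_tme.ode import N_VARS, VAR_INDEX
from pymt_tme.parameters import N_PARAMS, PARAM_NAMES

PIDX = {n: i for i, n in enumerate(PARAM_NAMES)}


class TestForwardSensitivities:
    def test_zero_horizon_gives_zero_sensitivities(self, table3, model):
        S = pt.forward_sensitivities(table3, model.initial_state(1),
                                     horizon=0.0)
        np.testing.assert_array_equal(S, 0.0)

    def test_pure_decay_closed_form(self):
        # isolate the regulatory equation: dx/dt = -delta*x, x(0)=1
        # => dx/d(delta) = -t exp(-delta t) = -3.67879 at delta=0.1, t=10
        theta = np.zeros(N_PARAMS)
        theta[PIDX["delta_Tr"]] = 0.1
        x0 = np.zeros(N_VARS)
        x0[VAR_INDEX["T_r"]] = 1.0
        S = pt.forward_sensitivities(pt.ParameterSet(theta), x0,
                                     horizon=10.0, step=0.01)
        val = S[VAR_INDEX["T_r"], PIDX["delta_Tr"]]
        assert val == pytest.approx(-10.0 * np.exp(-1.0), rel=1e-3)

    def test_euler_convergence_is_first_order(self, table3, model):
        x0 = model.initial_state(1)
        ref = pt.forward_sensitivities(table3, x0, horizon=10, step=0.001)
        errs = [np.linalg.norm(
            pt.forward_sensitivities(table3, x0, horizon=10, step=h) - ref)
            for h in (0.4, 0.2, 0.1)]
        ratios = np.array(errs[:-1]) / np.array(errs[1:])
        assert np.all(ratios > 1.7)  # ~2 for order 1

    def test_matches_finite_differences_of_trajectories(self, table3, model):
        x0 = model.initial_state(1)
        S = pt.forward_sensitivities(table3, x0, horizon=42, step=0.01)
        for name in ("delta_C", "lambda_CA", "delta_A", "lambda_TcD"):
            i = PIDX[name]
            h = table3[name] * 1e-4
            grid = np.array([0.0, 42.0])
            xp = pt.integrate(table3.replace(**{name: table3[name] + h}),
                              x0, 42, grid, rtol=1e-10, atol=1e-12).states[-1]
            xm = pt.integrate(table3.replace(**{name: table3[name] - h}),
                              x0, 42, grid, rtol=1e-10, atol=1e-12).states[-1]
            fd = (xp - xm) / (2 * h)
            err = np.linalg.norm(S[:, i] - fd) / np.linalg.norm(fd)
            assert err < 1e-3, name

    def test_batched_equals_sequential(self, table3, model):
        x0 = model.initial_state(1)
        thetas = np.vstack([table3.values, table3.values * 1.05])
        S = pt.forward_sensitivities(thetas, x0, horizon=5, step=0.05)
        S0 = pt.forward_sensitivities(thetas[0], x0, horizon=5, step=0.05)
        S1 = pt.forward_sensitivities(thetas[1], x0, horizon=5, step=0.05)
        np.testing.assert_allclose(S[0], S0, atol=1e-13)
        np.testing.assert_allclose(S[1], S1, atol=1e-13)


class TestOutputFunctional:
    def test_cancer_is_the_cancer_row(self, rng):
        S = rng.normal(size=(N_VARS, N_PARAMS))
        np.testing.assert_array_equal(
            pt.output_functional(S, "cancer"), S[VAR_INDEX["C"]])

    def test_total_cells_weights_without_scales(self, rng):
        S = rng.normal(size=(N_VARS, N_PARAMS))
        got = pt.output_functional(S, "total_cells")
        expect = (S.sum(axis=0) - S[VAR_INDEX["T_N"]]
                  - 0.8 * S[VAR_INDEX["M_N"]]
                  - S[VAR_INDEX["H"]] - S[VAR_INDEX["IL12"]]
                  - S[VAR_INDEX["IL10"]] - S[VAR_INDEX["IL6"]])
        np.testing.assert_allclose(got, expect, rtol=1e-12)

    def test_total_cells_matches_trajectory_finite_difference(self, table3,
                                                              model):
        """The projected sensitivity equals the numerical derivative of the
        dimensional total-cell functional along the trajectory."""
        x0 = model.initial_state(1)
        scales = model.scales
        S = pt.forward_sensitivities(table3, x0, horizon=42, step=0.01)
        s = pt.output_functional(S, "total_cells", scales)
        name = "delta_A"
        h = table3[name] * 1e-4
        grid = np.array([0.0, 42.0])
        def tot(ps):
            st = pt.integrate(ps, x0, 42, grid, rtol=1e-10,
                              atol=1e-12).states[-1]
            return pt.total_cells(st * scales.values)
        fd = (tot(table3.replace(**{name: table3[name] + h}))
              - tot(table3.replace(**{name: table3[name] - h}))) / (2 * h)
        assert s[PIDX[name]] == pytest.approx(fd, rel=1e-3)

    def test_unknown_output_rejected(self, rng):
        with pytest.raises(ValueError):
            pt.output_functional(rng.normal(size=(N_VARS, N_PARAMS)), "mass")


class TestSparseGrid:
    def test_weights_sum_to_one_and_node_count(self):
        for d in (2, 10, 57):
            nodes, w = pt.sparse_grid(d)
            assert nodes.shape == (2 * d + 1, d)
            assert w.sum() == pytest.approx(1.0)

    def test_exact_for_separable_cubics(self):
        # the level-1 rule integrates sums of per-coordinate cubics exactly
        nodes, w = pt.sparse_grid(3)
        f = (nodes ** 3 - 0.25 * nodes ** 2 + nodes + 2.0).sum(axis=1)
        # exact average of x^3 - x^2/4 + x + 2 over [-1,1] is -1/12 + 2
        assert w @ f == pytest.approx(3 * (2.0 - 1.0 / 12.0), rel=1e-12)

    def test_two_dim_average_matches_dense_tensor_quadrature(self):
        """On a smooth 2-parameter integrand the sparse average agrees with
        a dense Gauss-Legendre tensor grid to well under 1%."""
        nodes, w = pt.sparse_grid(2)
        g = lambda z: np.exp(0.1 * z[..., 0] + 0.2 * z[..., 1]) \
            / (1.5 + 0.3 * z[..., 0] * z[..., 1])
        sparse_avg = w @ g(nodes)
        xg, wg = roots_legendre(30)
        Z1, Z2 = np.meshgrid(xg, xg, indexing="ij")
        W = np.outer(wg, wg) / 4.0   # normalize to an average
        dense_avg = np.sum(W * g(np.stack([Z1, Z2], axis=-1)))
        assert sparse_avg == pytest.approx(dense_avg, rel=0.01)


class TestNeighborhoodAverage:
    def test_zero_fraction_reduces_to_raw_sensitivity(self, table3, model):
        x0 = model.initial_state(1)
        rep = pt.neighborhood_average(table3, x0, "cancer", fraction=0.0,
                                      horizon=20, step=0.05)
        np.testing.assert_allclose(rep.s_hat, rep.s_raw, rtol=1e-12)
        S = pt.forward_sensitivities(table3, x0, horizon=20, step=0.05)
        np.testing.assert_allclose(rep.s_raw, S[VAR_INDEX["C"]], rtol=1e-12)

    def test_ranking_uses_magnitude_and_keeps_signs(self, table3, model):
        rep = pt.neighborhood_average(table3, model.initial_state(1),
                                      "cancer", horizon=42, step=0.05)
        order = rep.ranking()
        mags = np.abs(rep.s_hat)
        sorted_mags = sorted(mags, reverse=True)
        np.testing.assert_allclose(
            [mags[PIDX[n]] for n in order], sorted_mags)
        # decay of cancer pushes cancer down, growth pulls it up
        assert rep.s_hat[PIDX["delta_C"]] < 0 < rep.s_hat[PIDX["lambda_C"]]

    def test_deterministic_for_fixed_rule(self, table3, model):
        kw = dict(horizon=20, step=0.05)
        r1 = pt.neighborhood_average(table3, model.initial_state(2),
                                     "cancer", **kw)
        r2 = pt.neighborhood_average(table3, model.initial_state(2),
                                     "cancer", **kw)
        np.testing.assert_array_equal(r1.s_hat, r2.s_hat)


class TestBifurcation:
    def test_curve_passes_through_baseline_at_fitted_value(self, table3,
                                                           model):
        inits = {1: model.initial_state(1)}
        fitted = table3["delta_C"]
        curve = pt.bifurcation_scan("delta_C", table3, inits,
                                    np.array([0.0, fitted, 0.2]),
                                    scales=model.scales)
        base = pt.integrate(table3, inits[1], 42,
                            np.array([0.0, 42.0])).states[-1, VAR_INDEX["C"]]
        base *= model.scales["C"]
        assert curve.values[1][1] == pytest.approx(base, rel=1e-6)

    def test_delta_C_scan_monotone_nonincreasing(self, table3, model):
        inits = {m: model.initial_state(m) for m in (1, 2, 3)}
        curve = pt.bifurcation_scan("delta_C", table3, inits,
                                    np.linspace(0, 0.2, 21),
                                    scales=model.scales)
        for v in curve.values.values():
            assert np.all(np.diff(v) <= 1e-9)

    def test_lambda_CA_scan_against_reintegration_oracle(self, table3,
                                                         model):
        """Spot-check scan points by re-integrating at tightened
        tolerances; the curve must be nondecreasing."""
        inits = {1: model.initial_state(1)}
        rng = np.random.default_rng(5)
        grid = np.linspace(0, 0.2, 21)
        curve = pt.bifurcation_scan("lambda_CA", table3, inits, grid,
                                    scales=model.scales)
        assert np.all(np.diff(curve.values[1]) >= -1e-9)
        for i in rng.choice(grid.size, 5, replace=False):
            tight = pt.integrate(table3.replace(lambda_CA=grid[i]),
                                 inits[1], 42, np.array([0.0, 42.0]),
                                 rtol=1e-10, atol=1e-12)
            oracle = tight.states[-1, VAR_INDEX["C"]] * model.scales["C"]
            assert curve.values[1][i] == pytest.approx(oracle, rel=1e-6)

    def test_raw_sign_matches_scan_slope(self, table3, model):
        """Internal consistency: the sign of the raw day-42 sensitivity
        agrees with the local slope of the bifurcation curve."""
        x0 = model.initial_state(1)
        S = pt.forward_sensitivities(table3, x0, horizon=42, step=0.02)
        s = pt.output_functional(S, "cancer")
        for name in ("delta_C", "lambda_C", "lambda_CA", "delta_A"):
            v = table3[name]
            eps = max(v * 0.2, 1e-4)
            curve = pt.bifurcation_scan(name, table3, {1: x0},
                                        np.array([max(v - eps, 0.0), v + eps]))
            slope = np.diff(curve.values[1])[0]
            assert np.sign(slope) == np.sign(s[PIDX[name]]), name

    def test_unknown_parameter_rejected(self, table3, model):
        with pytest.raises(KeyError):
            pt.bifurcation_scan("lambda_bogus", table3,
                                {1: model.initial_state(1)})

    def test_dataframe_export(self, table3, model):
        curve = pt.bifurcation_scan("delta_A", table3,
                                    {1: model.initial_state(1)},
                                    np.linspace(0, 0.2, 5))
        df = curve.to_dataframe()
        assert len(df) == 5 and set(df.columns) >= {"param", "value",
                                                    "mouse", "cancer"}
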