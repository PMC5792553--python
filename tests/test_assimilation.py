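import warnings

import numpy as np
import pytest
import scipy.optimize

import siftwin as st
from siftwin.assimilation import (
    AssimConfig,
    AssimilationError,
    closed_form_posterior,
    cost,
    error_reduction,
    jacobian_fd,
    minimise,
    posterior_covariance,
    propagate_uncertainty,
)
from siftwin.param_space import ParameterDef, ParameterTable
from siftwin.sif_operator import SIFField


def _toy_vector(n=3, prior=0.0, lo=-10.0, hi=10.0):
    """A small unconstrained-ish parameter vector for algebra tests."""
    table = st.default_parameter_table()
    defs = [
        ParameterDef(f"p{i}", "photosynthesis", "-", frozenset({2}), prior, lo, hi)
        for i in range(n)
    ]
    tab = ParameterTable(defs=defs, pfts=table.pfts)
    return st.build_parameter_vector(tab, [2])


class TestCost:
    def test_zero_at_prior_with_perfect_fit(self):
        vec = _toy_vector(2)
        y = SIFField(sif=np.array([[1.0, 2.0]]), sigma_obs=1.0)
        model = lambda v: np.array([1.0, 2.0])
        ev = cost(vec, y, np.ones(2), model)
        assert ev.J == 0.0 and ev.J_obs == 0.0 and ev.J_prior == 0.0

    def test_scalar_half_residual_squared(self):
        vec = _toy_vector(1)
        y = SIFField(sif=np.array([[1.0]]), sigma_obs=1.0)
        ev = cost(vec, y, np.ones(1), lambda v: np.array([2.0]))
        assert ev.J == pytest.approx(0.5)
        assert ev.residuals == pytest.approx([1.0])

    def test_one_sigma_prior_displacement_adds_half(self):
        vec = _toy_vector(1)
        y = SIFField(sif=np.array([[0.0]]), sigma_obs=1.0)
        model = lambda v: np.array([0.0])
        j0 = cost(vec, y, np.ones(1), model).J
        vec.values[0] = vec.prior[0] + vec.prior_sigma[0]
        j1 = cost(vec, y, np.ones(1), model).J
        assert j1 - j0 == pytest.approx(0.5)

    def test_decomposition(self):
        vec = _toy_vector(2)
        vec.values[:] = vec.prior + 0.3 * vec.prior_sigma
        y = SIFField(sif=np.array([[1.0, -1.0]]), sigma_obs=0.5)
        ev = cost(vec, y, np.full(2, 0.25), lambda v: np.array([0.5, 0.5]))
        assert ev.J == pytest.approx(ev.J_obs + ev.J_prior)
        assert ev.J_obs >= 0 and ev.J_prior >= 0

    def test_misaligned_rejected(self):
        vec = _toy_vector(1)
        y = SIFField(sif=np.array([[1.0, 2.0]]), sigma_obs=1.0)
        with pytest.raises(ValueError, match="misaligned"):
            cost(vec, y, np.ones(2), lambda v: np.array([1.0]))


class TestJacobianFD:
    def test_linear_model_exact(self):
        vec = _toy_vector(3)
        jac = jacobian_fd(lambda v: 3.0 * v, vec)
        assert np.allclose(jac.H, 3.0 * np.eye(3), atol=1e-9)

    def test_quadratic_first_order(self):
        vec = _toy_vector(1, prior=1.0)
        jac = jacobian_fd(lambda v: v**2, vec, step=0.001)
        delta = jac.fd_step[0]
        assert jac.H[0, 0] == pytest.approx(2.0, abs=2 * abs(delta))

    def test_step_flipped_at_upper_bound(self):
        vec = _toy_vector(1, prior=10.0)  # at the upper bound
        jac = jacobian_fd(lambda v: v.copy(), vec)
        assert jac.fd_step[0] < 0
        assert jac.H[0, 0] == pytest.approx(1.0, rel=1e-9)

    def test_nonfinite_rejected(self):
        vec = _toy_vector(1)
        with pytest.raises(AssimilationError):
            jacobian_fd(lambda v: np.array([np.nan]), vec)


class TestMinimise:
    def test_unconstrained_quadratic(self):
        res = minimise(
            lambda x: 0.5 * float((x[0] - 3.0) ** 2),
            lambda x: np.array([x[0] - 3.0]),
            [(0.0, 10.0)],
            np.array([0.5]),
        )
        assert res.x[0] == pytest.approx(3.0, abs=1e-6)
        assert res.converged

    def test_active_bound(self):
        res = minimise(
            lambda x: 0.5 * float((x[0] - 3.0) ** 2),
            lambda x: np.array([x[0] - 3.0]),
            [(0.0, 2.0)],
            np.array([0.5]),
        )
        assert res.x[0] == pytest.approx(2.0, abs=1e-9)

    def test_trajectory_non_increasing(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((8, 4))
        b = rng.standard_normal(8)
        fun = lambda x: 0.5 * float(np.sum((A @ x - b) ** 2))
        grad = lambda x: A.T @ (A @ x - b)
        res = minimise(fun, grad, [(-5, 5)] * 4, np.zeros(4))
        diffs = np.diff(res.trajectory)
        assert np.all(diffs <= 1e-9)

    def test_x0_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            minimise(lambda x: 0.0, lambda x: x, [(0, 1)], np.array([2.0]))

    def test_nonfinite_cost_aborts(self):
        with pytest.raises(AssimilationError, match="non-finite"):
            minimise(
                lambda x: float("nan"), lambda x: x, [(-1, 1)], np.array([0.0])
            )

    def test_linear_gaussian_equivalence(self):
        # dual route: bounded quasi-Newton vs closed-form GLS posterior
        rng = np.random.default_rng(42)
        n_obs, n_par = 12, 4
        H = rng.standard_normal((n_obs, n_par))
        r = rng.uniform(0.2, 2.0, n_obs)
        pb = rng.uniform(0.5, 2.0, n_par)
        xb = rng.standard_normal(n_par)
        y = H @ (xb + rng.standard_normal(n_par)) + rng.standard_normal(n_obs) * 0.1
        x_gls, P_gls = closed_form_posterior(H, r, pb, y, xb)

        def fun(x):
            d = H @ x - y
            return 0.5 * float(d @ (d / r) + (x - xb) @ ((x - xb) / pb))

        def grad(x):
            return H.T @ ((H @ x - y) / r) + (x - xb) / pb

        res = minimise(fun, grad, [(-50, 50)] * n_par, xb, gtol=1e-10, ftol=1e-14)
        assert np.allclose(res.x, x_gls, rtol=1e-6, atol=1e-8)


class TestClosedFormPosterior:
    def test_scalar_equal_weights(self):
        x, P = closed_form_posterior(
            np.array([[1.0]]), np.array([1.0]), np.array([1.0]),
            np.array([1.0]), np.array([0.0]),
        )
        assert x[0] == pytest.approx(0.5)
        assert P[0, 0] == pytest.approx(0.5)

    def test_no_innovation_returns_prior(self):
        rng = np.random.default_rng(0)
        H = rng.standard_normal((6, 3))
        xb = rng.standard_normal(3)
        x, _ = closed_form_posterior(H, np.ones(6), np.ones(3), H @ xb, xb)
        assert np.allclose(x, xb, atol=1e-12)

    def test_matches_direct_minimisation(self):
        # independent oracle: scipy minimises the quadratic cost directly
        rng = np.random.default_rng(3)
        H = rng.standard_normal((5, 3))
        r = rng.uniform(0.5, 1.5, 5)
        pb = rng.uniform(0.5, 1.5, 3)
        xb = rng.standard_normal(3)
        y = rng.standard_normal(5)
        x_gls, _ = closed_form_posterior(H, r, pb, y, xb)

        def fun(x):
            d = H @ x - y
            return 0.5 * (d @ (d / r) + (x - xb) @ ((x - xb) / pb))

        res = scipy.optimize.minimize(fun, xb, method="BFGS", tol=1e-12)
        assert np.allclose(x_gls, res.x, atol=1e-5)


class TestPosteriorCovariance:
    def test_scalar(self):
        P = posterior_covariance(np.array([[1.0]]), np.array([1.0]), np.array([1.0]))
        assert P[0, 0] == pytest.approx(0.5)

    def test_no_information_returns_prior(self):
        P = posterior_covariance(np.zeros((4, 2)), np.ones(4), np.array([2.0, 3.0]))
        assert np.allclose(np.diag(P), [2.0, 3.0])

    def test_perfect_observation_limit(self):
        P = posterior_covariance(np.array([[1.0]]), np.array([1e-12]), np.array([1.0]))
        assert P[0, 0] < 1e-10

    @pytest.mark.parametrize("seed", range(10))
    def test_psd_and_never_exceeds_prior(self, seed):
        rng = np.random.default_rng(seed)
        n_obs, n_par = rng.integers(3, 15), rng.integers(2, 8)
        H = rng.standard_normal((n_obs, n_par)) * rng.uniform(0, 3)
        r = rng.uniform(0.1, 5.0, n_obs)
        pb = rng.uniform(0.1, 5.0, n_par)
        P = posterior_covariance(H, r, pb)
        assert np.allclose(P, P.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(P) >= -1e-10)
        assert np.all(np.diag(P) <= pb + 1e-10)


class TestPropagation:
    def test_identity(self):
        P = np.diag([1.0, 2.0])
        assert np.allclose(propagate_uncertainty(np.eye(2), P), [1.0, 2.0])

    def test_scalar(self):
        assert propagate_uncertainty(np.array([[2.0]]), np.array([[1.0]]))[0] == pytest.approx(4.0)

    def test_rank_one(self):
        h = np.array([[1.0], [2.0], [3.0]])
        out = propagate_uncertainty(h, np.array([[0.5]]))
        assert np.allclose(out, 0.5 * np.array([1.0, 4.0, 9.0]))


class TestErrorReduction:
    def test_reference_global_sigma_case(self):
        # 57.2 -> 9.8 gives 82.9%, vs the printed 82.8% (input rounding)
        assert 100 * error_reduction(57.2, 9.8) == pytest.approx(82.87, abs=0.01)

    def test_no_change_is_zero(self):
        assert error_reduction(2.0, 2.0) == 0.0

    def test_perfect_is_one(self):
        assert error_reduction(2.0, 0.0) == 1.0

    def test_zero_prior_rejected(self):
        with pytest.raises(ValueError):
            error_reduction(0.0, 1.0)


@pytest.fixture(scope="module")
def result(small_scenario):
    vec = st.build_parameter_vector(small_scenario.table)
    sites = st.diagnostics.select_all_sites(
        small_scenario.pft_map, small_scenario.grid.cell_lat, n=4, seed=5
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        res = st.assimilate(
            vec,
            small_scenario.forcing,
            small_scenario.pft_map,
            small_scenario.observations,
            sites,
            AssimConfig(max_outer=2),
        )
    return res


class TestAssimilateSmall:
    def test_truth_at_prior_returns_prior(self, result, small_scenario):
        # observations were generated on the full grid; the forward run on
        # the site subset may equilibrate one spin-up cycle differently, so
        # J is near-zero rather than exactly zero
        vec = st.build_parameter_vector(small_scenario.table)
        n_obs = int(result.obs_mask.sum())
        assert result.cost_trajectory[-1] < 1e-3 * n_obs
        z_post = (result.x_post.values - vec.prior) / vec.prior_sigma
        assert np.max(np.abs(z_post)) < 0.05

    def test_cost_trajectory_non_increasing(self, result):
        assert np.all(np.diff(result.cost_trajectory) <= 1e-9)

    def test_posterior_variance_bounded(self, result, small_scenario):
        vec = st.build_parameter_vector(small_scenario.table)
        assert np.all(np.diag(result.P_post) <= vec.prior_sigma**2 + 1e-10)
        assert np.allclose(result.P_post, result.P_post.T, atol=1e-10)

    def test_error_reductions_in_unit_interval(self, result):
        r = result.error_reduction_params
        assert np.all(r >= -1e-10) and np.all(r <= 1.0 + 1e-10)

    def test_state_uncertainty_never_increases(self, result):
        assert np.all(result.R_post_diag <= result.R_prior_diag + 1e-10)

    def test_no_edge_hitting_at_prior(self, result):
        assert result.edge_hitting == set()

    def test_no_sites_rejected(self, small_scenario):
        vec = st.build_parameter_vector(small_scenario.table)
        with pytest.raises(ValueError, match="site"):
            st.assimilate(
                vec,
                small_scenario.forcing,
                small_scenario.pft_map,
                small_scenario.observations,
                {2: []},
            )
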