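import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from makl.group_lasso import (
    GroupLassoModel,
    GroupStructure,
    fit,
    group_prox,
    kkt_residual,
    lambda_max,
    logistic_objective,
)


def random_instance(rng, N=40, P=3, width=8, informative=1):
    """A small logistic instance with a known sparse generator."""
    Z = rng.standard_normal((N, P * width))
    beta = np.zeros(P * width)
    beta[: informative * width] = rng.standard_normal(informative * width)
    prob = 1.0 / (1.0 + np.exp(-(Z @ beta)))
    y = (rng.random(N) < prob).astype(int)
    if y.min() == y.max():  # re-draw degenerate labels
        y[0] = 1 - y[0]
    return Z, y, GroupStructure.contiguous([width] * P)


def reference_optimum(Z, y, structure, lam):
    """Independent solver: graduated smoothing + L-BFGS-B.

    The group norm is smoothed as sqrt(||b||^2 + mu^2) - mu with mu shrunk
    over stages, each warm-starting the next; the final objective is within
    ~1e-9 of the true minimum on these scales.
    """
    s = 2.0 * np.asarray(y) - 1.0

    def make_f(mu):
        def f(theta):
            b0, b = theta[0], theta[1:]
            fi = b0 + Z @ b
            val = np.logaddexp(0.0, -s * fi).sum()
            sig = -s / (1.0 + np.exp(s * fi))
            grad = np.concatenate([[sig.sum()], Z.T @ sig])
            for sl, w in zip(structure.slices, structure.group_weights):
                b_sl = b[sl]
                nb = np.sqrt(b_sl @ b_sl + mu * mu)
                val += lam * w * (nb - mu)
                grad[1:][sl] += lam * w * b_sl / nb
            return val, grad

        return f

    theta = np.zeros(Z.shape[1] + 1)
    for mu in (1e-2, 1e-4, 1e-6, 1e-9):
        res = minimize(
            make_f(mu), theta, jac=True, method="L-BFGS-B",
            options=dict(maxiter=50000, maxfun=200000, ftol=1e-16,
                         gtol=1e-12),
        )
        theta = res.x
    return res.fun


class TestGroupProx:
    def test_closed_form_shrinkage(self):
        np.testing.assert_allclose(
            group_prox(np.array([3.0, 4.0]), 2.5), [1.5, 2.0]
        )

    def test_boundary_zeroing_is_exact(self):
        out = group_prox(np.array([3.0, 4.0]), 5.0)
        assert out.tolist() == [0.0, 0.0]

    def test_zero_threshold_is_identity(self, rng):
        v = rng.standard_normal(7)
        np.testing.assert_array_equal(group_prox(v, 0.0), v)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            group_prox(np.ones(2), -0.1)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        v=st.lists(st.floats(-50, 50), min_size=1, max_size=6),
        t=st.floats(0, 100),
    )
    def test_prox_never_increases_norm_and_zeroes_exactly(self, v, t):
        v = np.asarray(v, dtype=float)
        out = group_prox(v, t)
        assert np.linalg.norm(out) <= np.linalg.norm(v) + 1e-12
        if t > 0 and np.linalg.norm(v) <= t:
            assert (out == 0.0).all()


class TestObjectiveAndLambdaMax:
    def test_null_model_loss_is_n_log_two(self):
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((10, 4))
        y = np.array([0, 1] * 5)
        st_ = GroupStructure.contiguous([2, 2])
        model = GroupLassoModel(
            intercept=0.0, blocks=[np.zeros(2), np.zeros(2)], lambda_=3.0
        )
        assert logistic_objective(Z, y, model, st_) == pytest.approx(
            10 * np.log(2)
        )

    def test_weight_lambda_scale_equivalence(self, rng):
        Z, y, _ = random_instance(rng)
        widths = [8, 8, 8]
        st1 = GroupStructure.contiguous(widths)
        st2 = GroupStructure.contiguous(
            widths, weights=2.0 * st1.group_weights
        )
        blocks = [rng.standard_normal(8) for _ in range(3)]
        m_lam2 = GroupLassoModel(intercept=0.1, blocks=blocks, lambda_=2.0)
        m_lam1 = GroupLassoModel(intercept=0.1, blocks=blocks, lambda_=1.0)
        assert logistic_objective(Z, y, m_lam2, st1) == pytest.approx(
            logistic_objective(Z, y, m_lam1, st2)
        )

    def test_fit_at_lambda_max_returns_null(self, rng):
        Z, y, st_ = random_instance(rng)
        m = fit(Z, y, st_, lambda_multiplier=1.0, tol=1e-10)
        assert all(np.all(b == 0.0) for b in m.blocks)
        n1 = y.sum()
        assert m.intercept == pytest.approx(np.log(n1 / (len(y) - n1)))

    def test_below_lambda_max_activates_groups(self, rng):
        Z, y, st_ = random_instance(rng)
        m = fit(Z, y, st_, lambda_multiplier=0.5, tol=1e-6)
        assert (m.etas > 0).sum() >= 1

    def test_lambda_max_homogeneous_in_Z(self, rng):
        Z, y, st_ = random_instance(rng)
        assert lambda_max(3.0 * Z, y, st_) == pytest.approx(
            3.0 * lambda_max(Z, y, st_)
        )

    def test_single_class_labels_rejected(self, rng):
        Z = rng.standard_normal((6, 4))
        st_ = GroupStructure.contiguous([4])
        with pytest.raises(ValueError):
            lambda_max(Z, np.ones(6, dtype=int), st_)


class TestFit:
    def test_matches_independent_convex_optimizer(self):
        """Fitted objective equals an independent reference solver's
        optimum within 1e-6 relative on random small instances."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            Z, y, st_ = random_instance(rng)
            m = fit(Z, y, st_, lambda_multiplier=0.5, tol=1e-8)
            obj = logistic_objective(Z, y, m, st_)
            ref = reference_optimum(Z, y, st_, m.lambda_)
            assert abs(obj - ref) / ref < 1e-6
            assert kkt_residual(Z, y, m, st_) <= 1e-6

    def test_objective_history_non_increasing(self, rng):
        Z, y, st_ = random_instance(rng)
        m = fit(Z, y, st_, lambda_multiplier=0.6, tol=1e-8)
        h = np.asarray(m.objective_history)
        assert (np.diff(h) <= 1e-10 * abs(h[0])).all()

    def test_solution_beats_null_objective(self, rng):
        Z, y, st_ = random_instance(rng)
        m = fit(Z, y, st_, lambda_multiplier=0.4, tol=1e-7)
        null = GroupLassoModel(
            intercept=m.intercept,
            blocks=[np.zeros_like(b) for b in m.blocks],
            lambda_=m.lambda_,
        )
        assert logistic_objective(Z, y, m, st_) <= logistic_objective(
            Z, y, null, st_
        ) + 1e-9

    def test_group_permutation_equivariance(self, rng):
        Z, y, st_ = random_instance(rng, P=3, width=4)
        m = fit(Z, y, st_, lambda_multiplier=0.5, tol=1e-9)
        perm = [2, 0, 1]
        cols = np.concatenate([np.arange(p * 4, p * 4 + 4) for p in perm])
        m2 = fit(Z[:, cols], y, st_, lambda_multiplier=0.5, tol=1e-9)
        for new_g, old_g in enumerate(perm):
            np.testing.assert_allclose(
                m2.blocks[new_g], m.blocks[old_g], atol=1e-5
            )

    def test_nonconvergence_warns_not_silent(self, rng):
        Z, y, st_ = random_instance(rng)
        with pytest.warns(RuntimeWarning, match="max_iter"):
            m = fit(Z, y, st_, lambda_multiplier=0.3, tol=1e-14, max_iter=3)
        assert not m.converged

    def test_active_set_shrinks_with_penalty_on_fixture(self, rng):
        Z, y, st_ = random_instance(rng, P=4, width=6, informative=2)
        counts = []
        for mult in (0.6, 0.7, 0.8, 0.9):
            m = fit(Z, y, st_, lambda_multiplier=mult, tol=1e-7)
            counts.append(int((m.etas > 0).sum()))
        assert counts[-1] <= counts[0]


class TestKktResidual:
    def test_null_model_at_lambda_max_is_stationary(self, rng):
        Z, y, st_ = random_instance(rng)
        lam = lambda_max(Z, y, st_)
        n1 = y.sum()
        null = GroupLassoModel(
            intercept=float(np.log(n1 / (len(y) - n1))),
            blocks=[np.zeros(8) for _ in range(3)],
            lambda_=lam,
        )
        assert kkt_residual(Z, y, null, st_) <= 1e-9

    def test_converged_fit_meets_tolerance(self, rng):
        Z, y, st_ = random_instance(rng)
        m = fit(Z, y, st_, lambda_multiplier=0.5, tol=1e-7)
        assert m.converged
        assert kkt_residual(Z, y, m, st_) <= 1e-7

    def test_perturbing_solution_increases_residual(self, rng):
        Z, y, st_ = random_instance(rng)
        m = fit(Z, y, st_, lambda_multiplier=0.5, tol=1e-9)
        base = kkt_residual(Z, y, m, st_)
        nz = next(i for i, b in enumerate(m.blocks) if np.any(b != 0))
        m.blocks[nz] = m.blocks[nz] + 0.1
        assert kkt_residual(Z, y, m, st_) > base


class TestGroupStructure:
    def test_non_contiguous_groups_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            GroupStructure(
                group_of_column=np.array([0, 1, 0]),
                group_weights=np.array([1.0, 1.0]),
            )

    def test_default_weights_are_sqrt_width(self):
        st_ = GroupStructure.contiguous([4, 9])
        np.testing.assert_allclose(st_.group_weights, [2.0, 3.0])
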