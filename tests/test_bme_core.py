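"""BME machinery: nuisance fits, χ², entropy closed forms, and the dual
optimizer checked against an exhaustive primal grid search on the simplex."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saxsbme import (
    ScatteringProfile,
    bme_optimize,
    chi2_reduced,
    fit_scale_offset,
    phi_eff,
    relative_entropy,
)


def _profile(values, sigma):
    q = np.linspace(0.01, 0.2, len(values))
    return ScatteringProfile(q=q, intensity=np.asarray(values, float),
                             sigma=np.asarray(sigma, float))


class TestScaleOffset:
    def test_identity(self, rng):
        calc = rng.uniform(1, 10, 19)
        a, b = fit_scale_offset(calc, _profile(calc, np.full(19, 0.1)))
        assert a == pytest.approx(1.0) and b == pytest.approx(0.0, abs=1e-10)

    def test_double_data(self, rng):
        calc = rng.uniform(1, 10, 19)
        a, b = fit_scale_offset(2 * calc, _profile(calc, np.full(19, 0.1)))
        assert a == pytest.approx(0.5) and b == pytest.approx(0.0, abs=1e-10)

    def test_matches_generic_weighted_lstsq(self, rng):
        calc = rng.uniform(1, 10, 19)
        exp = _profile(rng.uniform(1, 10, 19), rng.uniform(0.05, 0.5, 19))
        a, b = fit_scale_offset(calc, exp)
        # independent oracle: numpy weighted least squares on the design matrix
        A = np.column_stack([calc, np.ones(19)]) / exp.sigma[:, None]
        coef, *_ = np.linalg.lstsq(A, exp.intensity / exp.sigma, rcond=None)
        assert a == pytest.approx(coef[0], rel=1e-10)
        assert b == pytest.approx(coef[1], rel=1e-10)

    def test_degenerate_constant_calc(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_scale_offset(np.full(10, 3.0), _profile(np.arange(1, 11), np.full(10, 0.1)))


class TestChi2:
    def test_perfect_match_zero(self, rng):
        calc = rng.uniform(1, 10, 19)
        assert chi2_reduced(calc, _profile(calc, np.full(19, 0.1)), "none") == 0.0

    def test_one_sigma_offsets_give_unity(self, rng):
        sigma = rng.uniform(0.1, 0.5, 19)
        calc = rng.uniform(5, 10, 19)
        exp = _profile(calc + sigma, sigma)
        assert chi2_reduced(calc, exp, "none") == pytest.approx(1.0, rel=1e-12)

    def test_sigma_consistent_noise_averages_to_one(self, chain_ensemble, truth_case, rng):
        # the truth ensemble curve vs repeated noisy realizations of itself
        ideal = truth_case.noiseless_saxs.intensity
        sigma = truth_case.noiseless_saxs.sigma
        chis = [
            chi2_reduced(ideal, _profile(ideal + sigma * rng.standard_normal(19), sigma),
                         "none")
            for _ in range(200)
        ]
        se = np.std(chis, ddof=1) / np.sqrt(len(chis))
        assert np.mean(chis) == pytest.approx(1.0, abs=3 * se)


class TestEntropy:
    def test_identical_weights_zero(self):
        w = np.full(50, 1 / 50)
        assert relative_entropy(w, w) == 0.0
        assert phi_eff(w, w) == 1.0

    def test_single_frame_of_100(self):
        w0 = np.full(100, 0.01)
        w = np.zeros(100)
        w[3] = 1.0
        assert relative_entropy(w, w0) == pytest.approx(-np.log(100), rel=1e-12)
        assert phi_eff(w, w0) == pytest.approx(0.01, rel=1e-12)

    def test_half_mass_uniform(self):
        n = 60
        w0 = np.full(n, 1 / n)
        w = np.zeros(n)
        w[: n // 2] = 2 / n
        assert relative_entropy(w, w0) == pytest.approx(-np.log(2), rel=1e-12)
        assert phi_eff(w, w0) == pytest.approx(0.5, rel=1e-12)

    def test_absolute_continuity_enforced(self):
        w0 = np.array([0.5, 0.5, 0.0])
        w = np.array([0.25, 0.25, 0.5])
        with pytest.raises(ValueError, match="continuity"):
            relative_entropy(w, w0)

    @given(st.integers(2, 30), st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_never_positive(self, n, seed):
        r = np.random.default_rng(seed)
        w = r.dirichlet(np.ones(n))
        w0 = r.dirichlet(np.ones(n))
        assert relative_entropy(w, w0) <= 1e-12


def _simplex_grid(n, step):
    """All weight vectors on the (n-1)-simplex with resolution `step`."""
    k = int(round(1 / step))
    if n == 2:
        a = np.arange(k + 1) / k
        return np.column_stack([a, 1 - a])
    if n == 3:
        pts = [
            (i / k, j / k, (k - i - j) / k)
            for i in range(k + 1)
            for j in range(k + 1 - i)
        ]
        return np.array(pts)
    pts = [
        (i / k, j / k, l / k, (k - i - j - l) / k)
        for i in range(k + 1)
        for j in range(k + 1 - i)
        for l in range(k + 1 - i - j)
    ]
    return np.array(pts)


def _primal_objective(W, F, exp, w0, theta):
    """Eq-style objective ½χ² − θS_rel evaluated on many weight vectors."""
    calc = W @ F.T  # (n_points, m)
    chi2 = np.sum(((calc - exp.intensity) / exp.sigma) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logratio = np.where(W > 0, np.log(np.where(W > 0, W, 1) / w0), 0.0)
    s_rel = -np.sum(W * logratio, axis=1)
    return 0.5 * chi2 - theta * s_rel


class TestBmeOptimize:
    def test_huge_theta_returns_prior(self, observable_matrix, truth_case, chain_ensemble):
        res = bme_optimize(observable_matrix, truth_case.synthetic_saxs,
                           chain_ensemble.prior_weights, theta=1e12, scale_mode="none")
        assert np.max(np.abs(res.weights - chain_ensemble.prior_weights)) < 1e-6
        assert res.phi_eff == pytest.approx(1.0, abs=1e-6)
        assert res.chi2_red == pytest.approx(res.chi2_red_prior, rel=1e-6)

    def test_symmetric_two_frame_fixed_point(self):
        # a uniform prior already reproduces the data: BME must not move it
        F = np.array([[0.0, 1.0], [1.0, 0.0]])
        exp = ScatteringProfile(q=np.array([0.05, 0.06]),
                                intensity=np.array([0.5, 0.5]),
                                sigma=np.array([0.01, 0.01]))
        res = bme_optimize(F, exp, theta=1.0, scale_mode="none")
        np.testing.assert_allclose(res.weights, [0.5, 0.5], atol=1e-8)

    @pytest.mark.parametrize("n_frames,m,step", [(3, 2, 1e-3), (4, 3, 1e-2)])
    def test_dual_beats_primal_grid(self, n_frames, m, step):
        rng = np.random.default_rng(42)
        for _ in range(10):
            F = rng.uniform(0, 2, size=(m, n_frames))
            w_true = rng.dirichlet(np.ones(n_frames))
            target = F @ w_true + rng.normal(0, 0.02, m)
            exp = ScatteringProfile(q=np.linspace(0.01, 0.1, m),
                                    intensity=target, sigma=np.full(m, 0.05))
            w0 = np.full(n_frames, 1 / n_frames)
            theta = 1.0
            res = bme_optimize(F, exp, w0, theta=theta, scale_mode="none")
            W = _simplex_grid(n_frames, step)
            grid_min = _primal_objective(W, F, exp, w0, theta).min()
            dual_obj = _primal_objective(res.weights[None, :], F, exp, w0, theta)[0]
            assert dual_obj <= grid_min + 1e-4

    def test_optimality_form_of_weights(self, observable_matrix, truth_case,
                                        chain_ensemble):
        res = bme_optimize(observable_matrix, truth_case.synthetic_saxs,
                           chain_ensemble.prior_weights, theta=50.0, scale_mode="none")
        lam = res.lagrange_multipliers
        w_form = chain_ensemble.prior_weights * np.exp(-(lam @ observable_matrix.values))
        w_form /= w_form.sum()
        np.testing.assert_allclose(res.weights, w_form, rtol=1e-8)

    def test_deterministic(self, observable_matrix, truth_case, chain_ensemble):
        kw = dict(w0=chain_ensemble.prior_weights, theta=100.0, scale_mode="none")
        r1 = bme_optimize(observable_matrix, truth_case.synthetic_saxs, **kw)
        r2 = bme_optimize(observable_matrix, truth_case.synthetic_saxs, **kw)
        assert np.array_equal(r1.weights, r2.weights)

    def test_invalid_theta(self, observable_matrix, truth_case):
        with pytest.raises(ValueError, match="theta"):
            bme_optimize(observable_matrix, truth_case.synthetic_saxs, theta=0.0)
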