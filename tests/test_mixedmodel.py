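"""Mixed-model equations, REML estimators, Gibbs sampler and Geweke score."""

import numpy as np
import pytest
from numpy.testing import assert_allclose

from rngwas import (
    LegendreBasis,
    RandomRegressionMME,
    build_relationships,
    em_reml,
    geweke_z,
    gibbs_sampler,
)
from rngwas.mixedmodel import ai_reml
from rngwas.simulate import SimulationConfig, simulate_pedigree, _pedigree_polygenic


def _rn_fixture(rng, n=8):
    """Unrelated animals, one record each, random EG and fixed covariate."""
    from rngwas import Pedigree
    ped = Pedigree(np.arange(1, n + 1), np.full(n, -1), np.full(n, -1))
    rel = build_relationships(ped)
    eg = rng.uniform(-2.5, 2.5, n)
    phi = LegendreBasis(order=2).design(eg)
    X = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
    y = rng.normal(0, 1, n)
    return y, X, phi, rel


def _dense_gls(y, X, phi, H, K, s2e):
    n = len(y)
    W = np.zeros((n, 2 * n))
    W[np.arange(n), np.arange(n)] = phi[:, 0]
    W[np.arange(n), n + np.arange(n)] = phi[:, 1]
    G = np.kron(K, H)
    V = W @ G @ W.T + s2e * np.eye(n)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    a = G @ W.T @ Vi @ (y - X @ beta)
    P = Vi - Vi @ X @ np.linalg.solve(X.T @ Vi @ X, X.T @ Vi)
    ll = -0.5 * (np.linalg.slogdet(V)[1]
                 + np.linalg.slogdet(X.T @ Vi @ X)[1] + y @ P @ y)
    return beta, a, ll


def test_solution_matches_dense_gls_oracle(rng):
    y, X, phi, rel = _rn_fixture(rng)
    K = np.array([[2.0, 0.5], [0.5, 1.0]])
    s2e = 1.5
    mme = RandomRegressionMME(y, X, phi, np.arange(len(y)), rel.H_inv)
    sol = mme.solve(K, s2e)
    H = np.linalg.inv(rel.H_inv)
    beta, a, ll = _dense_gls(y, X, phi, H, K, s2e)
    assert_allclose(sol.beta, beta, atol=1e-8)
    assert_allclose(sol.coef.ravel(), a, atol=1e-8)
    assert mme.reml_loglik(K, s2e) == pytest.approx(ll, abs=1e-8)


def test_coefficient_matrix_symmetric(rng):
    y, X, phi, rel = _rn_fixture(rng)
    C = RandomRegressionMME(y, X, phi, np.arange(len(y)), rel.H_inv) \
        ._coefficient_matrix(np.eye(2), 1.0)
    assert np.abs(C - C.T).max() < 1e-12


def test_singular_K_rejected(rng):
    y, X, phi, rel = _rn_fixture(rng)
    mme = RandomRegressionMME(y, X, phi, np.arange(len(y)), rel.H_inv)
    with pytest.raises(ValueError, match="singular"):
        mme.solve(np.zeros((2, 2)), 1.0)


def test_vanishing_slope_variance_reduces_to_intercept_model(rng):
    y, X, phi, rel = _rn_fixture(rng, n=12)
    n = len(y)
    mme2 = RandomRegressionMME(y, X, phi, np.arange(n), rel.H_inv)
    sol2 = mme2.solve(np.diag([2.0, 1e-10]), 1.0)
    mme1 = RandomRegressionMME(y, X, phi[:, :1], np.arange(n), rel.H_inv)
    sol1 = mme1.solve(np.array([[2.0]]), 1.0)
    assert_allclose(sol2.coef[0], sol1.coef[0], atol=1e-5)
    assert np.abs(sol2.coef[1]).max() < 1e-5
    assert_allclose(sol2.beta, sol1.beta, atol=1e-5)


def test_aliased_fixed_columns_reported_nan(rng):
    y, X, phi, rel = _rn_fixture(rng)
    X = np.column_stack([X, X[:, 0] + X[:, 1]])  # third column aliased
    mme = RandomRegressionMME(y, X, phi, np.arange(len(y)), rel.H_inv)
    sol = mme.solve(np.eye(2), 1.0)
    assert np.isnan(sol.beta[2]) and not np.isnan(sol.beta[:2]).any()


def _pedigree_data(seed, s2a=2.0, s2e=1.0, n_founders=50):
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(n_founders=n_founders, n_generations=2,
                           n_offspring_per_mating=3, seed=seed)
    ped, _, _ = simulate_pedigree(cfg)
    rel = build_relationships(ped)
    u = _pedigree_polygenic(ped, np.array([[s2a]]), rng)[:, 0]
    y = 1.0 + u + rng.normal(0, np.sqrt(s2e), ped.n)
    X = np.ones((ped.n, 1))
    phi = np.ones((ped.n, 1))
    return RandomRegressionMME(y, X, phi, np.arange(ped.n), rel.H_inv)


def test_em_reml_loglik_monotone():
    mme = _pedigree_data(31)
    res = em_reml(mme, tol=1e-10, max_iter=60)
    assert np.all(np.diff(res.loglik_path) >= -1e-8)


def test_em_reml_null_heritability_boundary():
    rng = np.random.default_rng(2)
    mme = _pedigree_data(32, s2a=0.0, s2e=1.0)
    res = em_reml(mme, max_iter=100, tol=1e-4)
    assert res.K[0, 0] < 0.3           # shrinks toward the zero boundary
    assert res.sigma2_e == pytest.approx(1.0, rel=0.4)


def test_ai_reml_reaches_em_optimum():
    mme = _pedigree_data(33)
    em = em_reml(mme, tol=1e-10, max_iter=800, track_loglik=True)
    ai = ai_reml(mme, tol=1e-10)
    assert ai.converged
    assert ai.loglik_path[-1] >= em.loglik_path[-1] - 1e-6
    assert ai.K[0, 0] == pytest.approx(em.K[0, 0], rel=1e-2)
    assert ai.sigma2_e == pytest.approx(em.sigma2_e, rel=1e-2)


def test_em_reml_nonconvergence_is_flagged():
    mme = _pedigree_data(34)
    res = em_reml(mme, tol=1e-12, max_iter=2)
    assert not res.converged and "did not converge" in res.message


def test_gibbs_agrees_with_reml_on_identified_fixture():
    mme = _pedigree_data(35, n_founders=60)
    ai = ai_reml(mme)
    gb = gibbs_sampler(mme, n_iter=6000, burn_in=1500, thin=3, seed=2)
    assert gb.K[0, 0] == pytest.approx(ai.K[0, 0], abs=3 * gb.K_samples[:, 0, 0].std())
    assert gb.sigma2_e == pytest.approx(ai.sigma2_e, abs=3 * gb.sigma2_e_samples.std())


def test_gibbs_determinism_and_bookkeeping():
    mme = _pedigree_data(36, n_founders=12)
    a = gibbs_sampler(mme, n_iter=2000, burn_in=500, thin=5, seed=7)
    b = gibbs_sampler(mme, n_iter=2000, burn_in=500, thin=5, seed=7)
    assert np.array_equal(a.K_samples, b.K_samples)
    assert np.array_equal(a.sigma2_e_samples, b.sigma2_e_samples)
    assert len(a.sigma2_e_samples) == (2000 - 500) // 5
    with pytest.raises(ValueError, match="burn-in"):
        gibbs_sampler(mme, n_iter=100, burn_in=100)


# ---------------------------------------------------------------- Geweke


def test_geweke_iid_chain_calibrated():
    rng = np.random.default_rng(0)
    z = np.array([geweke_z(rng.standard_normal(10_000)) for _ in range(200)])
    assert 0.90 <= np.mean(np.abs(z) < 1.96) <= 1.0


def test_geweke_detects_trend():
    chain = np.linspace(0, 10, 10_000) + np.random.default_rng(1).normal(
        0, 0.5, 10_000)
    assert abs(geweke_z(chain)) > 5


def test_geweke_symmetry_and_errors():
    half = np.sin(np.arange(500)) + 2.0
    z = geweke_z(np.concatenate([half, half]), frac_first=0.5, frac_last=0.5)
    assert z == pytest.approx(0.0, abs=1e-10)
    with pytest.raises(ValueError, match="constant"):
        geweke_z(np.ones(1000))
    with pytest.raises(ValueError, match="length"):
        geweke_z(np.arange(50.0))
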