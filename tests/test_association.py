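"""SNP back-solving, approximate significance and trajectories."""

import numpy as np
import pandas as pd
import pytest
from numpy.testing import assert_allclose
from scipy import stats

from rngwas import (
    GenotypeMatrix,
    LegendreBasis,
    SignificanceConfig,
    SimulationConfig,
    backsolve_snp_effects,
    classify_snps,
    genomic_inflation_lambda,
    independent_segments,
    significance_thresholds,
    simulate_dataset,
    snp_pvalues,
    snp_trajectories,
)


def _geno(codes, chrom=1):
    codes = np.asarray(codes, dtype=float)
    m = codes.shape[1]
    markers = pd.DataFrame({"marker": [f"m{i}" for i in range(m)],
                            "chrom": chrom, "bp": (np.arange(m) + 1) * 10_000})
    return GenotypeMatrix(codes, np.arange(1, codes.shape[0] + 1), markers)


def test_backsolve_hand_example():
    # centred genotypes +-[1, 1]; a = (2, -2) solved by u = (1, 1)
    geno = _geno([[2, 2], [0, 0]])
    u = backsolve_snp_effects(geno, np.array([[2.0, -2.0]]))
    assert_allclose(u, [[1.0, 1.0]], atol=1e-5)


def test_backsolve_zero_gebv_zero_effects():
    geno = _geno([[2, 1], [0, 1], [1, 0]])
    u = backsolve_snp_effects(geno, np.zeros((2, 3)))
    assert_allclose(u, 0.0, atol=1e-12)


def test_backsolve_dimension_mismatch():
    geno = _geno([[2, 1], [0, 1]])
    with pytest.raises(ValueError, match="animals"):
        backsolve_snp_effects(geno, np.zeros((1, 3)))


def test_backsolve_equals_ridge_snp_blup():
    """GBLUP breeding values back-solve to the SNP-BLUP solutions (<= 1e-6)."""
    cfg = SimulationConfig(n_founders=50, n_generations=0, n_markers=200,
                           seed=7)
    geno = simulate_dataset(cfg).genotypes
    p = geno.allele_frequencies()
    Z = geno.centered(p)
    den = 2.0 * np.sum(p * (1.0 - p))
    G = Z @ Z.T / den
    rng = np.random.default_rng(0)
    y = rng.normal(0, 2, geno.n_animals)
    s2a, s2e = 1.0, 2.0
    V = s2a * G + s2e * np.eye(geno.n_animals)
    Vi = np.linalg.inv(V)
    X = np.ones((geno.n_animals, 1))
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = y - X @ beta
    a_gblup = s2a * G @ Vi @ resid
    u_snpblup = (s2a / den) * Z.T @ Vi @ resid
    u_back = backsolve_snp_effects(geno, a_gblup[None, :])[0]
    assert np.abs(u_back - u_snpblup).max() < 1e-6


def test_snp_pvalues_match_dense_recomputation(rng):
    cfg = SimulationConfig(n_founders=12, n_generations=0, n_markers=30,
                           maf_range=(0.2, 0.5), seed=13)
    geno = simulate_dataset(cfg).genotypes
    gebv = rng.normal(0, 1, (1, geno.n_animals))
    B = rng.normal(0, 0.3, (geno.n_animals, geno.n_animals))
    cov = [B @ B.T]
    table = snp_pvalues(geno, gebv, cov)
    M = geno.centered()
    MMt = M @ M.T
    MMt += 1e-8 * np.trace(MMt) / len(MMt) * np.eye(len(MMt))  # ridge path
    Bmat = np.linalg.inv(MMt) @ M
    u = gebv[0] @ Bmat
    sd = np.sqrt(np.diag(Bmat.T @ cov[0] @ Bmat))
    p = 2 * stats.norm.sf(np.abs(u) / sd)
    assert_allclose(table["u_int"], u, atol=1e-10)
    assert_allclose(table["sd_int"], sd, atol=1e-10)
    assert_allclose(table["p_int"], p, atol=1e-10)


def test_snp_pvalues_zero_sd_reports_one():
    geno = _geno([[2, 1], [0, 1], [1, 2]])
    table = snp_pvalues(geno, np.zeros((1, 3)),
                        [np.zeros((3, 3))])
    assert (table["p_int"] == 1.0).all()
    assert (table["u_int"] == 0.0).all()


def test_independent_segments_closed_form():
    me = independent_segments(196.0, 1.0)
    assert me == pytest.approx(392.0 / np.log(784.0), abs=1e-9)  # ~58.8
    assert 0.1 / me == pytest.approx(1.7e-3, abs=1e-4)
    with pytest.raises(ValueError):
        independent_segments(0.1, 0.1)


def test_significance_requires_both_rules():
    table = pd.DataFrame({
        "marker": ["a", "b", "c"], "chrom": [1, 1, 1],
        "bp": [10_000, 50_000, 100_000_000],
        "p_int": [1e-6, 1e-4, 0.5], "p_slope": [0.5, 1e-6, 1e-6],
        "u_int": [0.1] * 3, "u_slope": [0.1] * 3,
    })
    cfg = SignificanceConfig(chrom_lengths={1: 1.0})
    out = significance_thresholds(table, cfg)
    assert out["bonferroni_cutoff"].iloc[0] == pytest.approx(
        0.1 / independent_segments(196.0, 1.0))
    assert bool(out["pass_neglog10_int"][0]) and bool(out["significant_int"][0])
    # p = 1e-4 passes Bonferroni (1.7e-3) but not the -log10 > 5 rule
    assert bool(out["pass_bonferroni_int"][1])
    assert not bool(out["significant_int"][1])


def test_classification_venn_counts():
    table = pd.DataFrame({
        "significant_int": [True, False, True, False],
        "significant_slope": [False, True, True, False],
    })
    out, venn = classify_snps(table)
    assert list(out["classification"]) == [
        "intercept_only", "slope_only", "shared", "none"]
    assert venn == {"intercept_only": 1, "slope_only": 1, "shared": 1}


def test_trajectories_shapes_and_sign_change():
    basis = LegendreBasis(order=2, n_grid=61)
    table = pd.DataFrame({
        "marker": ["flat", "odd", "both"],
        "u_int": [1.0, 0.0, 1.0], "u_slope": [0.0, 0.5, 1.0],
        "significant_int": [True, True, True],
        "significant_slope": [False, True, True],
    })
    traj = snp_trajectories(table, basis)
    flat = traj[traj["marker"] == "flat"]["effect"].to_numpy()
    assert_allclose(flat, np.sqrt(0.5))  # phi0 * u_int everywhere
    odd = traj[traj["marker"] == "odd"]
    eff = odd["effect"].to_numpy()
    assert_allclose(eff, -eff[::-1], atol=1e-12)  # odd about EG = 0
    assert odd["sign_change"].all()
    both = traj[traj["marker"] == "both"]
    mid = both[both["eg"] == 0.0]["effect"].iloc[0]
    assert mid == pytest.approx(np.sqrt(0.5), abs=1e-12)
    # endpoints reproduce phi(+-3)' u exactly
    phi = basis.design(np.array([-3.0, 3.0]))
    assert both["effect"].iloc[0] == pytest.approx(phi[0] @ [1.0, 1.0])
    assert both["effect"].iloc[-1] == pytest.approx(phi[1] @ [1.0, 1.0])


def test_trajectories_only_significant_by_default():
    basis = LegendreBasis(order=2)
    table = pd.DataFrame({
        "marker": ["x"], "u_int": [1.0], "u_slope": [0.0],
        "significant_int": [False], "significant_slope": [False],
    })
    assert len(snp_trajectories(table, basis)) == 0
    assert len(snp_trajectories(table, basis, significant_only=False)) > 0


def test_genomic_inflation_lambda_properties(rng):
    p = rng.uniform(0, 1, 200_000)
    lam = genomic_inflation_lambda(p)
    assert lam == pytest.approx(1.0, abs=0.02)
    assert genomic_inflation_lambda(np.full(1000, 0.5)) == pytest.approx(1.0)
    assert genomic_inflation_lambda(p / 2) > 1.0
    with pytest.raises(ValueError):
        genomic_inflation_lambda(p[:50])
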