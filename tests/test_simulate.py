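"""Synthetic-population generator: structure, Mendelian rules, determinism."""

import numpy as np
import pandas as pd
import pytest

from rngwas import (
    Pedigree,
    SimulationConfig,
    drop_genotypes,
    simulate_dataset,
    simulate_pedigree,
)


def test_founders_only_population():
    cfg = SimulationConfig(n_founders=10, n_generations=0, seed=1)
    ped, sex, gen = simulate_pedigree(cfg)
    assert ped.n == 10
    assert (ped.sire == -1).all() and (ped.dam == -1).all()
    assert set(sex.tolist()) == {0, 1}


def test_parents_precede_offspring_and_come_from_previous_generation():
    cfg = SimulationConfig(n_founders=4, n_generations=2,
                           n_offspring_per_mating=2, seed=2)
    ped, sex, gen = simulate_pedigree(cfg)
    for i in range(ped.n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0:
            assert s < i and d < i and s != d
            assert gen[s] == gen[i] - 1 and gen[d] == gen[i] - 1


def test_single_sex_founders_raise():
    with pytest.raises(ValueError):
        simulate_pedigree(SimulationConfig(n_founders=1, seed=1))


def test_seed_reproducibility_bitwise():
    cfg = SimulationConfig(n_founders=20, n_generations=2, n_markers=100,
                           n_cg=5, seed=11)
    a, b = simulate_dataset(cfg), simulate_dataset(cfg)
    assert np.array_equal(a.ped.sire, b.ped.sire)
    assert np.array_equal(a.genotypes.codes, b.genotypes.codes)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
    pd.testing.assert_frame_equal(a.truth["animals"], b.truth["animals"])


def test_fixed_allele_gives_homozygous_everyone():
    cfg = SimulationConfig(n_founders=4, n_generations=2, n_markers=10, seed=5)
    ped, _, _ = simulate_pedigree(cfg)
    geno = drop_genotypes(ped, cfg, founder_freqs=np.ones(10))
    assert (geno.codes == 2.0).all()
    geno0 = drop_genotypes(ped, cfg, founder_freqs=np.zeros(10))
    assert (geno0.codes == 0.0).all()


def test_founder_mean_genotype_matches_binomial_oracle():
    cfg = SimulationConfig(n_founders=400, n_generations=0, n_markers=200,
                           seed=8)
    ped, _, _ = simulate_pedigree(cfg)
    geno = drop_genotypes(ped, cfg, founder_freqs=np.full(200, 0.5))
    # each code is Binomial(2, 0.5): mean 1, var 0.5
    se = np.sqrt(0.5 / (400 * 200))
    assert abs(geno.codes.mean() - 1.0) < 3 * se


def test_missing_parent_nonfounder_rejected():
    ped = Pedigree(np.array([1, 2]), np.array([-1, 0]), np.array([-1, -1]))
    cfg = SimulationConfig(n_founders=2, seed=1)
    with pytest.raises(ValueError, match="both parents"):
        drop_genotypes(ped, cfg)


def test_allele_frequency_preserved_in_expectation():
    """Gene dropping drifts but is unbiased across replicates."""
    drifts = []
    for seed in range(20):
        cfg = SimulationConfig(n_founders=30, n_generations=3, n_markers=50,
                               seed=100 + seed)
        ds = simulate_dataset(cfg)
        founders = ds.ped.sire < 0
        p0 = ds.genotypes.codes[founders].mean(axis=0) / 2
        p3 = ds.genotypes.codes[~founders].mean(axis=0) / 2
        drifts.append((p3 - p0).mean())
    drifts = np.asarray(drifts)
    assert abs(drifts.mean()) < 3 * drifts.std(ddof=1) / np.sqrt(len(drifts))


def test_no_genetics_limit_phenotypic_variance():
    cfg = SimulationConfig(n_founders=1000, n_generations=0, n_markers=50,
                           K_true=((0.0, 0.0), (0.0, 0.0)), resid_var=1.0,
                           cg_effect_sd=0.0, n_qtl=0, seed=21)
    ds = simulate_dataset(cfg)
    y = ds.phenotypes.query("trait == 'continuous'")["value"]
    # var of a chi2-flavoured variance estimate: sd ~ sqrt(2/n)
    assert abs(y.var() - 1.0) < 3 * np.sqrt(2.0 / len(y))


def test_no_plasticity_limit_shares_slope():
    cfg = SimulationConfig(n_founders=100, n_generations=0, n_markers=50,
                           K_true=((2.0, 0.0), (0.0, 0.0)), n_qtl=0, seed=22)
    ds = simulate_dataset(cfg)
    assert np.allclose(ds.truth["animals"]["a_slope"], 0.0)


def test_binary_incidence_matches_request():
    cfg = SimulationConfig(n_founders=600, n_generations=0, n_markers=50,
                           binary_incidence=0.5, seed=23)
    ds = simulate_dataset(cfg)
    v = ds.phenotypes.query("trait == 'binary'")["value"]
    assert set(v.unique()) <= {1.0, 2.0}
    frac = (v == 2.0).mean()
    assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / len(v))


def test_realized_genetic_covariance_matches_K_true():
    """Sample covariance of (a_int, a_slope) over independent founders."""
    K = np.array([[4.0, 1.0], [1.0, 1.0]])
    cfg = SimulationConfig(n_founders=2500, n_generations=0, n_markers=300,
                           K_true=K, n_qtl=20, qtl_effect_sd_int=0.2,
                           qtl_effect_sd_slope=0.1, seed=24)
    ds = simulate_dataset(cfg)
    a = ds.truth["animals"][["a_int", "a_slope"]].to_numpy()
    S = np.cov(a.T)
    n = len(a)
    for i in range(2):
        for j in range(2):
            se = np.sqrt((K[i, i] * K[j, j] + K[i, j] ** 2) / n)
            assert abs(S[i, j] - K[i, j]) < 3 * se, (i, j, S[i, j])


def test_qtl_variance_exceeding_K_rejected():
    with pytest.raises(ValueError, match="exceeds K_true"):
        simulate_dataset(SimulationConfig(
            n_founders=50, n_generations=0, n_markers=100, n_qtl=50,
            K_true=((0.1, 0.0), (0.0, 0.1)), qtl_effect_sd_int=1.0, seed=1,
        ))


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="positive semi-definite"):
        SimulationConfig(K_true=((1.0, 2.0), (2.0, 1.0)))
    with pytest.raises(ValueError, match="maf_range"):
        SimulationConfig(maf_range=(0.0, 0.6))
    with pytest.raises(ValueError, match="binary_incidence"):
        SimulationConfig(binary_incidence=1.5)
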