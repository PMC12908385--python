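"""Reusable simulation experiments: null calibration and parameter recovery.

These functions define the package's reference study conditions — a
polygenic population with genetic intercept/slope covariance
``K = [[4, 1], [1, 1]]`` (intercept-slope correlation 0.5) and residual
variance 4 — and are shared by the test suite and the acceptance script so
both always measure the same thing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gradient import assign_EG
from .mixedmodel import gibbs_sampler, reml_estimate
from .pipeline import TwoStepReactionNormGWAS
from .reaction_norm import ReactionNormModel
from .relmat import build_relationships
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["K_REFERENCE", "null_calibration", "parameter_recovery"]

K_REFERENCE = ((4.0, 1.0), (1.0, 1.0))


def null_calibration(
    seed: int,
    n_genotyped: int = 1_000,
    n_markers: int = 5_000,
    reml_tol: float = 1e-3,
) -> dict:
    """One null-GWAS replicate: polygenic signal only, no large QTL.

    Simulates a random-mating population of ``n_genotyped`` genotyped
    animals whose intercept/slope effects are spread infinitesimally over
    all markers (``polygenic_mode='markers'``, no individual QTL), runs the
    full two-step pipeline (gradient from the descriptor trait, REML
    reaction norm, SNP back-solving) and returns the intercept and slope
    p-values with their genomic inflation factors.
    """
    n_founders = max(n_genotyped // 4, 8)
    cfg = SimulationConfig(
        n_founders=n_founders,
        n_generations=3,
        n_offspring_per_mating=2,
        n_markers=n_markers,
        n_chromosomes=5,
        chromosome_length_bp=100_000_000,
        maf_range=(0.05, 0.5),
        n_cg=max(n_genotyped // 20, 4),
        cg_effect_sd=1.0,
        K_true=K_REFERENCE,
        resid_var=4.0,
        n_qtl=0,
        polygenic_mode="markers",
        descriptor_var_a=1.0,
        descriptor_var_e=2.0,
        seed=seed,
    )
    ds = simulate_dataset(cfg)
    model = TwoStepReactionNormGWAS(rn_method="reml", reml_tol=reml_tol)
    model.fit(ds.ped, ds.genotypes, ds.phenotypes)
    return {
        "lambda": model.lambda_,
        "p_int": model.snp_table_["p_int"].to_numpy(),
        "p_slope": model.snp_table_["p_slope"].to_numpy(),
        "model": model,
    }


def _recovery_config(seed: int, n_animals: int) -> SimulationConfig:
    # full-sib families of four over three generations give the sib/parent
    # contrasts that identify the slope genetic variance
    n_founders = max(round(n_animals / 15), 8)
    return SimulationConfig(
        n_founders=n_founders,
        n_generations=3,
        n_offspring_per_mating=4,
        n_markers=200,  # markers unused by the pedigree-based fit
        n_chromosomes=2,
        n_cg=max(n_animals // 25, 4),
        cg_effect_sd=1.0,
        K_true=K_REFERENCE,
        resid_var=4.0,
        n_qtl=0,
        polygenic_mode="pedigree",
        seed=seed,
    )


def parameter_recovery(
    seeds,
    n_animals: int = 2_000,
    method: str = "reml",
    reml_tol: float = 1e-5,
    gibbs_iter: int = 3_000,
    gibbs_burn_in: int = 1_000,
    gibbs_thin: int = 2,
) -> pd.DataFrame:
    """Variance-component recovery replicates under the reference conditions.

    Each replicate simulates a pedigreed population, attaches the true
    gradient to the records (isolating variance-component estimation from
    gradient-estimation noise), fits the reaction-norm model with pedigree
    relationships (``H = A``), and records the estimated K entries,
    residual variance and intercept-slope correlation.  Returns one row
    per replicate.
    """
    rows = []
    for seed in seeds:
        cfg = _recovery_config(int(seed), n_animals)
        ds = simulate_dataset(cfg)
        rel = build_relationships(ds.ped)  # pedigree only
        rn = ReactionNormModel(method="fixed", K=np.eye(2), sigma2_e=1.0)
        records = ds.phenotypes[ds.phenotypes["trait"] == "continuous"]
        truth_eg = dict(zip(ds.truth["cg"]["cg"], ds.truth["cg"]["eg_true"]))
        records = records.assign(eg=records["cg"].map(truth_eg))
        mme = rn.build_mme(records, rel)
        if method == "reml":
            res = reml_estimate(mme, algorithm="ai", tol=reml_tol,
                                max_iter=100)
            K, s2e = res.K, res.sigma2_e
        elif method == "gibbs":
            # two-stage workflow: REML point estimates centre the weakly
            # informative priors and start the chain; eigenvalues of the
            # prior centre are floored away from zero because an
            # inverse-Wishart scale that is singular pins the chain there
            pre = reml_estimate(mme, algorithm="ai", tol=reml_tol, max_iter=100)
            w, U = np.linalg.eigh(pre.K)
            floor = 0.1 * max(np.mean(np.diag(pre.K)), 1e-8)
            K0 = (U * np.maximum(w, floor)) @ U.T
            res = gibbs_sampler(mme, n_iter=gibbs_iter, burn_in=gibbs_burn_in,
                                thin=gibbs_thin, seed=int(seed),
                                K_start=K0, sigma2_e_start=pre.sigma2_e)
            K, s2e = res.K, res.sigma2_e
        else:
            raise ValueError("method must be 'reml' or 'gibbs'")
        rows.append({
            "seed": int(seed), "method": method,
            "K00": K[0, 0], "K01": K[0, 1], "K11": K[1, 1],
            "sigma2_e": s2e,
            "r_int_slope": K[0, 1] / np.sqrt(K[0, 0] * K[1, 1]),
        })
    return pd.DataFrame(rows)
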