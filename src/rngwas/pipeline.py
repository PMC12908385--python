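"""End-to-end two-step reaction-norm GWAS.

Step 1 estimates contemporary-group solutions for an environmental
descriptor trait with a single-step animal model and standardizes them into
the environmental gradient.  Step 2 fits the reaction-norm random
regression on the analysis trait, back-solves SNP effects for intercept and
slope from the genotyped animals' GEBVs, attaches approximate p-values,
applies the declaration rules and reconstructs significant-SNP trajectories
across the gradient.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .association import SignificanceConfig, run_gwas
from .gradient import AnimalModel, assign_EG
from .io import GenotypeMatrix
from .pedigree import Pedigree
from .reaction_norm import ReactionNormModel
from .relmat import RelationshipSet, build_relationships

__all__ = ["TwoStepReactionNormGWAS"]


class TwoStepReactionNormGWAS(BaseEstimator):
    """Two-step genomic reaction-norm GWAS (sklearn-style front end).

    Parameters mirror the underlying estimators; ``rn_method`` selects REML
    ("reml"), Gibbs sampling ("gibbs") or fixed variance components for the
    reaction-norm step.  ``fit`` takes the pedigree, QC'd genotypes and a
    long phenotype frame (animal, cg, trait, value) holding both the
    descriptor trait and the analysis trait.

    Fitted attributes
    -----------------
    relationships_ : pedigree/genomic/combined matrices.
    gradient_ : the standardized environmental gradient.
    animal_model_ : the step-1 estimator.
    rn_model_ : the step-2 estimator.
    snp_table_ : per-marker effects, SDs, p-values, flags, classification.
    venn_ : significant-marker counts per class.
    trajectories_ : significant-SNP effects along the EG grid.
    lambda_ : genomic inflation factor per coefficient.
    """

    def __init__(self, descriptor_trait: str = "descriptor",
                 trait: str = "continuous", order: int = 2,
                 eg_max: float = 3.0, n_grid: int = 61,
                 blend_weight: float = 0.05, tune: bool = True,
                 rn_method: str = "reml", K=None, sigma2_e=None,
                 step1_var_a=None, step1_var_e=None,
                 reml_tol: float = 1e-4, reml_max_iter: int = 200,
                 gibbs_iter: int = 20_000, gibbs_burn_in: int = 5_000,
                 gibbs_thin: int = 5, seed=None,
                 significance: SignificanceConfig | None = None):
        self.descriptor_trait = descriptor_trait
        self.trait = trait
        self.order = order
        self.eg_max = eg_max
        self.n_grid = n_grid
        self.blend_weight = blend_weight
        self.tune = tune
        self.rn_method = rn_method
        self.K = K
        self.sigma2_e = sigma2_e
        self.step1_var_a = step1_var_a
        self.step1_var_e = step1_var_e
        self.reml_tol = reml_tol
        self.reml_max_iter = reml_max_iter
        self.gibbs_iter = gibbs_iter
        self.gibbs_burn_in = gibbs_burn_in
        self.gibbs_thin = gibbs_thin
        self.seed = seed
        self.significance = significance

    def fit(self, ped: Pedigree, geno: GenotypeMatrix, pheno: pd.DataFrame):
        rel = build_relationships(
            ped, geno.imputed(), geno.allele_frequencies(), geno.ids,
            blend_weight=self.blend_weight, tune=self.tune,
        )
        self.relationships_ = rel

        # --- step 1: gradient from the descriptor trait
        desc = pheno[pheno["trait"] == self.descriptor_trait]
        if desc.empty:
            raise ValueError(f"no records for descriptor {self.descriptor_trait!r}")
        am = AnimalModel(var_a=self.step1_var_a, var_e=self.step1_var_e,
                         reml_tol=self.reml_tol,
                         reml_max_iter=self.reml_max_iter)
        am.fit(desc, rel)
        self.animal_model_ = am
        self.gradient_ = am.gradient(clamp=self.eg_max)

        # --- step 2: reaction-norm model on the analysis trait
        records = pheno[pheno["trait"] == self.trait]
        if records.empty:
            raise ValueError(f"no records for trait {self.trait!r}")
        records = assign_EG(records, self.gradient_)
        rn = ReactionNormModel(
            order=self.order, eg_max=self.eg_max, n_grid=self.n_grid,
            method=self.rn_method, K=self.K, sigma2_e=self.sigma2_e,
            reml_tol=self.reml_tol, reml_max_iter=self.reml_max_iter,
            gibbs_iter=self.gibbs_iter, gibbs_burn_in=self.gibbs_burn_in,
            gibbs_thin=self.gibbs_thin, seed=self.seed, track_loglik=False,
        )
        rn.fit(records, rel)
        self.rn_model_ = rn

        # --- GWAS: back-solve from the genotyped animals' GEBVs
        gidx = rel.genotyped_idx
        if gidx is None:
            raise ValueError("GWAS requires genotyped animals")
        gebv = rn.coef_[:, gidx]
        cov = []
        for c in range(self.order):
            pev = rn.solution_.random_block_cov(c, c)[np.ix_(gidx, gidx)]
            cov.append(rel.G * rn.K_[c, c] - pev)
        cfg = self.significance or SignificanceConfig()
        res = run_gwas(geno, gebv, cov, cfg, rn.basis_)
        self.snp_table_ = res["table"]
        self.venn_ = res["venn"]
        self.trajectories_ = res["trajectories"]
        self.lambda_ = res["lambda"]
        return self
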