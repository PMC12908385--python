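"""Step 2: the single-step genomic reaction-norm random-regression model.

Fits

    y_ij = X b + omega_f phi_f(EG_j) + alpha_fi phi_f(EG_j) + e_ij

with contemporary-group fixed effects, fixed regressions on the normalized
Legendre basis of the environmental gradient, per-animal random intercept
and slope with covariance ``K (x) H``, and iid residuals.  Variance
components come from EM-REML (default) or Gibbs sampling and are then fixed
to obtain the genomic breeding values (the two-stage strategy usual in
genetic evaluation).  Because the fixed regressions are linear combinations
of the CG effects whenever EG is constant within CG, the fixed part is
rank-deficient by construction; aliased coefficients are dropped
deterministically (first-come order) and reported as NaN without affecting
breeding values or predictions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .legendre import LegendreBasis
from .mixedmodel import RandomRegressionMME, gibbs_sampler, reml_estimate
from .relmat import RelationshipSet

__all__ = [
    "ReactionNormModel",
    "genetic_params_along_EG",
    "h2_liability_to_observed",
    "h2_observed_to_liability",
]


class ReactionNormModel(BaseEstimator):
    """Reaction-norm random-regression mixed model (sklearn-style).

    Parameters
    ----------
    order : number of Legendre coefficients (2 = intercept + slope).
    eg_max : half-range of the gradient used for the [-1, 1] mapping.
    n_grid : points of the EG trajectory grid.
    method : "reml", "gibbs", or "fixed" (use the supplied K / sigma2_e).
    K, sigma2_e : starting values, or the fixed components for "fixed".
    seed : Gibbs chain seed.

    Fitted attributes
    -----------------
    K_ : (order, order) genetic covariance of the regression coefficients.
    sigma2_e_ : residual variance.
    coef_ : (order, q) random-regression coefficients per animal in H.
    fixed_ : fixed-effect solutions (NaN where aliased).
    solution_ : full MME solution, including the inverse coefficient matrix
        needed for prediction-error variances.
    basis_ : the Legendre basis in use.
    """

    def __init__(self, order: int = 2, eg_max: float = 3.0, n_grid: int = 61,
                 method: str = "reml", K=None, sigma2_e=None,
                 reml_algorithm: str = "ai",
                 reml_tol: float = 1e-6, reml_max_iter: int = 300,
                 gibbs_iter: int = 20_000, gibbs_burn_in: int = 5_000,
                 gibbs_thin: int = 5, seed=None, track_loglik: bool = True):
        self.order = order
        self.eg_max = eg_max
        self.n_grid = n_grid
        self.method = method
        self.K = K
        self.sigma2_e = sigma2_e
        self.reml_algorithm = reml_algorithm
        self.reml_tol = reml_tol
        self.reml_max_iter = reml_max_iter
        self.gibbs_iter = gibbs_iter
        self.gibbs_burn_in = gibbs_burn_in
        self.gibbs_thin = gibbs_thin
        self.seed = seed
        self.track_loglik = track_loglik

    # ------------------------------------------------------------------

    def build_mme(self, pheno: pd.DataFrame,
                  relationships: RelationshipSet) -> RandomRegressionMME:
        """Assemble Henderson's equations for records carrying an ``eg``."""
        if "eg" not in pheno.columns:
            raise ValueError("phenotypes must carry an 'eg' column (assign_EG)")
        pheno = pheno.reset_index(drop=True)
        y = pheno["value"].to_numpy(dtype=float)
        basis = LegendreBasis(self.order, self.eg_max, self.n_grid)
        phi = basis.design(pheno["eg"].to_numpy(dtype=float))
        cg_labels, cg_codes = np.unique(pheno["cg"].to_numpy(), return_inverse=True)
        n_cg = len(cg_labels)
        X = np.ones((len(y), self.order + n_cg))
        X[:, : self.order] = phi  # fixed regressions omega
        for j in range(n_cg - 1):
            X[:, self.order + 1 + j] = (
                (cg_codes == j).astype(float) - (cg_codes == n_cg - 1)
            )
        animal_idx = relationships.ped.positions(pheno["animal"].to_numpy())
        self.basis_ = basis
        self.cg_labels_ = cg_labels
        return RandomRegressionMME(y, X, phi, animal_idx, relationships.H_inv)

    def fit(self, pheno: pd.DataFrame, relationships: RelationshipSet):
        mme = self.build_mme(pheno, relationships)
        K0 = None if self.K is None else np.atleast_2d(np.asarray(self.K, float))
        s0 = self.sigma2_e

        if self.method == "reml":
            kw = {} if self.reml_algorithm == "ai" else \
                {"track_loglik": self.track_loglik}
            res = reml_estimate(mme, algorithm=self.reml_algorithm,
                                K_start=K0, sigma2_e_start=s0,
                                tol=self.reml_tol,
                                max_iter=self.reml_max_iter, **kw)
            self.reml_result_ = res
            K_hat, s2e_hat = res.K, res.sigma2_e
        elif self.method == "gibbs":
            res = gibbs_sampler(mme, n_iter=self.gibbs_iter,
                                burn_in=self.gibbs_burn_in, thin=self.gibbs_thin,
                                seed=self.seed, K_start=K0, sigma2_e_start=s0)
            self.gibbs_result_ = res
            K_hat, s2e_hat = res.K, res.sigma2_e
        elif self.method == "fixed":
            if K0 is None or s0 is None:
                raise ValueError("method='fixed' requires K and sigma2_e")
            K_hat, s2e_hat = K0, float(s0)
        else:
            raise ValueError("method must be 'reml', 'gibbs' or 'fixed'")

        # components fixed, breeding values predicted (two-stage strategy)
        sol = mme.solve(K_hat, s2e_hat, return_inverse=True)
        self.mme_ = mme
        self.K_ = np.atleast_2d(K_hat)
        self.sigma2_e_ = float(s2e_hat)
        self.coef_ = sol.coef
        self.fixed_ = sol.beta
        self.solution_ = sol
        return self

    def predict(self, eg, animal_positions=None) -> np.ndarray:
        """GEBV of each animal at the requested EG values: ``phi(EG)' a_i``.

        Returns an (n_animals, n_eg) array; rows follow the relationship
        matrix unless ``animal_positions`` selects a subset.
        """
        phi = self.basis_.design(np.atleast_1d(np.asarray(eg, dtype=float)))
        coef = self.coef_ if animal_positions is None \
            else self.coef_[:, animal_positions]
        return coef.T @ phi.T

    def genetic_parameters(self) -> pd.DataFrame:
        """Genetic variance, heritability and correlation along the grid."""
        return genetic_params_along_EG(self.K_, self.sigma2_e_, self.basis_)

    @property
    def intercept_slope_correlation_(self) -> float:
        den = np.sqrt(self.K_[0, 0] * self.K_[1, 1])
        return float(self.K_[0, 1] / den) if den > 0 else float("nan")


def genetic_params_along_EG(K, sigma2_e: float,
                            basis: LegendreBasis) -> pd.DataFrame:
    """Per grid point: ``var_g = phi' K phi`` and ``h2 = var_g/(var_g + s2e)``.

    The intercept-slope genetic correlation is attached as a constant
    column (NaN when either variance is zero, where it is undefined).
    """
    K = np.atleast_2d(np.asarray(K, dtype=float))
    T = basis.grid_matrix
    var_g = np.einsum("gi,ij,gj->g", T, K, T)
    h2 = var_g / (var_g + sigma2_e) if sigma2_e >= 0 else np.full_like(var_g, np.nan)
    if K.shape[0] >= 2 and K[0, 0] > 0 and K[1, 1] > 0:
        r = K[0, 1] / np.sqrt(K[0, 0] * K[1, 1])
    else:
        r = np.nan
    return pd.DataFrame({"eg": basis.grid, "var_g": var_g, "h2": h2,
                         "r_int_slope": r})


# ----------------------------------------------------------------------
# liability <-> observed scale (Dempster-Lerner)


def _dl_factor(incidence: float) -> float:
    if not 0.0 < incidence < 1.0:
        raise ValueError("incidence must be in (0, 1)")
    t = stats.norm.ppf(1.0 - incidence)  # threshold with upper-tail mass p
    z = stats.norm.pdf(t)
    return z**2 / (incidence * (1.0 - incidence))


def h2_liability_to_observed(h2_liability: float, incidence: float) -> float:
    """Dempster-Lerner: ``h2_obs = h2_liab * z^2 / (p (1 - p))``."""
    if not 0.0 <= h2_liability <= 1.0:
        raise ValueError("heritability must be within [0, 1]")
    return h2_liability * _dl_factor(incidence)


def h2_observed_to_liability(h2_observed: float, incidence: float) -> float:
    """Inverse Dempster-Lerner transformation."""
    if not 0.0 <= h2_observed <= 1.0:
        raise ValueError("heritability must be within [0, 1]")
    return h2_observed / _dl_factor(incidence)
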