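"""Step 1 of the two-step reaction-norm analysis: the environmental gradient.

Contemporary-group (CG) solutions (BLUEs) for an environmental-descriptor
trait are estimated with a single-step GBLUP animal model, standardized to
mean 0 / SD 1 across CGs, validated against the nominal [-3, +3] range, and
attached to the analysis traits' records as the environmental gradient (EG).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .mixedmodel import RandomRegressionMME, reml_estimate
from .relmat import RelationshipSet

__all__ = ["AnimalModel", "EnvironmentalGradient", "standardize_EG", "assign_EG"]

logger = logging.getLogger(__name__)


@dataclass
class EnvironmentalGradient:
    """Standardized CG solutions: the environmental gradient.

    ``eg`` has mean 0 and sample SD 1 across CGs; values outside
    [-clamp, +clamp] are flagged and clamped.
    """

    cg: np.ndarray
    blue: np.ndarray
    eg: np.ndarray
    mean: float
    sd: float
    clamped: np.ndarray
    clamp: float = 3.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cg": self.cg, "blue": self.blue, "eg": self.eg,
             "clamped": self.clamped}
        )

    def as_mapping(self) -> dict:
        return dict(zip(self.cg.tolist(), self.eg.tolist()))


def standardize_EG(blues, clamp: float = 3.0, policy: str = "clamp") -> EnvironmentalGradient:
    """Standardize CG BLUEs to mean 0, sample SD 1 (the gradient itself).

    ``blues`` maps cg label -> BLUE (dict or Series).  Values beyond
    ``clamp`` SDs are flagged and either clamped (default) or dropped,
    keeping the gradient inside its declared range.
    """
    s = pd.Series(blues, dtype=float)
    if s.size < 2:
        raise ValueError("at least two contemporary groups are required")
    sd = float(s.std(ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("CG solutions have zero spread; gradient undefined")
    mean = float(s.mean())
    eg = (s.to_numpy() - mean) / sd
    clamped = np.abs(eg) > clamp
    if clamped.any():
        logger.warning("%d CG solutions beyond +/-%g SD (%s)",
                       clamped.sum(), clamp, policy)
    if policy == "clamp":
        eg = np.clip(eg, -clamp, clamp)
        keep = np.ones(len(eg), dtype=bool)
    elif policy == "drop":
        keep = ~clamped
    else:
        raise ValueError("policy must be 'clamp' or 'drop'")
    return EnvironmentalGradient(
        s.index.to_numpy()[keep], s.to_numpy()[keep], eg[keep],
        mean, sd, clamped[keep], clamp,
    )


def assign_EG(pheno: pd.DataFrame, eg: EnvironmentalGradient,
              cg_map: dict | None = None) -> pd.DataFrame:
    """Attach an ``eg`` column to trait records via their CG.

    ``cg_map`` translates a trait CG to a descriptor CG (identity by
    default).  Records in CGs with no gradient value are dropped and the
    count logged.
    """
    mapping = eg.as_mapping()
    cgs = pheno["cg"] if cg_map is None else pheno["cg"].map(cg_map)
    values = cgs.map(mapping)
    out = pheno.copy()
    out["eg"] = values.to_numpy()
    dropped = int(out["eg"].isna().sum())
    if dropped:
        logger.info("dropping %d records in CGs without a gradient value", dropped)
        out = out[out["eg"].notna()]
    return out.reset_index(drop=True)


class AnimalModel(BaseEstimator):
    """Single-step GBLUP animal model for contemporary-group BLUEs.

    Fits ``y = X beta + Z alpha + e`` with ``alpha ~ N(0, H sigma2_a)`` by
    Henderson's mixed-model equations.  The CG design uses an intercept
    plus sum-to-zero contrasts, so reported BLUEs (intercept + effect) are
    invariant to the constraint up to translation — which the gradient
    standardization removes.

    Parameters
    ----------
    var_a, var_e : float or None
        Variance components.  When either is None both are estimated by
        EM-REML before solving.
    reml_tol, reml_max_iter : EM-REML controls.

    Fitted attributes
    -----------------
    cg_labels_, blues_ : CG labels and their BLUE solutions.
    gebv_ : breeding value per animal of the relationship set.
    var_a_, var_e_ : variance components used.
    """

    def __init__(self, var_a=None, var_e=None, reml_tol: float = 1e-6,
                 reml_max_iter: int = 200, reml_algorithm: str = "ai"):
        self.var_a = var_a
        self.var_e = var_e
        self.reml_tol = reml_tol
        self.reml_max_iter = reml_max_iter
        self.reml_algorithm = reml_algorithm

    def fit(self, pheno: pd.DataFrame, relationships: RelationshipSet):
        """``pheno`` needs columns animal, cg, value; animals must be in the
        relationship set's pedigree."""
        pheno = pheno.reset_index(drop=True)
        y = pheno["value"].to_numpy(dtype=float)
        if len(y) == 0:
            raise ValueError("no phenotype records")
        cg_labels, cg_codes = np.unique(pheno["cg"].to_numpy(), return_inverse=True)
        n_cg = len(cg_labels)
        if n_cg < 1:
            raise ValueError("no contemporary groups")
        # intercept + sum-to-zero contrasts
        X = np.ones((len(y), n_cg))
        for j in range(n_cg - 1):
            X[:, j + 1] = (cg_codes == j).astype(float) - (cg_codes == n_cg - 1)
        animal_idx = relationships.ped.positions(pheno["animal"].to_numpy())
        phi = np.ones((len(y), 1))
        mme = RandomRegressionMME(y, X, phi, animal_idx, relationships.H_inv)

        var_a, var_e = self.var_a, self.var_e
        if var_a is None or var_e is None:
            res = reml_estimate(mme, algorithm=self.reml_algorithm,
                                tol=self.reml_tol,
                                max_iter=self.reml_max_iter)
            var_a, var_e = float(res.K[0, 0]), res.sigma2_e
            self.reml_result_ = res
        sol = mme.solve(np.array([[var_a]]), var_e)
        beta = np.nan_to_num(sol.beta)  # aliased contrasts (if any) -> 0
        mu = beta[0]
        effects = np.append(beta[1:n_cg], -beta[1:n_cg].sum())
        self.cg_labels_ = cg_labels
        self.blues_ = mu + effects
        self.gebv_ = sol.coef[0]
        self.var_a_ = float(var_a)
        self.var_e_ = float(var_e)
        self.n_records_ = len(y)
        return self

    def blues(self) -> pd.Series:
        return pd.Series(self.blues_, index=self.cg_labels_)

    def gradient(self, clamp: float = 3.0, policy: str = "clamp") -> EnvironmentalGradient:
        """Standardize the fitted BLUEs into the environmental gradient."""
        return standardize_EG(self.blues(), clamp=clamp, policy=policy)
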