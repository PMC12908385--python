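"""SNP effects back-solved from genomic breeding values, with significance.

Per random-regression coefficient c (intercept, slope), marker effects are
recovered from the GEBVs of the genotyped animals as

    u_c = M' [M M']^-1 a_c,

with M the matrix of 2p-centred genotype codes.  Approximate standard
errors come from the GEBV sampling covariance Var(a_c) = G sigma2_c - PEV_c
propagated through the same linear map, giving two-sided normal p-values

    p_i = 2 (1 - Phi(|u_i / sd_i|)).

Significance combines the fixed -log10(p) > 5 declaration rule with a
chromosome-wide Bonferroni companion whose number of independent tests is
the classic independent-chromosome-segment count Me = 2 Ne L / ln(4 Ne L)
(Ne = effective population size, L = chromosome map length in Morgans).
Effects of significant markers are mapped across the gradient as
trajectories ``SNP_k = T u_k`` on the Legendre grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .io import GenotypeMatrix
from .legendre import LegendreBasis

__all__ = [
    "SignificanceConfig",
    "backsolve_snp_effects",
    "snp_pvalues",
    "independent_segments",
    "significance_thresholds",
    "classify_snps",
    "snp_trajectories",
    "genomic_inflation_lambda",
    "run_gwas",
]

logger = logging.getLogger(__name__)

COEF_NAMES = ("int", "slope")


@dataclass
class SignificanceConfig:
    """Multiple-testing settings for SNP declaration."""

    alpha: float = 0.1
    ne: float = 196.0
    neglog10_cutoff: float = 5.0
    morgans_per_bp: float = 1e-8  # 1 cM per Mb
    chrom_lengths: dict = field(default_factory=dict)  # chrom -> Morgans


def _centered_M(geno: GenotypeMatrix) -> np.ndarray:
    p = geno.allele_frequencies()
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic markers present; run QC first")
    return geno.centered(p)


def _mmt_inverse(M: np.ndarray):
    """Inverse of M M', ridge-stabilized (and logged) when near-singular."""
    MMt = M @ M.T
    n = MMt.shape[0]
    w = np.linalg.eigvalsh(MMt)
    if w.min() <= 1e-10 * max(w.max(), 1.0):
        ridge = 1e-8 * np.trace(MMt) / n
        logger.warning("M M' near-singular; adding ridge %g to the diagonal", ridge)
        MMt = MMt + ridge * np.eye(n)
    return linalg.inv(MMt)


def backsolve_snp_effects(geno: GenotypeMatrix, gebv: np.ndarray) -> np.ndarray:
    """``u_c = M'[M M']^-1 a_c`` for each coefficient (row of ``gebv``).

    ``gebv`` is (n_coef, n_genotyped) with columns aligned to the genotype
    matrix rows; returns (n_coef, n_markers).
    """
    gebv = np.atleast_2d(np.asarray(gebv, dtype=float))
    if gebv.shape[1] != geno.n_animals:
        raise ValueError(
            f"GEBV vector covers {gebv.shape[1]} animals but the genotype "
            f"matrix has {geno.n_animals}"
        )
    M = _centered_M(geno)
    return (gebv @ _mmt_inverse(M)) @ M


def snp_pvalues(geno: GenotypeMatrix, gebv: np.ndarray,
                gebv_cov: np.ndarray | list) -> pd.DataFrame:
    """Back-solved effects with approximate SDs and two-sided p-values.

    ``gebv_cov[c]`` is the sampling covariance of the genotyped animals'
    GEBVs for coefficient c: ``Var(a_c) = G sigma2_c - PEV_c``.  Markers
    whose computed variance is negative (numerical) are clipped to zero and
    reported with p = 1.
    """
    gebv = np.atleast_2d(np.asarray(gebv, dtype=float))
    M = _centered_M(geno)
    MMt_inv = _mmt_inverse(M)
    B = MMt_inv @ M  # (n, m)
    out = {}
    n_clipped = 0
    for c in range(gebv.shape[0]):
        name = COEF_NAMES[c] if c < len(COEF_NAMES) else str(c)
        u = (gebv[c] @ MMt_inv) @ M
        V = np.asarray(gebv_cov[c], dtype=float)
        var_u = np.einsum("im,im->m", V @ B, B)
        neg = var_u < 0
        n_clipped += int(neg.sum())
        var_u = np.maximum(var_u, 0.0)
        sd = np.sqrt(var_u)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, np.abs(u) / sd, 0.0)
        p = 2.0 * stats.norm.sf(z)
        p = np.where(sd > 0, np.clip(p, np.finfo(float).tiny, 1.0), 1.0)
        out[f"u_{name}"] = u
        out[f"sd_{name}"] = sd
        out[f"p_{name}"] = p
        out[f"neglog10p_{name}"] = -np.log10(p)
    if n_clipped:
        logger.warning("clipped %d negative SNP-effect variances to zero",
                       n_clipped)
    table = geno.markers[["marker", "chrom", "bp"]].copy()
    for k, v in out.items():
        table[k] = v
    return table


def independent_segments(ne: float, length_morgans: float) -> float:
    """Effective number of independent segments: ``Me = 2 Ne L / ln(4 Ne L)``."""
    x = 4.0 * ne * length_morgans
    if x <= 1.0:
        raise ValueError("Ne * chromosome length too small for the Me formula")
    return 2.0 * ne * length_morgans / np.log(x)


def significance_thresholds(table: pd.DataFrame,
                            cfg: SignificanceConfig) -> pd.DataFrame:
    """Attach per-marker significance calls for every coefficient.

    For each chromosome the Bonferroni cutoff is ``alpha / Me`` with Me from
    :func:`independent_segments`; chromosome lengths default to the marker
    span converted at 1 cM/Mb.  Final declaration requires both the
    ``-log10(p) > cutoff`` rule and the chromosome-wide Bonferroni pass;
    both columns are also reported separately for audit.
    """
    table = table.copy()
    chroms = table["chrom"].unique()
    cutoffs = {}
    for ch in chroms:
        if ch in cfg.chrom_lengths:
            L = cfg.chrom_lengths[ch]
        else:
            bp = table.loc[table["chrom"] == ch, "bp"]
            L = float(bp.max()) * cfg.morgans_per_bp
            if L <= 0:
                raise ValueError(f"cannot derive a map length for chromosome {ch}")
        cutoffs[ch] = cfg.alpha / independent_segments(cfg.ne, L)
    bonf = table["chrom"].map(cutoffs).to_numpy(dtype=float)
    table["bonferroni_cutoff"] = bonf
    for c in COEF_NAMES:
        if f"p_{c}" not in table.columns:
            continue
        p = table[f"p_{c}"].to_numpy()
        table[f"pass_neglog10_{c}"] = -np.log10(p) > cfg.neglog10_cutoff
        table[f"pass_bonferroni_{c}"] = p < bonf
        table[f"significant_{c}"] = (
            table[f"pass_neglog10_{c}"] & table[f"pass_bonferroni_{c}"]
        )
    return table


def classify_snps(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Label each marker intercept_only / slope_only / shared / none.

    Returns the table with a ``classification`` column and the Venn counts
    of the significant classes.
    """
    table = table.copy()
    si = table["significant_int"].to_numpy(dtype=bool)
    ss = table["significant_slope"].to_numpy(dtype=bool)
    cls = np.where(si & ss, "shared",
                   np.where(si, "intercept_only",
                            np.where(ss, "slope_only", "none")))
    table["classification"] = cls
    counts = {k: int((cls == k).sum())
              for k in ("intercept_only", "slope_only", "shared")}
    return table, counts


def snp_trajectories(table: pd.DataFrame, basis: LegendreBasis,
                     significant_only: bool = True) -> pd.DataFrame:
    """Effect of each (significant) marker across the gradient: ``SNP_k = T u_k``.

    Long-format output: marker, eg, effect, plus a per-marker sign-change
    flag marking effects that cross zero inside the grid.
    """
    if significant_only:
        mask = table["significant_int"] | table["significant_slope"]
        table = table[mask]
    T = basis.grid_matrix
    rows = []
    for _, row in table.iterrows():
        u = np.array([row[f"u_{c}"] for c in COEF_NAMES[: T.shape[1]]])
        eff = T @ u
        sign_change = bool(eff.min() < 0 < eff.max())
        rows.append(pd.DataFrame({
            "marker": row["marker"], "eg": basis.grid, "effect": eff,
            "sign_change": sign_change,
        }))
    if not rows:
        return pd.DataFrame(columns=["marker", "eg", "effect", "sign_change"])
    return pd.concat(rows, ignore_index=True)


def genomic_inflation_lambda(pvalues: np.ndarray) -> float:
    """``lambda = median(chi2_1 quantile of 1 - p) / 0.4549364``."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 100:
        raise ValueError("need at least 100 p-values for a stable lambda")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, 1))


def run_gwas(geno: GenotypeMatrix, gebv: np.ndarray, gebv_cov,
             cfg: SignificanceConfig | None = None,
             basis: LegendreBasis | None = None) -> dict:
    """Back-solve, test, classify and trace SNP effects in one call.

    Returns a dict with the marker ``table``, ``venn`` counts,
    ``trajectories`` and the per-coefficient inflation factors ``lambda``.
    """
    cfg = cfg or SignificanceConfig()
    basis = basis or LegendreBasis(order=np.atleast_2d(gebv).shape[0])
    table = snp_pvalues(geno, gebv, gebv_cov)
    table = significance_thresholds(table, cfg)
    table, venn = classify_snps(table)
    traj = snp_trajectories(table, basis)
    lam = {c: genomic_inflation_lambda(table[f"p_{c}"].to_numpy())
           for c in COEF_NAMES if f"p_{c}" in table.columns}
    return {"table": table, "venn": venn, "trajectories": traj, "lambda": lam}
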