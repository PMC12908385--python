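"""Synthetic pedigreed populations with genotype-by-environment structure.

The generator emulates a multi-farm, multi-generation livestock population
of the kind reaction-norm analyses are applied to: discrete non-overlapping
generations under random mating, SNP genotypes gene-dropped along the
pedigree with Haldane recombination (1 cM ~ 1 Mb), contemporary groups (CGs)
acting as environmental units, and per-animal genetic intercept/slope
effects with a chosen 2x2 covariance ``K_true``.  Phenotypes follow the
reaction-norm model generatively:

    y = cg_effect + a_int phi0(EG) + a_slope phi1(EG) + e,

where the true environmental gradient EG is the standardized CG effect and
phi are the normalized Legendre basis functions used by the analysis.  A
separate environmental-descriptor trait (body-weight analogue) shares the
CG effects so the analysis pipeline can re-estimate the gradient, and a
binary trait is produced by thresholding a latent liability at the quantile
matching the requested incidence (coded 1 = failure, 2 = success).

Genetic effects decompose into marker-borne QTL effects (so SNP-detection
experiments have known targets) plus a polygenic remainder sized so the
total covariance equals ``K_true``.  The remainder is drawn either along
the pedigree (default) or spread over all markers as an infinitesimal
marker-effect model (``polygenic_mode="markers"``) for purely marker-borne
null simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    GenotypeMatrix,
    write_genotypes,
    write_marker_map,
    write_pedigree,
    write_phenotypes,
)
from .legendre import LegendreBasis
from .pedigree import Pedigree
from .relmat import inbreeding

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_pedigree",
    "drop_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "write_dataset",
]

MORGAN_PER_BP = 1e-8  # 1 cM per Mb


@dataclass
class SimulationConfig:
    """Parameters of the synthetic population.

    Variances are on the phenotype scale of the continuous trait; genetic
    intercept/slope covariance ``K_true`` must be symmetric PSD; marker
    allele frequencies are drawn uniformly within ``maf_range``.
    """

    n_founders: int = 80
    n_generations: int = 3
    n_offspring_per_mating: int = 2
    n_markers: int = 1_000
    n_chromosomes: int = 5
    chromosome_length_bp: int = 100_000_000
    maf_range: tuple = (0.05, 0.5)
    n_cg: int = 20
    min_cg_size: int = 5
    cg_effect_sd: float = 1.0
    K_true: tuple = ((4.0, 1.0), (1.0, 1.0))
    resid_var: float = 4.0
    n_qtl: int = 10
    qtl_effect_sd_int: float = 0.3
    qtl_effect_sd_slope: float = 0.15
    binary_incidence: float = 0.5
    descriptor_var_a: float = 1.0
    descriptor_var_e: float = 2.0
    polygenic_mode: str = "pedigree"  # or "markers"
    seed: int = 42

    def __post_init__(self) -> None:
        K = np.asarray(self.K_true, dtype=float)
        if K.shape != (2, 2) or not np.allclose(K, K.T):
            raise ValueError("K_true must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(K).min() < -1e-12:
            raise ValueError("K_true must be positive semi-definite")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("n_founders", "n_offspring_per_mating", "n_markers",
                     "n_chromosomes", "n_cg"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if not 0.0 < self.binary_incidence < 1.0:
            raise ValueError("binary_incidence must be in (0, 1)")
        if self.polygenic_mode not in ("pedigree", "markers"):
            raise ValueError("polygenic_mode must be 'pedigree' or 'markers'")

    @property
    def K(self) -> np.ndarray:
        return np.asarray(self.K_true, dtype=float)


@dataclass
class SyntheticDataset:
    """One simulated population with its generating truth."""

    ped: Pedigree
    sex: np.ndarray            # 0 = male, 1 = female, per pedigree row
    generation: np.ndarray
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame   # long format: animal, cg, trait, value
    truth: dict = field(default_factory=dict)
    config: SimulationConfig | None = None


# ----------------------------------------------------------------------


def simulate_pedigree(config: SimulationConfig, rng=None):
    """Discrete-generation random-mating pedigree.

    Returns ``(Pedigree, sex, generation)``.  Founders have unknown parents;
    every non-founder's sire and dam come from the previous generation and
    each dam is mated to one randomly chosen sire per season, producing
    ``n_offspring_per_mating`` offspring with random sex.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n0 = config.n_founders
    if n0 < 2:
        raise ValueError("need at least one male and one female founder")
    sex = np.zeros(n0, dtype=np.int64)
    sex[rng.permutation(n0)[: n0 // 2]] = 1  # half females

    sires: list[int] = [-1] * n0
    dams: list[int] = [-1] * n0
    gen = [0] * n0
    sex_all = sex.tolist()
    prev = list(range(n0))
    for g in range(1, config.n_generations + 1):
        males = [i for i in prev if sex_all[i] == 0]
        females = [i for i in prev if sex_all[i] == 1]
        if not males or not females:
            raise ValueError(
                f"generation {g - 1} lacks a male or a female; increase "
                "n_founders"
            )
        cur = []
        for dam in females:
            sire = males[rng.integers(len(males))]
            for _ in range(config.n_offspring_per_mating):
                idx = len(sires)
                sires.append(sire)
                dams.append(dam)
                gen.append(g)
                sex_all.append(int(rng.integers(2)))
                cur.append(idx)
        prev = cur

    ids = np.arange(1, len(sires) + 1)
    ped = Pedigree(ids, np.asarray(sires), np.asarray(dams))
    return ped, np.asarray(sex_all), np.asarray(gen)


def _marker_map(config: SimulationConfig, rng) -> pd.DataFrame:
    per_chrom = np.full(config.n_chromosomes, config.n_markers // config.n_chromosomes)
    per_chrom[: config.n_markers % config.n_chromosomes] += 1
    rows = []
    for c, k in enumerate(per_chrom, start=1):
        bp = np.sort(rng.choice(config.chromosome_length_bp, size=k, replace=False)) + 1
        rows.append(pd.DataFrame({"chrom": c, "bp": bp}))
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "marker", [f"snp{i + 1}" for i in range(len(out))])
    return out


def _recombination_probs(markers: pd.DataFrame) -> np.ndarray:
    """Per marker: probability of switching parental haplotype before it.

    Haldane map function on the physical distance to the previous marker;
    the first marker of each chromosome segregates independently (r = 0.5).
    """
    bp = markers["bp"].to_numpy(dtype=float)
    chrom = markers["chrom"].to_numpy()
    d = np.diff(bp) * MORGAN_PER_BP
    r = np.empty(len(bp))
    r[0] = 0.5
    r[1:] = 0.5 * (1.0 - np.exp(-2.0 * d))
    r[1:][chrom[1:] != chrom[:-1]] = 0.5
    return r


def _gametes(hap0, hap1, parent_rows, r, rng) -> np.ndarray:
    """Vectorized meiosis: one gamete per row of ``parent_rows``."""
    n, m = len(parent_rows), hap0.shape[1]
    switch = rng.random((n, m)) < r
    choose = np.cumsum(switch, axis=1) % 2  # 0 -> hap0, 1 -> hap1
    h0 = hap0[parent_rows]
    h1 = hap1[parent_rows]
    return np.where(choose == 0, h0, h1)


def drop_genotypes(
    ped: Pedigree,
    config: SimulationConfig,
    rng=None,
    markers: pd.DataFrame | None = None,
    founder_freqs: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Gene-drop genotypes (0/1/2) for every animal in the pedigree.

    Founders are sampled in Hardy-Weinberg proportions at frequencies drawn
    uniformly within ``maf_range``; descendants inherit one recombinant
    gamete per parent.  Requires both parents known for every non-founder.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if markers is None:
        markers = _marker_map(config, rng)
    m = len(markers)
    if founder_freqs is None:
        founder_freqs = rng.uniform(*config.maf_range, size=m)
    bad = (ped.sire < 0) != (ped.dam < 0)
    if bad.any():
        raise ValueError("non-founders must have both parents known")
    founder = ped.sire < 0
    r = _recombination_probs(markers)

    hap0 = np.zeros((ped.n, m), dtype=np.int8)
    hap1 = np.zeros((ped.n, m), dtype=np.int8)
    fidx = np.flatnonzero(founder)
    hap0[fidx] = rng.random((len(fidx), m)) < founder_freqs
    hap1[fidx] = rng.random((len(fidx), m)) < founder_freqs

    # process non-founders in topological order, batched by generation
    gen = ped.generations()
    for g in range(1, gen.max() + 1) if ped.n > len(fidx) else []:
        rows = np.flatnonzero(gen == g)
        hap0[rows] = _gametes(hap0, hap1, ped.sire[rows], r, rng)
        hap1[rows] = _gametes(hap0, hap1, ped.dam[rows], r, rng)

    codes = (hap0 + hap1).astype(float)
    return GenotypeMatrix(codes, ped.ids, markers)


# ----------------------------------------------------------------------


def _pedigree_polygenic(ped: Pedigree, K: np.ndarray, rng) -> np.ndarray:
    """Sample correlated (intercept, slope) effects along the pedigree.

    Founders ~ N(0, K); offspring get the parent average plus Mendelian
    sampling noise with covariance ``d_i K``, ``d_i = 0.5 - 0.25 (F_s + F_d)``,
    so the marginal covariance of every animal is (relationship-weighted) K.
    """
    dim = K.shape[0]
    w, U = np.linalg.eigh(K)
    if w.min() < -1e-10:
        raise ValueError("polygenic covariance must be PSD")
    L = U * np.sqrt(np.clip(w, 0.0, None))  # exact PSD factor, L L' = K
    F = inbreeding(ped)
    u = np.zeros((ped.n, dim))
    z = rng.standard_normal((ped.n, dim))
    for i in range(ped.n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (F[s] + F[d])
            u[i] = 0.5 * (u[s] + u[d]) + np.sqrt(max(di, 0.0)) * (L @ z[i])
        else:
            u[i] = L @ z[i]
    return u


def simulate_phenotypes(
    ped: Pedigree,
    geno: GenotypeMatrix,
    config: SimulationConfig,
    generation: np.ndarray,
    rng=None,
):
    """Phenotypes plus generating truth for all three trait kinds.

    Returns ``(phenotypes, truth)`` where ``truth`` holds per-animal genetic
    coefficients, per-CG effects/true gradient, and per-QTL marker effects.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = ped.n
    K = config.K

    # contemporary groups: random within generation, sizes >= min_cg_size
    cg_of = np.zeros(n, dtype=np.int64)
    next_cg = 0
    for g in np.unique(generation):
        rows = np.flatnonzero(generation == g)
        share = max(int(round(config.n_cg * len(rows) / n)), 1)
        share = min(share, max(len(rows) // config.min_cg_size, 1))
        perm = rng.permutation(rows)
        for j, chunk in enumerate(np.array_split(perm, share)):
            cg_of[chunk] = next_cg + j
        next_cg += share
    n_cg = next_cg
    cg_eff = rng.normal(0.0, config.cg_effect_sd, size=n_cg)
    sd = cg_eff.std(ddof=1)
    eg_true = (cg_eff - cg_eff.mean()) / sd if sd > 0 else np.zeros(n_cg)

    # genetic effects: QTL on real markers + polygenic remainder
    p = geno.allele_frequencies()
    Z = geno.centered(p)
    qtl_idx = np.sort(rng.choice(geno.n_markers, size=config.n_qtl, replace=False)) \
        if config.n_qtl > 0 else np.array([], dtype=int)
    beta = np.zeros((config.n_qtl, 2))
    a_qtl = np.zeros((n, 2))
    K_qtl = np.zeros((2, 2))
    if config.n_qtl > 0:
        beta[:, 0] = rng.normal(0.0, config.qtl_effect_sd_int, config.n_qtl)
        beta[:, 1] = rng.normal(0.0, config.qtl_effect_sd_slope, config.n_qtl)
        a_qtl = Z[:, qtl_idx] @ beta
        het = 2.0 * p[qtl_idx] * (1.0 - p[qtl_idx])
        K_qtl = np.diag(
            [config.qtl_effect_sd_int**2 * het.sum(),
             config.qtl_effect_sd_slope**2 * het.sum()]
        )
    K_poly = K - K_qtl
    if np.linalg.eigvalsh(K_poly).min() < -1e-10:
        raise ValueError(
            "expected QTL variance exceeds K_true; reduce n_qtl or the QTL "
            "effect SDs"
        )
    K_poly = np.clip(K_poly, None, None)

    if config.polygenic_mode == "markers":
        het_all = 2.0 * np.sum(p * (1.0 - p))
        wm, Um = np.linalg.eigh(K_poly / het_all)
        Lm = Um * np.sqrt(np.clip(wm, 0.0, None))
        b_poly = rng.standard_normal((geno.n_markers, 2)) @ Lm.T
        a_poly = Z @ b_poly
        u_w = Z @ (rng.standard_normal(geno.n_markers)
                   * np.sqrt(config.descriptor_var_a / het_all))
    else:
        a_poly = _pedigree_polygenic(ped, K_poly, rng)
        u_w = _pedigree_polygenic(
            ped, np.array([[config.descriptor_var_a]]), rng
        )[:, 0]
    a = a_qtl + a_poly

    basis = LegendreBasis(order=2)
    phi = basis.design(eg_true[cg_of])
    genetic = a[:, 0] * phi[:, 0] + a[:, 1] * phi[:, 1]

    y_cont = cg_eff[cg_of] + genetic + rng.normal(0, np.sqrt(config.resid_var), n)
    liab = cg_eff[cg_of] + genetic + rng.normal(0, np.sqrt(config.resid_var), n)
    thr = np.quantile(liab, 1.0 - config.binary_incidence)
    y_bin = np.where(liab > thr, 2, 1)
    y_desc = cg_eff[cg_of] + u_w + rng.normal(
        0, np.sqrt(config.descriptor_var_e), n
    )

    cg_label = np.array([f"cg{c + 1}" for c in range(n_cg)])
    frames = []
    for trait, val in (("descriptor", y_desc), ("continuous", y_cont),
                       ("binary", y_bin.astype(float))):
        frames.append(pd.DataFrame({
            "animal": ped.ids, "cg": cg_label[cg_of],
            "trait": trait, "value": val,
        }))
    phenotypes = pd.concat(frames, ignore_index=True)

    truth = {
        "animals": pd.DataFrame({
            "animal": ped.ids, "a_int": a[:, 0], "a_slope": a[:, 1],
            "cg": cg_label[cg_of],
        }),
        "cg": pd.DataFrame({
            "cg": cg_label, "effect": cg_eff, "eg_true": eg_true,
        }),
        "qtl": pd.DataFrame({
            "marker": geno.markers["marker"].to_numpy()[qtl_idx],
            "marker_index": qtl_idx,
            "effect_int": beta[:, 0], "effect_slope": beta[:, 1],
        }),
    }
    return phenotypes, truth


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full deterministic simulation from one config (seed-reproducible)."""
    rng = np.random.default_rng(config.seed)
    ped, sex, gen = simulate_pedigree(config, rng)
    geno = drop_genotypes(ped, config, rng)
    pheno, truth = simulate_phenotypes(ped, geno, config, gen, rng)
    return SyntheticDataset(ped, sex, gen, geno, pheno, truth, config)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Persist a dataset as the package's TSV dialects plus truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pedigree(ds.ped, outdir / "pedigree.tsv")
    write_genotypes(ds.genotypes, outdir / "genotypes.tsv")
    write_marker_map(ds.genotypes.markers, outdir / "markers.tsv")
    write_phenotypes(ds.phenotypes, outdir / "phenotypes.tsv")
    for name, frame in ds.truth.items():
        frame.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)
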