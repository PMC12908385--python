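"""Marker and phenotype quality control.

Marker QC applies, in this fixed order: non-autosomal removal, marker call
rate, minor allele frequency, Hardy-Weinberg equilibrium, then sample call
rate.  Boundary semantics follow the printed rules exactly: MAF *lower than*
the threshold and call rate *below* the threshold are strict comparisons,
while the HWE rule removes markers with p <= alpha (inclusive).

Phenotype QC removes, per contemporary group (CG): continuous records more
than ``sd_limit`` sample standard deviations from the CG mean (single pass);
binary CGs without variation (all 1s or all 2s); and finally CGs left with
fewer than ``min_cg`` records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix

__all__ = ["QcReport", "qc_markers", "filter_phenotypes", "hwe_chi2_pvalue"]


@dataclass
class QcReport:
    """Counts removed per rule, in application order."""

    removed: dict = field(default_factory=dict)
    retained_markers: int = 0
    retained_animals: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": list(self.removed), "removed": list(self.removed.values())}
        )


def hwe_chi2_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square Hardy-Weinberg test p-value from genotype counts."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    p = (2 * n_bb + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    stat = np.sum((obs - exp) ** 2 / exp)
    return float(stats.chi2.sf(stat, 1))


def _is_autosome(label) -> bool:
    try:
        return int(label) > 0
    except (TypeError, ValueError):
        return False


def qc_markers(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_alpha: float = 1e-5,
    call_rate_min: float = 0.90,
    autosomes_only: bool = True,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the marker/sample QC pipeline; see the module docstring for order.

    Raises ``ValueError`` if no marker survives.
    """
    report = QcReport()
    g = geno

    if autosomes_only:
        keep = np.array([_is_autosome(c) for c in g.markers["chrom"]])
        report.removed["non_autosomal"] = int((~keep).sum())
        g = g.subset(marker_mask=keep)
    else:
        report.removed["non_autosomal"] = 0

    marker_cr, _ = g.call_rates()
    keep = ~(marker_cr < call_rate_min)
    report.removed["marker_call_rate"] = int((~keep).sum())
    g = g.subset(marker_mask=keep)

    p = g.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    keep = ~(maf < maf_min)
    report.removed["maf"] = int((~keep).sum())
    g = g.subset(marker_mask=keep)

    hwe_p = np.empty(g.n_markers)
    for j in range(g.n_markers):
        col = g.codes[:, j]
        col = col[~np.isnan(col)]
        hwe_p[j] = hwe_chi2_pvalue(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    keep = hwe_p > hwe_alpha
    report.removed["hwe"] = int((~keep).sum())
    g = g.subset(marker_mask=keep)

    if g.n_markers == 0:
        raise ValueError("QC removed every marker; nothing left to analyse")

    _, sample_cr = g.call_rates()
    keep = ~(sample_cr < call_rate_min)
    report.removed["sample_call_rate"] = int((~keep).sum())
    g = g.subset(animal_mask=keep)

    report.retained_markers = g.n_markers
    report.retained_animals = g.n_animals
    return g, report


def filter_phenotypes(
    pheno: pd.DataFrame,
    sd_limit: float = 3.5,
    min_cg: int = 5,
    binary: bool = False,
) -> tuple[pd.DataFrame, QcReport]:
    """Phenotype filters for one trait (frame with ``cg`` and ``value``).

    Continuous traits: records outside CG mean +/- ``sd_limit`` CG sample SDs
    are removed in a single pass; a CG with zero SD loses no record to this
    rule.  Binary traits (values 1/2): CGs with no variation are removed
    wholesale.  Finally CGs with fewer than ``min_cg`` remaining records are
    dropped.
    """
    report = QcReport()
    df = pheno.copy()

    if binary:
        nunique = df.groupby("cg")["value"].transform("nunique")
        removed = int((nunique < 2).sum())
        report.removed["cg_no_variation"] = removed
        df = df[nunique >= 2]
    else:
        grp = df.groupby("cg")["value"]
        mean = grp.transform("mean")
        sd = grp.transform("std")  # ddof=1; NaN for singleton CGs
        dev = (df["value"] - mean).abs()
        out = (dev > sd_limit * sd) & sd.notna() & (sd > 0)
        report.removed["sd_outliers"] = int(out.sum())
        df = df[~out]

    size = df.groupby("cg")["value"].transform("size")
    report.removed["small_cg"] = int((size < min_cg).sum())
    df = df[size >= min_cg]

    report.retained_animals = len(df)
    return df.reset_index(drop=True), report
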