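"""Marker and phenotype quality-control rules, checked against hand fixtures."""

import numpy as np
import pandas as pd
import pytest

from rngwas import GenotypeMatrix, filter_phenotypes, qc_markers
from rngwas.qc import hwe_chi2_pvalue


def _geno(columns, chroms=None, ids=None):
    """Build a GenotypeMatrix from per-marker code lists."""
    codes = np.array(columns, dtype=float).T
    m = codes.shape[1]
    markers = pd.DataFrame({
        "marker": [f"m{i}" for i in range(m)],
        "chrom": chroms if chroms is not None else [1] * m,
        "bp": np.arange(1, m + 1) * 1000,
    })
    n = codes.shape[0]
    return GenotypeMatrix(codes, ids if ids is not None else np.arange(1, n + 1),
                          markers)


def _maf_column(p, n=100):
    """n genotype codes whose allele frequency is exactly p."""
    copies = int(round(2 * n * p))
    col = [2] * (copies // 2) + [1] * (copies % 2)
    return col + [0] * (n - len(col))


def test_maf_rule_is_strictly_lower_than():
    cols = [_maf_column(p) for p in (0.01, 0.05, 0.10, 0.30, 0.50)]
    geno = _geno(cols)
    out, report = qc_markers(geno, maf_min=0.05, hwe_alpha=0.0)
    assert report.removed["maf"] == 1  # only the 0.01 marker; 0.05 retained
    assert out.n_markers == 4


def test_perfect_hwe_marker_retained():
    col = [0] * 25 + [1] * 50 + [2] * 25
    assert hwe_chi2_pvalue(25, 50, 25) == 1.0
    out, report = qc_markers(_geno([col]), hwe_alpha=1e-5)
    assert report.removed["hwe"] == 0 and out.n_markers == 1


def test_hwe_violation_removed_inclusively():
    # no heterozygotes at p = 0.5: chi-square = n, p-value far below 1e-5
    col = [0] * 50 + [2] * 50
    good = [0] * 25 + [1] * 50 + [2] * 25
    out, report = qc_markers(_geno([col, good]), hwe_alpha=1e-5)
    assert report.removed["hwe"] == 1 and out.n_markers == 1


def test_marker_call_rate_strictly_below():
    col_bad = [np.nan] * 15 + [1] * 85          # call rate 0.85 -> removed
    col_edge = [np.nan] * 10 + [1] * 45 + [0] * 45  # exactly 0.90 -> kept
    geno = _geno([col_bad, col_edge, _maf_column(0.3)])
    out, report = qc_markers(geno, call_rate_min=0.90, maf_min=0.0,
                             hwe_alpha=0.0)
    assert report.removed["marker_call_rate"] == 1
    assert "m0" not in set(out.markers["marker"])


def _hwe_column(p, n=100):
    n_bb = int(round(n * p * p))
    n_ab = int(round(2 * n * p * (1 - p)))
    return [2] * n_bb + [1] * n_ab + [0] * (n - n_bb - n_ab)


def test_non_autosomal_markers_removed_first():
    geno = _geno([_hwe_column(0.3), _hwe_column(0.3)], chroms=[1, "X"])
    out, report = qc_markers(geno)
    assert report.removed["non_autosomal"] == 1
    assert list(out.markers["chrom"]) == [1]


def test_sample_call_rate_filter():
    codes = np.ones((10, 10))
    codes[0, :2] = np.nan  # sample 0 call rate 0.8
    markers = pd.DataFrame({"marker": [f"m{i}" for i in range(10)],
                            "chrom": 1, "bp": np.arange(10) + 1})
    # keep marker call rates at 0.9 (one missing entry among 10 samples)
    geno = GenotypeMatrix(codes, np.arange(10), markers)
    out, report = qc_markers(geno, maf_min=0.0, hwe_alpha=0.0,
                             call_rate_min=0.90)
    assert report.removed["sample_call_rate"] == 1
    assert out.n_animals == 9


def test_qc_is_idempotent(tiny_dataset):
    codes = tiny_dataset.genotypes.codes.copy()
    rng = np.random.default_rng(0)
    codes[rng.random(codes.shape) < 0.05] = np.nan
    geno = GenotypeMatrix(codes, tiny_dataset.genotypes.ids,
                          tiny_dataset.genotypes.markers)
    once, _ = qc_markers(geno)
    twice, rep2 = qc_markers(once)
    assert twice.n_markers == once.n_markers
    assert all(v == 0 for v in rep2.removed.values())


def test_all_markers_removed_raises():
    with pytest.raises(ValueError, match="every marker"):
        qc_markers(_geno([_maf_column(0.01)]), maf_min=0.05)


# ---------------------------------------------------------------- phenotypes


def test_sd_filter_uses_cg_sample_sd():
    # {10 x5, 100}: mean 25, sample SD ~36.7, deviation 2.04 SD -> kept
    pheno = pd.DataFrame({"cg": ["a"] * 6,
                          "value": [10, 10, 10, 10, 10, 100]})
    out, report = filter_phenotypes(pheno, sd_limit=3.5, min_cg=5)
    assert report.removed["sd_outliers"] == 0
    assert len(out) == 6


def test_sd_filter_removes_genuine_outlier():
    values = [10.0] * 19 + [10.5] + [60.0]  # z for 60 is far above 3.5
    pheno = pd.DataFrame({"cg": ["a"] * 21, "value": values})
    out, report = filter_phenotypes(pheno, sd_limit=3.5, min_cg=5)
    assert report.removed["sd_outliers"] == 1
    assert 60.0 not in out["value"].to_numpy()


def test_zero_sd_cg_loses_no_record():
    pheno = pd.DataFrame({"cg": ["a"] * 6, "value": [7.0] * 6})
    out, report = filter_phenotypes(pheno)
    assert report.removed["sd_outliers"] == 0 and len(out) == 6


def test_binary_cg_without_variation_removed():
    pheno = pd.DataFrame({
        "cg": ["a"] * 5 + ["b"] * 6,
        "value": [2.0] * 5 + [1.0, 2.0] * 3,
    })
    out, report = filter_phenotypes(pheno, binary=True)
    assert report.removed["cg_no_variation"] == 5
    assert set(out["cg"]) == {"b"}


def test_small_cg_removed_after_other_rules():
    pheno = pd.DataFrame({"cg": ["a"] * 4 + ["b"] * 5,
                          "value": np.arange(9, dtype=float)})
    out, report = filter_phenotypes(pheno, min_cg=5)
    assert report.removed["small_cg"] == 4
    assert set(out["cg"]) == {"b"}
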