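"""Positional-candidate windows and hypergeometric category enrichment.

Significant markers are intersected with user-supplied gene or QTL interval
sets inside a symmetric window (default +/-100 kb), and category
over-representation among the hit intervals is tested with the upper-tail
hypergeometric distribution against the supplied interval universe, with
Benjamini-Hochberg (default) or Bonferroni adjustment and a significance
flag at adjusted p < 0.10.

Coordinates are 1-based inclusive throughout (GFF3 convention); BED input
(0-based half-open) is converted on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "IntervalSet",
    "read_gff3",
    "read_bed",
    "window_candidates",
    "hypergeometric_enrichment",
]


@dataclass
class IntervalSet:
    """Genomic intervals with identifiers and a category label.

    ``frame`` columns: chrom, start, end (1-based inclusive), id, category.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end", "id", "category"}
        missing = need - set(self.frame.columns)
        if missing:
            raise ValueError(f"interval set lacks columns {sorted(missing)}")
        if (self.frame["start"] > self.frame["end"]).any():
            raise ValueError("interval start exceeds end")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)


_GFF_ID = re.compile(r"(?:^|;)(?:ID|gene_id|Name)=([^;]+)")


def read_gff3(path, feature_types=("gene",),
              category_from: str = "type") -> IntervalSet:
    """Read a GFF3 file into an IntervalSet (1-based inclusive, as stored).

    ``category_from`` is either "type" (the GFF3 feature type column) or an
    attribute key to pull from column 9.
    """
    frame = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "source", "type", "start", "end", "score",
               "strand", "phase", "attributes"],
        dtype={"chrom": str},
    )
    if feature_types:
        frame = frame[frame["type"].isin(feature_types)]
    ids = []
    for attr in frame["attributes"].astype(str):
        m = _GFF_ID.search(attr)
        ids.append(m.group(1) if m else attr[:40])
    if category_from == "type":
        cat = frame["type"].to_numpy()
    else:
        pat = re.compile(rf"(?:^|;){re.escape(category_from)}=([^;]+)")
        cat = [m.group(1) if (m := pat.search(a)) else "NA"
               for a in frame["attributes"].astype(str)]
    out = pd.DataFrame({
        "chrom": frame["chrom"].to_numpy(), "start": frame["start"].to_numpy(),
        "end": frame["end"].to_numpy(), "id": ids, "category": cat,
    })
    return IntervalSet(out)


def read_bed(path) -> IntervalSet:
    """Read a BED file (0-based half-open), converting to 1-based inclusive.

    Column 4 is the identifier; column 5 (if present) the category, else
    the identifier doubles as category.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", header=None,
                        dtype={0: str})
    if frame.shape[1] < 4:
        raise ValueError("BED input needs at least chrom/start/end/name")
    out = pd.DataFrame({
        "chrom": frame[0], "start": frame[1] + 1, "end": frame[2],
        "id": frame[3],
        "category": frame[4] if frame.shape[1] > 4 else frame[3],
    })
    return IntervalSet(out)


def window_candidates(snps: pd.DataFrame, intervals: IntervalSet,
                      window_bp: int = 100_000) -> pd.DataFrame:
    """Intervals overlapping a symmetric window around each marker.

    ``snps`` needs marker/chrom/bp columns (1-based).  An interval is a hit
    when ``[bp - window, bp + window]`` and ``[start, end]`` share at least
    one base; each marker-interval pair is listed once with the signed
    distance from marker to the nearest interval edge (0 when inside).
    """
    iv = intervals.frame
    snp_chroms = set(snps["chrom"].astype(str))
    iv_chroms = set(iv["chrom"].astype(str))
    orphan = snp_chroms - iv_chroms
    if orphan and not (snp_chroms & iv_chroms):
        raise ValueError(
            f"no interval chromosome matches the markers; offending marker "
            f"chromosomes: {sorted(orphan)[:10]}"
        )
    rows = []
    for _, snp in snps.iterrows():
        lo, hi = snp["bp"] - window_bp, snp["bp"] + window_bp
        sel = iv[(iv["chrom"].astype(str) == str(snp["chrom"]))
                 & (iv["end"] >= lo) & (iv["start"] <= hi)]
        for _, g in sel.iterrows():
            if g["start"] <= snp["bp"] <= g["end"]:
                dist = 0
            elif snp["bp"] < g["start"]:
                dist = int(g["start"] - snp["bp"])
            else:
                dist = int(snp["bp"] - g["end"])
            rows.append((snp["marker"], g["id"], g["category"], dist))
    return pd.DataFrame(rows, columns=["marker", "id", "category", "distance"]) \
        .drop_duplicates(["marker", "id"]).reset_index(drop=True)


def hypergeometric_enrichment(candidates: pd.DataFrame,
                              universe: IntervalSet,
                              adjust: str = "bh",
                              alpha: float = 0.10) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per category.

    The universe is the supplied interval set; the draw is the set of
    distinct candidate intervals.  ``P[X >= k]`` with X ~
    Hypergeom(N=universe size, K=category size, n=draw size), adjusted
    across categories by Benjamini-Hochberg ("bh") or "bonferroni", flagged
    at adjusted p < ``alpha``.
    """
    uni = universe.frame.drop_duplicates("id")
    N = len(uni)
    drawn = candidates.drop_duplicates("id")
    n = len(drawn)
    cat_sizes = uni.groupby("category")["id"].nunique()
    hits = drawn.groupby("category")["id"].nunique()
    rows = []
    for cat, K in cat_sizes.items():
        k = int(hits.get(cat, 0))
        if k > K:
            raise ValueError(
                f"category {cat!r}: {k} hits exceed category size {K}"
            )
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append((cat, k, int(K), p))
    out = pd.DataFrame(rows, columns=["category", "hits", "category_size",
                                      "p_value"])
    if len(out):
        method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[adjust]
        out["adj_p_value"] = multipletests(out["p_value"], method=method)[1]
        out["significant"] = out["adj_p_value"] < alpha
        out = out.sort_values("p_value", ignore_index=True)
    return out
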