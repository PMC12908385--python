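"""Tab-separated readers/writers for pedigree, genotype, map and phenotype tables.

Dialects
--------
pedigree.tsv   : animal, sire, dam            (0 = unknown parent)
genotypes.tsv  : animal, <marker1>, ...       (codes 0/1/2, NA = missing)
markers.tsv    : marker, chrom, bp            (bp 1-based)
phenotypes.tsv : animal, cg, trait, value     (binary traits coded 1/2)

All writers round-trip: ``read(write(x)) == x``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = [
    "GenotypeMatrix",
    "read_pedigree",
    "write_pedigree",
    "read_genotypes",
    "write_genotypes",
    "read_marker_map",
    "write_marker_map",
    "read_phenotypes",
    "write_phenotypes",
]

PHENO_COLUMNS = ["animal", "cg", "trait", "value"]


@dataclass
class GenotypeMatrix:
    """Animals x markers genotype codes with the marker map.

    ``codes`` is a float array with entries in {0, 1, 2} and NaN for missing
    calls; ``ids`` labels the rows; ``markers`` is a (marker, chrom, bp)
    frame labelling the columns.
    """

    codes: np.ndarray
    ids: np.ndarray
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        self.ids = np.asarray(self.ids)
        self.markers = self.markers.reset_index(drop=True)
        if self.codes.shape != (len(self.ids), len(self.markers)):
            raise ValueError(
                f"genotype matrix {self.codes.shape} does not match "
                f"{len(self.ids)} animals x {len(self.markers)} markers"
            )
        observed = self.codes[~np.isnan(self.codes)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")

    @property
    def n_animals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Observed alternate-allele frequency per marker (missing ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.codes, axis=0) / 2.0

    def call_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(marker call rate, sample call rate)."""
        called = ~np.isnan(self.codes)
        return called.mean(axis=0), called.mean(axis=1)

    def imputed(self, p: np.ndarray | None = None) -> np.ndarray:
        """Codes with missing entries filled by the marker mean ``2 p_i``."""
        if p is None:
            p = self.allele_frequencies()
        out = self.codes.copy()
        fill = np.broadcast_to(2.0 * p, out.shape)
        mask = np.isnan(out)
        out[mask] = fill[mask]
        return out

    def centered(self, p: np.ndarray | None = None) -> np.ndarray:
        """Mean-imputed codes centred by ``2 p_i`` (the M - P of GBLUP)."""
        if p is None:
            p = self.allele_frequencies()
        return self.imputed(p) - 2.0 * p

    def subset(self, animal_mask=None, marker_mask=None) -> "GenotypeMatrix":
        codes, ids, markers = self.codes, self.ids, self.markers
        if animal_mask is not None:
            codes, ids = codes[animal_mask], ids[animal_mask]
        if marker_mask is not None:
            codes = codes[:, marker_mask]
            markers = markers.loc[np.asarray(marker_mask)].reset_index(drop=True)
        return GenotypeMatrix(codes, ids, markers)


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValueError(f"cannot parse {path}: {exc}") from exc


def read_pedigree(path) -> Pedigree:
    frame = _read_tsv(path)
    if frame.shape[1] < 3:
        raise ValueError(f"{path}: pedigree needs animal/sire/dam columns")
    return Pedigree.from_frame(frame, unknown=0)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame(unknown=0).to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> pd.DataFrame:
    frame = _read_tsv(path)
    need = {"marker", "chrom", "bp"}
    if not need.issubset(frame.columns):
        raise ValueError(f"{path}: marker map needs columns {sorted(need)}")
    return frame[["marker", "chrom", "bp"]]


def write_marker_map(markers: pd.DataFrame, path) -> None:
    markers.to_csv(path, sep="\t", index=False)


def read_genotypes(path, markers: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a genotype TSV; validates codes and reports the offending line."""
    frame = _read_tsv(path)
    ids = frame.iloc[:, 0].to_numpy()
    if len(set(ids.tolist())) != len(ids):
        raise ValueError(f"{path}: duplicate animal ids")
    body = frame.iloc[:, 1:]
    values = body.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    # tokens that were present but not numeric 0/1/2 (NA is allowed)
    bad = np.isnan(values) & body.notna().to_numpy() & (body != "NA").to_numpy()
    bad |= ~np.isnan(values) & ~np.isin(values, (0.0, 1.0, 2.0))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: invalid genotype token {body.iat[r, c]!r} at line {r + 2}, "
            f"column {body.columns[c]!r}"
        )
    if markers is None:
        markers = pd.DataFrame(
            {"marker": body.columns, "chrom": 0, "bp": np.arange(1, body.shape[1] + 1)}
        )
    else:
        if list(markers["marker"]) != list(body.columns):
            raise ValueError(f"{path}: marker columns do not match the marker map")
    return GenotypeMatrix(values, ids, markers)


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    frame = pd.DataFrame(geno.codes, columns=geno.markers["marker"])
    frame = frame.astype("Int64")  # keeps 0/1/2 integral, NA for missing
    frame.insert(0, "animal", geno.ids)
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        return pd.DataFrame(columns=PHENO_COLUMNS)
    frame = _read_tsv(path)
    if frame.empty:
        return pd.DataFrame(columns=PHENO_COLUMNS)
    missing = set(PHENO_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: phenotype table lacks columns {sorted(missing)}")
    return frame[PHENO_COLUMNS]


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno[PHENO_COLUMNS].to_csv(path, sep="\t", index=False)
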