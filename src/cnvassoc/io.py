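"""Plain-text I/O for LRR matrices, phenotype tables and region files.

Conventions: marker indices are 0-based half-open internally and in BED
output; human-readable TSV reports use 1-based inclusive positions.  One
chromosome per table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("cnvassoc")

__all__ = [
    "LrrTable",
    "PhenotypeTable",
    "read_lrr",
    "read_phenotype",
    "write_lrr",
    "write_bed",
    "write_tsv",
]

_LRR_META = ("marker", "chrom", "pos")


@dataclass(frozen=True)
class LrrTable:
    """LRR matrix for one chromosome: markers x samples on disk,
    subjects x markers in memory (``matrix``)."""

    markers: np.ndarray  # marker ids (str)
    chrom: str
    positions: np.ndarray  # 1-based bp, strictly increasing
    samples: tuple[str, ...]
    matrix: np.ndarray  # n_samples x n_markers, float

    @property
    def n_markers(self) -> int:
        return self.positions.size

    def series(self, sample: str):
        from .segmentation import IntensitySeries

        idx = self.samples.index(sample)
        return IntensitySeries(self.matrix[idx], self.positions, self.chrom)


@dataclass(frozen=True)
class PhenotypeTable:
    samples: tuple[str, ...]
    phenotype: np.ndarray
    covariates: Optional[np.ndarray] = None
    covariate_names: tuple[str, ...] = ()

    def aligned_to(self, sample_order: Sequence[str]) -> "PhenotypeTable":
        """Reorder rows to match an LrrTable's sample columns."""
        missing = set(sample_order) ^ set(self.samples)
        if missing:
            raise ValueError(
                "sample mismatch between LRR and phenotype tables: "
                + ", ".join(sorted(missing))
            )
        idx = [self.samples.index(s) for s in sample_order]
        cov = self.covariates[idx] if self.covariates is not None else None
        return PhenotypeTable(tuple(sample_order), self.phenotype[idx], cov,
                              self.covariate_names)


def read_lrr(path, drop_missing: bool = True) -> LrrTable:
    """Read a tab-separated LRR file (marker, chrom, pos, sample1..sampleN).

    Rows with missing or non-numeric intensities are dropped (count
    logged) unless drop_missing is False, in which case they are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    for col in _LRR_META:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    sample_cols = [c for c in df.columns if c not in _LRR_META]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns found")
    vals = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    bad = vals.isna()
    if bad.any().any():
        if not drop_missing:
            r, c = np.argwhere(bad.values)[0]
            raise ValueError(
                f"{path}: non-numeric value at data row {r + 1}, "
                f"column {sample_cols[c]!r}"
            )
        n_bad = int(bad.any(axis=1).sum())
        log.warning("%s: dropping %d row(s) with missing values", path, n_bad)
        keep = ~bad.any(axis=1)
        df, vals = df[keep], vals[keep]
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"{path}: expected one chromosome, found {list(chroms)}")
    pos = df["pos"].to_numpy()
    if not (np.diff(pos) > 0).all():
        raise ValueError(f"{path}: positions must be strictly increasing")
    return LrrTable(
        markers=df["marker"].to_numpy(dtype=str),
        chrom=str(chroms[0]),
        positions=pos,
        samples=tuple(sample_cols),
        matrix=np.ascontiguousarray(vals.to_numpy(dtype=float).T),
    )


def write_lrr(table: LrrTable, path) -> None:
    meta = pd.DataFrame({"marker": table.markers, "chrom": table.chrom,
                         "pos": table.positions})
    vals = pd.DataFrame(table.matrix.T, columns=list(table.samples))
    pd.concat([meta, vals], axis=1).to_csv(path, sep="\t", index=False)


def read_phenotype(path) -> PhenotypeTable:
    """Read a tab-separated phenotype file (sample, phenotype[, covars...])."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    for col in ("sample", "phenotype"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated sample id {dup!r}")
    cov_names = tuple(c for c in df.columns if c not in ("sample", "phenotype"))
    cov = df[list(cov_names)].to_numpy(dtype=float) if cov_names else None
    return PhenotypeTable(
        samples=tuple(df["sample"]),
        phenotype=df["phenotype"].to_numpy(dtype=float),
        covariates=cov,
        covariate_names=cov_names,
    )


def write_bed(intervals, path, chrom: str = "chr0", positions=None) -> None:
    """Write intervals as BED (0-based half-open).

    ``intervals`` is an iterable of objects with start/end marker indices
    plus optional sample/direction/mean attributes (CnvCall, Segment,
    DetectedRegion, CommonRegion all qualify).  When marker ``positions``
    are given, start/end are mapped to genomic coordinates (BED start =
    pos[start] - 1, end = pos[end - 1]).
    """
    rows = []
    for iv in intervals:
        start, end = iv.start, iv.end
        if positions is not None:
            bstart, bend = int(positions[start]) - 1, int(positions[end - 1])
        else:
            bstart, bend = start, end
        name = getattr(iv, "sample", None) or getattr(iv, "direction", ".")
        score = (
            getattr(iv, "segment_mean", None)
            or getattr(iv, "mean", None)
            or getattr(iv, "mean_transformed", None)
            or 0.0
        )
        rows.append((chrom, bstart, bend, name, f"{score:.6g}", end - start))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
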