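"""Core containers and feature transforms for binned single-cell CNA data.

The unit of analysis is a fixed-width genomic bin.  For ``n`` cells and ``m``
bins the raw inputs are a non-negative integer read-count matrix ``R`` and a
B-allele-frequency (BAF) matrix ``Y``, both cell-by-bin.  Two derived features
drive everything downstream:

* the read-depth ratio (RDR) -- the bias-normalized count divided by the
  cell's mean count, so each cell's RDR averages 1 and is proportional to
  ``total copy number / ploidy``;
* the mirrored BAF (mBAF) ``min(Y, 1 - Y)``, which folds the arbitrary
  labelling of the two alleles into ``[0, 0.5]`` so that e.g. states {2,3}
  and {3,2} look identical.

Allele-specific copy-number states are unordered pairs ``{c_minor, c_major}``.
Masked bins (extreme GC, poor mappability) carry NaN in every derived matrix
and are excluded -- never imputed -- from all means, fits and likelihoods.
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinTable",
    "CellBinMatrices",
    "CopyState",
    "StateSpace",
    "ZeroCoverageCellError",
    "compute_features",
    "expected_state_mean",
    "read_matrix_tsv",
    "write_matrix_tsv",
]

BIN_TABLE_COLUMNS = ("chrom", "start", "end", "gc", "mappability", "masked")


class ZeroCoverageCellError(ValueError):
    """Raised when one or more cells have zero total read count."""

    def __init__(self, cell_indices: Sequence[int]):
        self.cell_indices = list(cell_indices)
        super().__init__(
            f"cells with zero coverage over unmasked bins: {self.cell_indices}"
        )


@dataclass(frozen=True)
class BinTable:
    """Genomic bin annotations shared by all cell-by-bin matrices.

    Wraps a DataFrame with columns ``chrom, start, end, gc, mappability,
    masked``.  Bins must be grouped by chromosome and, within a chromosome,
    sorted and non-overlapping.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.reset_index(drop=True).copy()
        if "masked" not in df.columns:
            df["masked"] = False
        missing = [c for c in BIN_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"bin table missing columns: {missing}")
        df = df[list(BIN_TABLE_COLUMNS)]
        if (df["end"] <= df["start"]).any():
            raise ValueError("every bin must satisfy end > start")
        seen = []
        for chrom, grp in df.groupby("chrom", sort=False):
            if chrom in seen:
                raise ValueError(f"bins of chromosome {chrom} are not contiguous")
            seen.append(chrom)
            starts, ends = grp["start"].to_numpy(), grp["end"].to_numpy()
            if not (starts[1:] >= ends[:-1]).all():
                raise ValueError(f"bins overlap or are unsorted on {chrom}")
        object.__setattr__(self, "df", df)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_bins(self) -> int:
        return len(self.df)

    @property
    def masked(self) -> np.ndarray:
        """Boolean mask, True where the bin is excluded from analysis."""
        return self.df["masked"].to_numpy(dtype=bool)

    @property
    def unmasked_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.masked)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def chromosome_spans(self) -> list[tuple[str, int, int]]:
        """Half-open genome-wide bin index range ``(chrom, lo, hi)`` per chromosome."""
        spans = []
        for chrom, grp in self.df.groupby("chrom", sort=False):
            spans.append((chrom, int(grp.index[0]), int(grp.index[-1]) + 1))
        return spans

    def bin_ids(self) -> list[str]:
        return [
            f"{c}:{s}-{e}"
            for c, s, e in zip(self.df["chrom"], self.df["start"], self.df["end"])
        ]

    def with_mask(self, masked: np.ndarray) -> "BinTable":
        df = self.df.copy()
        df["masked"] = np.asarray(masked, dtype=bool)
        return BinTable(df)

    # -- IO ----------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "BinTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


class CopyState(NamedTuple):
    """Unordered allele-specific copy-number state ``{c_minor, c_major}``."""

    c_minor: int
    c_major: int

    @classmethod
    def make(cls, a: int, b: int) -> "CopyState":
        a, b = int(a), int(b)
        if a < 0 or b < 0:
            raise ValueError("copy numbers must be non-negative")
        return cls(min(a, b), max(a, b))

    @property
    def total(self) -> int:
        return self.c_minor + self.c_major


@dataclass(frozen=True)
class StateSpace:
    """All copy states with total copy number at most ``max_total``."""

    max_total: int
    states: tuple[CopyState, ...] = field(init=False)

    def __post_init__(self):
        if self.max_total < 0:
            raise ValueError("max_total must be >= 0")
        states = tuple(
            CopyState(minor, total - minor)
            for total in range(self.max_total + 1)
            for minor in range(total // 2 + 1)
        )
        object.__setattr__(self, "states", states)

    def __len__(self) -> int:
        return len(self.states)

    def as_array(self) -> np.ndarray:
        """(S, 2) integer array of (c_minor, c_major) rows, ordered by (total, minor)."""
        return np.array(self.states, dtype=int)


def expected_state_mean(state: CopyState, ploidy: float) -> tuple[float, float]:
    """Expected (RDR, mBAF) of a copy state in a cell of the given ploidy.

    RDR is ``total / ploidy``; mBAF is ``c_minor / total``.  A nullisomic
    state (total 0) has no allelic-imbalance signal and is given mBAF 0.5 so
    that it never attracts extreme-mBAF bins.
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    total = state.c_minor + state.c_major
    rdr = total / ploidy
    mbaf = 0.5 if total == 0 else min(state.c_minor, state.c_major) / total
    return rdr, mbaf


@dataclass
class CellBinMatrices:
    """Raw and derived cell-by-bin matrices for one dataset.

    Attributes
    ----------
    cell_ids : list of str
    R : (n, m) int array, raw read counts (kept raw even at masked bins).
    X : (n, m) float array, bias-normalized counts; NaN at masked bins.
    X_bar : (n,) per-cell mean of X over unmasked bins.
    rdr : (n, m) read-depth ratios ``X / X_bar``; NaN at masked bins.
    baf : (n, m) B-allele frequencies in [0, 1]; NaN at masked bins.
    mbaf : (n, m) mirrored BAF ``min(baf, 1 - baf)``; NaN at masked bins.
    bin_table : BinTable the matrices are aligned to.
    """

    cell_ids: list[str]
    R: np.ndarray
    X: np.ndarray
    X_bar: np.ndarray
    rdr: np.ndarray
    baf: np.ndarray
    mbaf: np.ndarray
    bin_table: BinTable

    @property
    def n_cells(self) -> int:
        return self.R.shape[0]

    @property
    def n_bins(self) -> int:
        return self.R.shape[1]

    def feature_points(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Stack unmasked (RDR, mBAF) pairs across all cells.

        Returns ``(points, cell_idx, bin_idx)`` where ``points`` is (N, 2).
        """
        unmasked = self.bin_table.unmasked_idx
        n = self.n_cells
        cell_idx = np.repeat(np.arange(n), unmasked.size)
        bin_idx = np.tile(unmasked, n)
        pts = np.column_stack(
            [self.rdr[cell_idx, bin_idx], self.mbaf[cell_idx, bin_idx]]
        )
        return pts, cell_idx, bin_idx


def compute_features(
    R: np.ndarray,
    baf: np.ndarray,
    norm_factors: np.ndarray,
    bin_table: BinTable,
    cell_ids: Sequence[str] | None = None,
) -> CellBinMatrices:
    """Turn raw counts and BAFs into normalized counts, RDR and mBAF.

    ``X_ij = R_ij / lambda_j`` with per-bin normalization factors lambda,
    then ``rdr_ij = X_ij / mean_j(X_ij)`` over unmasked bins.  Cells whose
    mean normalized count is zero cannot be scaled and are rejected with
    :class:`ZeroCoverageCellError`.  Zero-count bins inside valid cells keep
    RDR 0 -- a legitimate homozygous-deletion signal.
    """
    R = np.asarray(R)
    baf = np.asarray(baf, dtype=float)
    lam = np.asarray(norm_factors, dtype=float)
    if R.ndim != 2 or baf.shape != R.shape:
        raise ValueError("R and baf must be 2D arrays of identical shape")
    if R.shape[1] != bin_table.n_bins or lam.shape != (bin_table.n_bins,):
        raise ValueError("bin dimension mismatch between matrices and bin table")
    if (R < 0).any():
        raise ValueError("read counts must be non-negative")
    masked = bin_table.masked
    if (~masked).sum() == 0:
        raise ValueError("all bins are masked")
    if np.any(lam[~masked] <= 0) or np.any(~np.isfinite(lam[~masked])):
        raise ValueError("normalization factors must be positive on unmasked bins")

    n = R.shape[0]
    if cell_ids is None:
        cell_ids = [f"cell_{i}" for i in range(n)]

    X = R.astype(float) / lam[None, :]
    X[:, masked] = np.nan
    X_bar = np.nanmean(X, axis=1)
    dead = np.flatnonzero(X_bar == 0)
    if dead.size:
        raise ZeroCoverageCellError(dead)
    rdr = X / X_bar[:, None]
    baf = baf.copy()
    baf[:, masked] = np.nan
    mbaf = np.minimum(baf, 1.0 - baf)
    return CellBinMatrices(
        cell_ids=list(cell_ids),
        R=R,
        X=X,
        X_bar=X_bar,
        rdr=rdr,
        baf=baf,
        mbaf=mbaf,
        bin_table=bin_table,
    )


# ---------------------------------------------------------------------------
# Matrix IO: TSV with the cell ID in the first column and bin IDs of the form
# chrom:start-end as the remaining column headers.
# ---------------------------------------------------------------------------

def write_matrix_tsv(
    path: str | Path,
    matrix: np.ndarray,
    cell_ids: Sequence[str],
    bin_table: BinTable,
) -> None:
    df = pd.DataFrame(matrix, index=list(cell_ids), columns=bin_table.bin_ids())
    df.index.name = "cell"
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a cell-by-bin TSV; returns ``(matrix, cell_ids, bin_ids)``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), [str(c) for c in df.index], list(df.columns)
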