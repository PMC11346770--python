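"""Bin masking, normal-cell detection and read-count normalization.

Normal (diploid, CNA-free) cells have flat read-count profiles, so their Gini
coefficient over bin counts sits near 0 while aneuploid cells with multi-state
profiles score higher.  Cells at or below a Gini threshold form the normal set
``D``; the per-bin normalization factor is then

    lambda_j = mean over d in D of  R_dj / R_bar_d,

the expected fractional deviation of bin j's count, which soaks up GC,
mappability and other locus-specific biases.  When no normal cells are found,
lambda falls back to a smooth fit of the median count ratio on GC content with
a mappability correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data_model import BinTable

__all__ = [
    "AllBinsMaskedError",
    "NormalizationProfile",
    "gini_coefficient",
    "identify_normal_cells",
    "mask_bins",
    "normalization_factors",
]


class AllBinsMaskedError(ValueError):
    """Raised when GC/mappability masking removes every bin."""


@dataclass
class NormalizationProfile:
    """Per-bin factors and the diagnostics behind them.

    ``factors`` is NaN at masked bins.  ``normal_cells`` is the detected set
    D (empty when the GC fallback was used).  ``gini`` holds the per-cell
    Gini coefficients used for the detection and ``r_bar`` the mean read
    count of each normal cell over unmasked bins.
    """

    factors: np.ndarray
    normal_cells: set[int]
    gini: np.ndarray
    r_bar: dict[int, float] | None = None
    used_fallback: bool = False


def mask_bins(
    bin_table: BinTable,
    gc_low: float = 0.2,
    gc_high: float = 0.8,
    map_min: float = 0.9,
) -> BinTable:
    """Mask bins with extreme GC (< gc_low or > gc_high) or mappability < map_min.

    Boundary values are kept (the inequalities are strict).  Bins already
    masked stay masked.
    """
    if not (0 <= gc_low < gc_high <= 1):
        raise ValueError("require 0 <= gc_low < gc_high <= 1")
    gc = bin_table.df["gc"].to_numpy(dtype=float)
    mp = bin_table.df["mappability"].to_numpy(dtype=float)
    masked = bin_table.masked | (gc < gc_low) | (gc > gc_high) | (mp < map_min)
    if masked.all():
        raise AllBinsMaskedError("GC/mappability filters removed every bin")
    return bin_table.with_mask(masked)


def gini_coefficient(counts: np.ndarray) -> float:
    """Gini coefficient ``sum_ij |x_i - x_j| / (2 n^2 mean)`` of a count vector."""
    x = np.asarray(counts, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty count vector")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero count vector has no Gini coefficient")
    # O(n log n) equivalent of the pairwise-difference formula.
    xs = np.sort(x)
    n = x.size
    ranks = np.arange(1, n + 1)
    return float((2.0 * (ranks * xs).sum()) / (n * total) - (n + 1) / n)


def identify_normal_cells(
    R: np.ndarray,
    gini_threshold: float = 0.12,
    bin_table: BinTable | None = None,
) -> set[int]:
    """Cells whose Gini coefficient over (unmasked) bin counts is <= threshold.

    Returns an empty set, not an error, when no cell qualifies.
    """
    R = np.asarray(R)
    cols = slice(None) if bin_table is None else bin_table.unmasked_idx
    out = set()
    for i in range(R.shape[0]):
        if gini_coefficient(R[i, cols]) <= gini_threshold:
            out.add(i)
    return out


def _fallback_factors(
    R: np.ndarray, bin_table: BinTable, frac: float
) -> np.ndarray:
    # Two-factor correction: remove the mappability effect, LOWESS the median
    # count ratio against GC, then restore mappability and rescale to mean 1.
    unmasked = bin_table.unmasked_idx
    gc = bin_table.df["gc"].to_numpy(dtype=float)[unmasked]
    mp = bin_table.df["mappability"].to_numpy(dtype=float)[unmasked]
    sub = R[:, unmasked].astype(float)
    cell_mean = sub.mean(axis=1)
    if (cell_mean == 0).any():
        raise ValueError("cells with zero coverage cannot inform the GC fallback")
    ratio = np.median(sub / cell_mean[:, None], axis=0) / mp
    smooth = lowess(ratio, gc, frac=frac, return_sorted=False)
    lam_un = smooth * mp
    lam_un = np.maximum(lam_un, 1e-6)
    lam_un /= lam_un.mean()
    lam = np.full(bin_table.n_bins, np.nan)
    lam[unmasked] = lam_un
    return lam


def normalization_factors(
    R: np.ndarray,
    normal_cells: set[int],
    bin_table: BinTable,
    lowess_frac: float = 0.3,
) -> tuple[NormalizationProfile, BinTable]:
    """Per-bin lambda from the normal-cell set, or the GC fallback if D is empty.

    Bins where lambda comes out non-positive (e.g. zero counts in every
    normal cell) are masked with a warning; the returned BinTable carries the
    updated mask.
    """
    R = np.asarray(R)
    unmasked = bin_table.unmasked_idx
    gini = np.array([gini_coefficient(R[i, unmasked]) for i in range(R.shape[0])])

    if normal_cells:
        D = sorted(normal_cells)
        sub = R[D][:, unmasked].astype(float)
        r_bar = sub.mean(axis=1)
        if (r_bar == 0).any():
            raise ValueError("normal cell with zero coverage")
        lam = np.full(bin_table.n_bins, np.nan)
        lam[unmasked] = (sub / r_bar[:, None]).mean(axis=0)
        r_bar_map = {d: float(r) for d, r in zip(D, r_bar)}
        used_fallback = False
    else:
        lam = _fallback_factors(R, bin_table, lowess_frac)
        r_bar_map = None
        used_fallback = True

    bad = np.zeros(bin_table.n_bins, dtype=bool)
    bad[unmasked] = ~(lam[unmasked] > 0)
    out_table = bin_table
    if bad.any():
        warnings.warn(
            f"masking {int(bad.sum())} bins with non-positive normalization factors"
        )
        lam[bad] = np.nan
        out_table = bin_table.with_mask(bin_table.masked | bad)
        if out_table.masked.all():
            raise AllBinsMaskedError("normalization left no usable bins")
    profile = NormalizationProfile(
        factors=lam,
        normal_cells=set(normal_cells),
        gini=gini,
        r_bar=r_bar_map,
        used_fallback=used_fallback,
    )
    return profile, out_table
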