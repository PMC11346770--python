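"""Accuracy metrics: LSSE, ploidy agreement, tolerant breakpoint P/R/F1.

The log-scaled sum-of-squares error (LSSE) of a cell is ``ln(1 + SSE)``
over its unmasked bins, applied either to total copy numbers (total-LSSE)
or to both alleles of the mirrored states (allele-LSSE); a perfect call
scores 0.  The ploidy-adjusted variant rescales the estimated totals by
``true_ploidy / est_ploidy`` and rounds before scoring, removing pure
ploidy-scale errors.  Breakpoint accuracy matches predicted to true
breakpoints within a tolerance of ``l`` bins; because one true breakpoint
may validate only one prediction, the matching is a maximum-cardinality
bipartite matching rather than a greedy sweep.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "EvalReport",
    "adjusted_lsse",
    "allele_lsse",
    "breakpoint_prf",
    "evaluate_calls",
    "lsse",
    "ploidy_agreement",
]


def _validate_pair(true_cn: np.ndarray, est_cn: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.atleast_2d(np.asarray(true_cn, dtype=float))
    e = np.atleast_2d(np.asarray(est_cn, dtype=float))
    if t.shape != e.shape:
        raise ValueError("true and estimated matrices must share a shape")
    if t.shape[1] == 0:
        raise ValueError("no shared bins to evaluate")
    return t, e


def lsse(true_cn: np.ndarray, est_cn: np.ndarray) -> np.ndarray:
    """Per-cell ``ln(1 + sum_j (true_ij - est_ij)^2)``."""
    t, e = _validate_pair(true_cn, est_cn)
    return np.log1p(((t - e) ** 2).sum(axis=1))


def allele_lsse(
    true_minor: np.ndarray,
    true_major: np.ndarray,
    est_minor: np.ndarray,
    est_major: np.ndarray,
) -> np.ndarray:
    """LSSE summed over both alleles of mirrored-matched states.

    States are compared minor-to-minor and major-to-major after sorting, so
    the arbitrary allele labelling ({1,2} vs {2,1}) never contributes error.
    """
    tmin = np.minimum(true_minor, true_major)
    tmaj = np.maximum(true_minor, true_major)
    emin = np.minimum(est_minor, est_major)
    emaj = np.maximum(est_minor, est_major)
    tmin, emin = _validate_pair(tmin, emin)
    tmaj, emaj = _validate_pair(tmaj, emaj)
    sse = ((tmin - emin) ** 2).sum(axis=1) + ((tmaj - emaj) ** 2).sum(axis=1)
    return np.log1p(sse)


def adjusted_lsse(
    true_cn: np.ndarray,
    est_cn: np.ndarray,
    true_ploidy: np.ndarray,
    est_ploidy: np.ndarray,
) -> np.ndarray:
    """Total-LSSE after forcing the estimated ploidy onto the truth.

    Estimated totals are scaled by ``true_ploidy / est_ploidy`` per cell and
    rounded to integers, so an estimate that is a pure ploidy multiple of
    the truth scores 0.
    """
    t, e = _validate_pair(true_cn, est_cn)
    tp = np.atleast_1d(np.asarray(true_ploidy, dtype=float))
    ep = np.atleast_1d(np.asarray(est_ploidy, dtype=float))
    if np.any(ep <= 0):
        raise ValueError("estimated ploidies must be positive")
    scaled = np.rint(e * (tp / ep)[:, None])
    return np.log1p(((t - scaled) ** 2).sum(axis=1))


def breakpoint_prf(
    true_bps, pred_bps, l: int = 1
) -> tuple[float, float, float]:
    """Precision/recall/F1 of predicted breakpoints at tolerance ``l`` bins.

    A true and a predicted breakpoint may be paired iff they are within
    ``l`` bins; pairs are chosen by maximum-cardinality bipartite matching
    so each true breakpoint validates at most one prediction.  Conventions:
    precision is 1 when nothing is predicted, recall is 1 when there is
    nothing to find.
    """
    if l < 0:
        raise ValueError("tolerance l must be >= 0")
    true_bps = sorted(int(b) for b in set(np.asarray(true_bps, dtype=int).ravel()))
    pred_bps = sorted(int(b) for b in set(np.asarray(pred_bps, dtype=int).ravel()))
    precision = 1.0 if not pred_bps else None
    recall = 1.0 if not true_bps else None
    if precision is None or recall is None:
        G = nx.Graph()
        top = [("t", b) for b in true_bps]
        G.add_nodes_from(top, bipartite=0)
        G.add_nodes_from([("p", b) for b in pred_bps], bipartite=1)
        for bt in true_bps:
            for bp in pred_bps:
                if abs(bt - bp) <= l:
                    G.add_edge(("t", bt), ("p", bp))
        matching = nx.bipartite.hopcroft_karp_matching(G, top_nodes=top)
        n_matched = len(matching) // 2
        if precision is None:
            precision = n_matched / len(pred_bps)
        if recall is None:
            recall = n_matched / len(true_bps)
    f1 = (
        0.0
        if precision == 0 or recall == 0
        else 2 * precision * recall / (precision + recall)
    )
    return float(precision), float(recall), float(f1)


def ploidy_agreement(
    true_ploidies: np.ndarray, est_ploidies: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation and RMSE between true and estimated cell ploidies.

    PCC is NaN (with a warning) when either vector has zero variance.
    """
    t = np.asarray(true_ploidies, dtype=float)
    e = np.asarray(est_ploidies, dtype=float)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("ploidy vectors must be 1D and aligned")
    rmse = float(np.sqrt(np.mean((t - e) ** 2)))
    if t.size < 2 or np.std(t) == 0 or np.std(e) == 0:
        warnings.warn("ploidy PCC undefined for constant or singleton vectors")
        return np.nan, rmse
    return float(stats.pearsonr(t, e).statistic), rmse


@dataclass
class EvalReport:
    """Per-cell metrics plus dataset summaries for one simulated run."""

    total_lsse: np.ndarray
    allele_lsse: np.ndarray
    adjusted_lsse: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    ploidy_pcc: float
    ploidy_rmse: float
    tolerance_l: int

    def summary(self) -> dict[str, float]:
        return {
            "total_lsse_mean": float(np.mean(self.total_lsse)),
            "allele_lsse_mean": float(np.mean(self.allele_lsse)),
            "adjusted_lsse_mean": float(np.mean(self.adjusted_lsse)),
            "precision_mean": float(np.mean(self.precision)),
            "recall_mean": float(np.mean(self.recall)),
            "f1_mean": float(np.mean(self.f1)),
            "ploidy_pcc": float(self.ploidy_pcc),
            "ploidy_rmse": float(self.ploidy_rmse),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def evaluate_calls(truth, result, final_breakpoints, bin_table, l: int = 1) -> EvalReport:
    """Score a :class:`~ascna.calling.CallResult` against a simulation truth.

    LSSE metrics are computed over unmasked bins; breakpoint metrics compare
    each cell's final predicted breakpoints (a
    :class:`~ascna.gmm_segmentation.BreakpointSets`) with the truth at
    tolerance ``l``.
    """
    unmasked = bin_table.unmasked_idx
    true_total = truth.cell_total[:, unmasked]
    est_total = (result.c_minor + result.c_major)[:, unmasked]
    tot = lsse(true_total, est_total)
    allele = allele_lsse(
        truth.cell_minor[:, unmasked],
        truth.cell_major[:, unmasked],
        result.c_minor[:, unmasked],
        result.c_major[:, unmasked],
    )
    adj = adjusted_lsse(true_total, est_total, truth.ploidy, result.ploidy)
    n = truth.n_cells
    precision = np.empty(n)
    recall = np.empty(n)
    f1 = np.empty(n)
    for i in range(n):
        precision[i], recall[i], f1[i] = breakpoint_prf(
            truth.breakpoints[i], final_breakpoints[i], l
        )
    pcc, rmse = ploidy_agreement(truth.ploidy, result.ploidy)
    return EvalReport(tot, allele, adj, precision, recall, f1, pcc, rmse, l)
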