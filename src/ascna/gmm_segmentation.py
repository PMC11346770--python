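"""Global segmentation: a 2D Gaussian mixture over (RDR, mBAF).

All unmasked bins of all cells are pooled into one point cloud; bins sharing
a latent allele-specific copy-number state are assumed to follow one Gaussian
component.  EM is run for each component count K in ``[k_min, k_max]`` with
several seeded restarts, the K minimizing BIC is kept, near-duplicate
components are merged post hoc under a weighted distance threshold (mBAF
differences are down-weighted because BAFs are the noisier measurement), and
per-cell candidate breakpoints are read off wherever the component assignment
changes between adjacent bins of the same chromosome.

The EM is implemented here rather than delegated so that the per-iteration
log-likelihood trace (monotone by construction, asserted in tests), the
restart seed stream and the ridge regularization are explicit and
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .data_model import BinTable, CellBinMatrices

__all__ = [
    "BreakpointSets",
    "MixtureModel",
    "candidate_breakpoints",
    "fit_gmm",
    "merge_components",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MixtureModel:
    """A fitted (and possibly merged) Gaussian mixture over (RDR, mBAF).

    ``assignments`` is a cell-by-bin integer matrix of component labels,
    -1 at masked bins.  ``loglik_trace`` is the EM trace of the selected fit.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    loglik: float
    loglik_trace: list[float]
    assignments: np.ndarray
    n_points: int
    bic: float = np.nan

    @property
    def K(self) -> int:
        return len(self.weights)


@dataclass
class BreakpointSets:
    """Per-cell sorted arrays of genome-wide breakpoint indices.

    A breakpoint is the 0-based index of the LEFT bin of an adjacent pair
    whose state differs; both bins lie on the same chromosome.  This one
    convention is used by every module.
    """

    cells: list[np.ndarray] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.cells[i]


# ---------------------------------------------------------------------------
# EM internals
# ---------------------------------------------------------------------------

def _component_logpdf(pts: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of a 2D Gaussian at each point, via the closed-form 2x2 inverse."""
    a, b, c = cov[0, 0], cov[0, 1], cov[1, 1]
    det = a * c - b * b
    dx = pts[:, 0] - mean[0]
    dy = pts[:, 1] - mean[1]
    quad = (c * dx * dx - 2.0 * b * dx * dy + a * dy * dy) / det
    return -_LOG2PI - 0.5 * np.log(det) - 0.5 * quad


def _log_resp(pts, weights, means, covs) -> np.ndarray:
    """(N, K) log of weight_k * N(pt; mu_k, cov_k), vectorized over components."""
    a = covs[:, 0, 0]
    b = covs[:, 0, 1]
    c = covs[:, 1, 1]
    det = a * c - b * b
    dx = pts[:, 0][:, None] - means[:, 0][None, :]
    dy = pts[:, 1][:, None] - means[:, 1][None, :]
    quad = (c * dx * dx - 2.0 * b * dx * dy + a * dy * dy) / det
    return np.log(weights) - _LOG2PI - 0.5 * np.log(det) - 0.5 * quad


def _maximin_init(pts: np.ndarray, K: int) -> np.ndarray:
    """Deterministic k-center (maximin) seeding.

    Each new seed is the point farthest from all previous seeds, so every
    well-separated cluster receives a seed before any capacity is spent on
    near-duplicates -- on (near-)noiseless data this covers even tiny
    clusters that random seeding misses.
    """
    n = pts.shape[0]
    means = np.empty((K, 2))
    means[0] = pts[int(np.argmax(np.sum((pts - pts.mean(axis=0)) ** 2, axis=1)))]
    d2 = np.sum((pts - means[0]) ** 2, axis=1)
    for k in range(1, K):
        means[k] = pts[int(np.argmax(d2))]
        d2 = np.minimum(d2, np.sum((pts - means[k]) ** 2, axis=1))
    return means


def _kpp_init(pts: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding of component means."""
    n = pts.shape[0]
    means = np.empty((K, 2))
    means[0] = pts[rng.integers(n)]
    d2 = np.sum((pts - means[0]) ** 2, axis=1)
    for k in range(1, K):
        tot = d2.sum()
        if tot <= 0:
            means[k] = pts[rng.integers(n)]
        else:
            means[k] = pts[rng.choice(n, p=d2 / tot)]
        d2 = np.minimum(d2, np.sum((pts - means[k]) ** 2, axis=1))
    return means


def _lloyd_refine(pts: np.ndarray, means: np.ndarray, n_iter: int = 10) -> np.ndarray:
    """A few k-means iterations to sharpen seeded means before EM.

    Empty clusters (including duplicates collapsed by the assignment step)
    are re-seeded at the point farthest from its nearest mean, so no
    component capacity is wasted on coincident seeds.
    """
    for _ in range(n_iter):
        d2 = ((pts[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)
        new = means.copy()
        nearest = d2[np.arange(pts.shape[0]), labels]
        for k in range(means.shape[0]):
            sel = labels == k
            if sel.any():
                new[k] = pts[sel].mean(axis=0)
            else:
                far = int(np.argmax(nearest))
                new[k] = pts[far]
                nearest[far] = 0.0
        if np.allclose(new, means):
            break
        means = new
    return means


def _run_em(
    pts: np.ndarray,
    K: int,
    rng: np.random.Generator,
    *,
    kmeans_init: bool,
    max_iter: int,
    tol: float,
    ridge: float,
):
    n = pts.shape[0]
    if kmeans_init:
        means = _lloyd_refine(pts, _maximin_init(pts, K))
    else:
        means = _lloyd_refine(pts, _kpp_init(pts, K, rng), n_iter=5)
    # Initialize weights and covariances from the hard k-means partition (an
    # M-step from hard labels); per-cluster covariances keep tight clusters
    # from being absorbed by broad neighbours in the first E-steps.
    labels = np.argmin(
        ((pts[:, None, :] - means[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    base_cov = np.cov(pts.T) + ridge * np.eye(2)
    covs = np.repeat(base_cov[None], K, axis=0)
    weights = np.full(K, 1.0 / n)
    for k in range(K):
        sel = labels == k
        if sel.any():
            weights[k] = sel.sum() / n
            d = pts[sel] - means[k]
            covs[k] = (d.T @ d) / sel.sum() + ridge * np.eye(2)
    weights = weights / weights.sum()

    x, y = pts[:, 0], pts[:, 1]
    xx, yy, xy = x * x, y * y, x * y
    trace: list[float] = []
    for _ in range(max_iter):
        lr = _log_resp(pts, weights, means, covs)
        top = lr.max(axis=1)
        resp = np.exp(lr - top[:, None])
        norm = resp.sum(axis=1)
        ll = float((top + np.log(norm)).sum())
        trace.append(ll)
        resp /= norm[:, None]
        nk = resp.sum(axis=0)
        # Empty components are left in place with a vanishing weight; they do
        # not harm the likelihood and re-seeding them would break monotonicity.
        safe_nk = np.maximum(nk, 1e-12)
        weights = np.maximum(nk / n, 1e-300)
        weights = weights / weights.sum()
        means = (resp.T @ pts) / safe_nk[:, None]
        # Second moments via three matvecs; cov_k = E[xx^T] - mu mu^T + ridge.
        sxx = resp.T @ xx / safe_nk
        syy = resp.T @ yy / safe_nk
        sxy = resp.T @ xy / safe_nk
        covs = np.empty((K, 2, 2))
        covs[:, 0, 0] = sxx - means[:, 0] ** 2 + ridge
        covs[:, 1, 1] = syy - means[:, 1] ** 2 + ridge
        covs[:, 0, 1] = covs[:, 1, 0] = sxy - means[:, 0] * means[:, 1]
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * (1.0 + abs(trace[-1])):
            break
    # Final E step so loglik/trace reflect the returned parameters.
    lr = _log_resp(pts, weights, means, covs)
    ll = float(logsumexp(lr, axis=1).sum())
    trace.append(max(ll, trace[-1]))
    return weights, means, covs, trace


def fit_gmm(
    features: CellBinMatrices,
    k_min: int = 8,
    k_max: int = 25,
    seed: int = 0,
    *,
    n_restarts: int = 5,
    max_iter: int = 150,
    tol: float = 1e-6,
    ridge: float = 1e-6,
) -> MixtureModel:
    """Fit the pooled (RDR, mBAF) mixture; select K by minimum BIC.

    For each K the best of ``n_restarts`` seeded EM runs (the first with
    k-means++ seeding, the rest with random-point seeding) is kept; BIC is
    ``P ln N - 2 loglik`` with ``P = 6K - 1`` free parameters for full 2x2
    covariances.  Degenerate covariances are kept positive-definite by a
    ridge on the diagonal.
    """
    if k_min < 1 or k_max < k_min:
        raise ValueError("require 1 <= k_min <= k_max")
    pts, cell_idx, bin_idx = features.feature_points()
    n = pts.shape[0]
    if n < k_max:
        raise ValueError("fewer unmasked points than k_max components")

    ss = np.random.SeedSequence(seed)
    best = None
    for K in range(k_min, k_max + 1):
        children = ss.spawn(n_restarts)
        best_fit = None
        for r in range(n_restarts):
            rng = np.random.default_rng(children[r])
            fit = _run_em(
                pts, K, rng,
                kmeans_init=(r == 0), max_iter=max_iter, tol=tol, ridge=ridge,
            )
            if best_fit is None or fit[3][-1] > best_fit[3][-1]:
                best_fit = fit
        weights, means, covs, trace = best_fit
        ll = trace[-1]
        bic = (6 * K - 1) * np.log(n) - 2.0 * ll
        if best is None or bic < best[0]:
            best = (bic, weights, means, covs, ll, trace)

    bic, weights, means, covs, ll, trace = best
    lr = _log_resp(pts, weights, means, covs)
    labels = np.argmax(lr, axis=1)
    assignments = np.full(features.R.shape, -1, dtype=int)
    assignments[cell_idx, bin_idx] = labels
    return MixtureModel(
        weights=weights,
        means=means,
        covariances=covs,
        loglik=ll,
        loglik_trace=trace,
        assignments=assignments,
        n_points=n,
        bic=bic,
    )


# ---------------------------------------------------------------------------
# Post hoc weighted component merging
# ---------------------------------------------------------------------------

def _pair_distance(means: np.ndarray, baf_weight: float) -> np.ndarray:
    d_rdr = means[:, None, 0] - means[None, :, 0]
    d_mbaf = means[:, None, 1] - means[None, :, 1]
    return np.sqrt(d_rdr**2 + baf_weight * d_mbaf**2)


def merge_components(
    model: MixtureModel,
    delta: float = 0.1,
    baf_weight: float = 0.5,
    features: CellBinMatrices | None = None,
) -> MixtureModel:
    """Iteratively merge the closest component pair while it is within ``delta``.

    The merge distance is ``sqrt(d_rdr^2 + baf_weight * d_mbaf^2)`` between
    component means; the merged component takes the weight sum, the
    weight-proportional mean, and the moment-matched mixture covariance.
    With ``delta = 0`` the model is returned unchanged.  When ``features``
    are supplied, bins are re-assigned under the merged model and the
    log-likelihood is recomputed.
    """
    if delta < 0 or not (0 <= baf_weight <= 1):
        raise ValueError("require delta >= 0 and 0 <= baf_weight <= 1")
    weights = model.weights.copy()
    means = model.means.copy()
    covs = model.covariances.copy()
    if delta == 0 or model.K == 1:
        return model

    while len(weights) > 1:
        dist = _pair_distance(means, baf_weight)
        np.fill_diagonal(dist, np.inf)
        a, b = np.unravel_index(np.argmin(dist), dist.shape)
        if not dist[a, b] < delta:
            break
        wa, wb = weights[a], weights[b]
        w = wa + wb
        mu = (wa * means[a] + wb * means[b]) / w
        second = (
            wa * (covs[a] + np.outer(means[a], means[a]))
            + wb * (covs[b] + np.outer(means[b], means[b]))
        ) / w
        cov = second - np.outer(mu, mu)
        keep = [i for i in range(len(weights)) if i not in (a, b)]
        weights = np.append(weights[keep], w)
        means = np.vstack([means[keep], mu])
        covs = np.concatenate([covs[keep], cov[None]], axis=0)

    if features is not None:
        pts, cell_idx, bin_idx = features.feature_points()
        lr = _log_resp(pts, weights, means, covs)
        ll = float(logsumexp(lr, axis=1).sum())
        assignments = np.full(model.assignments.shape, -1, dtype=int)
        assignments[cell_idx, bin_idx] = np.argmax(lr, axis=1)
    else:
        ll = model.loglik
        assignments = model.assignments
    return MixtureModel(
        weights=weights,
        means=means,
        covariances=covs,
        loglik=ll,
        loglik_trace=list(model.loglik_trace),
        assignments=assignments,
        n_points=model.n_points,
        bic=model.bic,
    )


# ---------------------------------------------------------------------------
# Candidate breakpoints
# ---------------------------------------------------------------------------

def candidate_breakpoints(model: MixtureModel, bin_table: BinTable) -> BreakpointSets:
    """Per-cell bin indices where adjacent same-chromosome assignments change.

    Masked bins are skipped: a component change across a masked gap yields a
    single breakpoint at the left unmasked bin.  Chromosome boundaries never
    produce breakpoints.
    """
    q = model.assignments
    masked = bin_table.masked
    cells = []
    for i in range(q.shape[0]):
        bps = []
        for _, lo, hi in bin_table.chromosome_spans():
            u = np.flatnonzero(~masked[lo:hi]) + lo
            if u.size < 2:
                continue
            change = q[i, u[:-1]] != q[i, u[1:]]
            bps.extend(u[:-1][change])
        cells.append(np.array(sorted(bps), dtype=int))
    return BreakpointSets(cells)
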