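"""Joint ploidy selection and allele-specific copy-number calling.

Each segment is assigned to the nearest mixture component in (RDR, mBAF)
space.  Candidate ploidies are anchored on the balanced component -- the
highest-weight component whose mean mBAF is ~0.5, i.e. bins with no allelic
imbalance -- whose mean RDR ``r`` fixes the scale: a cell with ``w``
whole-genome duplications has candidate ploidy ``2^(w+1) / r``.  For each
candidate, every component independently receives the copy state in the
bounded state space that maximizes the Gaussian likelihood of its bins
around the state's expected (RDR, mBAF); the candidate minimizing the
RDR-weighted BIC

    phi(p) * ln(m) * |Omega|  -  2 L(p)

wins, where ``phi`` is the sum of squared distances of ``p * RDR`` from the
nearest integers over the cell's unmasked bins.  Weighting by ``phi`` leans
on the read-depth signal, which is typically cleaner than the BAFs, while
``L`` still rules out states that contradict the observed allelic imbalance.
Ties go to the smaller ploidy (parsimony against spurious WGD calls).

The reported per-cell ploidy is the mean called total copy number over
unmasked bins; the selected candidate scale is kept alongside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    BinTable,
    CellBinMatrices,
    CopyState,
    StateSpace,
    expected_state_mean,
)
from .ensemble import Segment, SegmentSet
from .gmm_segmentation import MixtureModel

__all__ = [
    "CallResult",
    "assign_segments",
    "call_cells",
    "candidate_ploidies",
    "select_ploidy",
    "state_likelihood",
]


@dataclass
class CallResult:
    """Per-cell ploidies and per-bin allele-specific copy states.

    ``c_minor``/``c_major`` are cell-by-bin integer matrices, -1 at masked
    bins.  ``ploidy`` is the mean called total copy number per cell;
    ``candidate_ploidy`` is the selected scale from the WGD candidate set
    and ``wgd`` its whole-genome-duplication count.  ``bic_trace`` maps each
    candidate ploidy to its weighted-BIC score, per cell.
    """

    cell_ids: list[str]
    ploidy: np.ndarray
    candidate_ploidy: np.ndarray
    wgd: np.ndarray
    c_minor: np.ndarray
    c_major: np.ndarray
    component_states: list[dict[int, CopyState]]
    segment_components: list[np.ndarray]
    bic_trace: list[dict[float, float]]
    state_space: StateSpace

    @property
    def total_cn(self) -> np.ndarray:
        tot = self.c_minor + self.c_major
        return np.where(self.c_minor < 0, -1, tot)

    def ploidy_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": self.cell_ids,
                "ploidy": self.ploidy,
                "candidate_ploidy": self.candidate_ploidy,
                "wgd": self.wgd,
            }
        )

    def profile_frame(self, bin_table: BinTable) -> pd.DataFrame:
        """Long-format per-bin states: cell, chrom, start, end, c_minor, c_major."""
        rows = []
        chrom = bin_table.df["chrom"].to_numpy()
        start = bin_table.df["start"].to_numpy()
        end = bin_table.df["end"].to_numpy()
        for i, cid in enumerate(self.cell_ids):
            for j in bin_table.unmasked_idx:
                rows.append(
                    (cid, chrom[j], start[j], end[j],
                     int(self.c_minor[i, j]), int(self.c_major[i, j]))
                )
        return pd.DataFrame(
            rows, columns=["cell", "chrom", "start", "end", "c_minor", "c_major"]
        )


def assign_segments(segments: list[Segment], model: MixtureModel) -> np.ndarray:
    """Nearest component (Euclidean in feature space) per segment.

    Distance ties are broken toward the higher-weight component, then the
    lower component index.
    """
    if not segments:
        return np.empty(0, dtype=int)
    seg_pts = np.array([[s.rdr_mean, s.mbaf_mean] for s in segments])
    d = np.sqrt(((seg_pts[:, None, :] - model.means[None, :, :]) ** 2).sum(axis=2))
    out = np.empty(len(segments), dtype=int)
    for z in range(len(segments)):
        dz = d[z]
        tie = np.flatnonzero(dz <= dz.min() + 1e-12)
        out[z] = tie[np.argmax(model.weights[tie])] if tie.size > 1 else tie[0]
    return out


def candidate_ploidies(
    model: MixtureModel,
    max_wgd: int = 2,
    balanced_tol: float = 0.05,
    density: np.ndarray | None = None,
    component_rdr: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """WGD-aware candidate ploidies ``2^(w+1) / r`` for w = 0..max_wgd.

    ``r`` is the mean RDR of the balanced anchor: the highest-density
    component with ``|mean mBAF - 0.5| <= balanced_tol``.  ``density``
    weights the components when picking the anchor -- per cell, the
    fraction of the cell's bins each component carries, so each cell is
    anchored on its own balanced state; without it the global mixture
    weights are used.  ``component_rdr`` likewise substitutes per-component
    RDR means measured on the cell's own bins (NaN where the cell has
    none), so the anchor scale tracks the cell rather than the pooled
    component.  If no component is balanced within tolerance (or the
    balanced ones carry zero density) the densest component overall is used
    with a warning.  Returns (candidates ascending, anchor RDR).
    """
    if max_wgd < 0:
        raise ValueError("max_wgd must be >= 0")
    dens = model.weights if density is None else np.asarray(density, dtype=float)
    if dens.shape != model.weights.shape:
        raise ValueError("density must have one entry per component")
    balanced = np.flatnonzero(np.abs(model.means[:, 1] - 0.5) <= balanced_tol)
    base_total = 2.0
    if balanced.size == 0 or not np.any(dens[balanced] > 0):
        # No balanced state to anchor on (e.g. a pure triploid genome):
        # anchor on the densest component and take the smallest copy-number
        # total whose allelic ratio is consistent with the anchor's mBAF, so
        # the anchor still pins a known total at w = 0.
        warnings.warn(
            "no populated component with mBAF ~ 0.5; anchoring ploidy on the "
            "densest component"
        )
        anchor = int(np.argmax(dens))
        mbaf = float(model.means[anchor, 1])
        for total in range(1, 9):
            if any(
                abs(mbaf - c / total) <= balanced_tol for c in range(total // 2 + 1)
            ):
                base_total = float(total)
                break
    else:
        anchor = int(balanced[np.argmax(dens[balanced])])
    r = float(model.means[anchor, 0])
    if component_rdr is not None and np.isfinite(component_rdr[anchor]):
        r = float(component_rdr[anchor])
    if r <= 1e-3:
        # Anchor degenerated onto a deletion cluster near RDR 0 (e.g. a cell
        # dominated by homozygous losses); re-anchor on the densest component
        # with appreciable read depth.
        usable = np.flatnonzero(model.means[:, 0] > 0.1)
        if usable.size == 0:
            raise ValueError("no component with positive mean RDR to anchor on")
        anchor = int(usable[np.argmax(dens[usable])])
        base_total = 2.0
        r = float(model.means[anchor, 0])
        if component_rdr is not None and np.isfinite(component_rdr[anchor]):
            r = float(component_rdr[anchor])
    return np.array([base_total * 2.0**w / r for w in range(max_wgd + 1)]), r


def folded_mbaf_mean(ratio, sigma: float):
    """Expected observed mBAF for a true allelic ratio under fold-in noise.

    Mirrored BAF lives in [0, 0.5]; Gaussian BAF noise of scale ``sigma``
    reflects at both boundaries, so balanced bins average
    ``0.5 - sigma*sqrt(2/pi)`` rather than 0.5 and LOH bins average
    ``sigma*sqrt(2/pi)`` rather than 0.  Ignoring this bias makes high-total
    states with ratios just below 0.5 look better than the truly balanced
    state.  Each boundary's shift is the folded-normal mean excess, accurate
    when the boundaries do not interact (sigma << 0.25).
    """
    q = np.asarray(ratio, dtype=float)
    if sigma <= 0:
        return q

    def _excess(m):
        # E|N(m, sigma)| - m for m >= 0
        z = m / sigma
        return (
            sigma * np.sqrt(2.0 / np.pi) * np.exp(-0.5 * z * z)
            - m * 2.0 * stats.norm.sf(z)
        )

    return q + _excess(q) - _excess(0.5 - q)


def _state_log_density(
    pts: np.ndarray,
    cov: np.ndarray,
    states: np.ndarray,
    ploidy: float,
    baf_fold_sd: float = 0.0,
) -> np.ndarray:
    """(S,) summed log density of ``pts`` under each state's expected mean."""
    totals = states.sum(axis=1).astype(float)
    rdr_e = totals / ploidy
    with np.errstate(invalid="ignore", divide="ignore"):
        mbaf_e = np.where(totals > 0, states[:, 0] / np.maximum(totals, 1.0), 0.5)
    mbaf_e = folded_mbaf_mean(mbaf_e, baf_fold_sd)
    a, b, c = cov[0, 0], cov[0, 1], cov[1, 1]
    det = a * c - b * b
    const = -np.log(2.0 * np.pi) - 0.5 * np.log(det)
    dx = pts[None, :, 0] - rdr_e[:, None]
    dy = pts[None, :, 1] - mbaf_e[:, None]
    quad = (c * dx * dx - 2.0 * b * dx * dy + a * dy * dy) / det
    return pts.shape[0] * const - 0.5 * quad.sum(axis=1)


def state_likelihood(
    ploidy: float,
    segments: list[Segment],
    assignment: np.ndarray,
    model: MixtureModel,
    omega: StateSpace,
    features: CellBinMatrices,
    cell: int,
    baf_fold_sd: float = 0.0,
) -> tuple[dict[int, CopyState], float]:
    """Best state per component and the summed log-likelihood at this ploidy.

    For each component with assigned segments, enumerate the state space and
    keep the state maximizing the summed bin log-density under a Gaussian at
    the state's expected (RDR, mBAF) with the component's covariance.  Exact
    ties resolve to the smaller (total, minor) state via enumeration order.
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    states = omega.as_array()
    best: dict[int, CopyState] = {}
    total_ll = 0.0
    for k in np.unique(assignment):
        bins = np.concatenate(
            [segments[z].bins for z in range(len(segments)) if assignment[z] == k]
        )
        pts = np.column_stack([features.rdr[cell, bins], features.mbaf[cell, bins]])
        ll = _state_log_density(
            pts, model.covariances[int(k)], states, ploidy, baf_fold_sd
        )
        s = int(np.argmax(ll))
        best[int(k)] = omega.states[s]
        total_ll += float(ll[s])
    return best, total_ll


def rounding_sse(
    ploidy: float, rdr: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """phi: squared distance of ``ploidy * rdr`` from the nearest integers.

    The ploidy-scoring term of the weighted BIC.  Zero whenever every scaled
    value is integral.  ``weights`` allows scoring segment means weighted by
    their bin counts, which is how ploidy selection uses it: segment means
    average away bin-level noise, so the integer-grid signal survives noise
    levels at which per-bin rounding errors saturate.
    """
    scaled = ploidy * np.asarray(rdr, dtype=float)
    d2 = (scaled - np.rint(scaled)) ** 2
    if weights is not None:
        d2 = d2 * np.asarray(weights, dtype=float)
    return float(d2.sum())


_phi = rounding_sse  # shorthand used in selection


def select_ploidy(
    cell: int,
    candidates: np.ndarray,
    segments: list[Segment],
    assignment: np.ndarray,
    model: MixtureModel,
    omega: StateSpace,
    features: CellBinMatrices,
    baf_fold_sd: float = 0.0,
    refine: bool = True,
) -> tuple[float, dict[int, CopyState], dict[float, float]]:
    """Minimize the RDR-weighted BIC over candidate ploidies for one cell.

    Returns (selected candidate, its per-component states, the score trace).
    Ties favour the smallest candidate.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate ploidy set")
    m = features.bin_table.unmasked_idx.size
    # phi scores the integer-grid fit of segment means; means of very short
    # segments are noise-dominated and only dilute the signal, so they are
    # left out of the score.
    wide = [s for s in segments if s.bins.size >= 3] or list(segments)
    seg_means = np.array([s.rdr_mean for s in wide])
    seg_sizes = np.array([s.bins.size for s in wide], dtype=float)
    trace: dict[float, float] = {}
    best_p, best_states, best_score = None, None, np.inf
    for p in sorted(float(c) for c in candidates):
        states, ll = state_likelihood(
            p, segments, assignment, model, omega, features, cell, baf_fold_sd
        )
        score = _phi(p, seg_means, seg_sizes) * np.log(m) * len(omega) - 2.0 * ll
        trace[p] = score
        if score < best_score - 1e-9:
            best_p, best_states, best_score = p, states, score

    # Local scale refinement within the winning WGD basin: the candidate is
    # derived from the balanced bins only, so its scale carries their
    # sampling error.  Re-fit the scale from all segments against their
    # called totals (weighted least squares through the origin) and
    # re-optimize the states once; iterate to a fixed point.  At zero noise
    # this reproduces the candidate exactly.
    if not refine:
        return best_p, best_states, trace
    all_means = np.array([s.rdr_mean for s in segments])
    all_sizes = np.array([s.bins.size for s in segments], dtype=float)
    states = best_states
    p = best_p
    for _ in range(3):
        totals = np.array(
            [sum(states[int(assignment[z])]) for z in range(len(segments))],
            dtype=float,
        )
        denom = float((all_sizes * all_means**2).sum())
        if denom <= 0:
            break
        p_new = float((all_sizes * totals * all_means).sum()) / denom
        if not (0.8 * best_p <= p_new <= 1.25 * best_p) or abs(p_new - p) < 1e-9:
            break
        new_states, _ = state_likelihood(
            p_new, segments, assignment, model, omega, features, cell, baf_fold_sd
        )
        converged = new_states == states
        p, states = p_new, new_states
        if converged:
            break
    return p, states, trace


def call_cells(
    features: CellBinMatrices,
    segset: SegmentSet,
    model: MixtureModel,
    max_total: int = 10,
    max_wgd: int = 2,
    balanced_tol: float = 0.05,
    known_ploidies: np.ndarray | None = None,
) -> CallResult:
    """Run segment assignment, ploidy selection and state calling per cell.

    ``known_ploidies`` (e.g. from FACS) bypasses candidate generation: each
    cell is called at its given ploidy.
    """
    omega = StateSpace(max_total)
    n, m = features.R.shape
    c_minor = np.full((n, m), -1, dtype=int)
    c_major = np.full((n, m), -1, dtype=int)
    ploidy = np.zeros(n)
    cand_ploidy = np.zeros(n)
    wgd = np.zeros(n, dtype=int)
    comp_states: list[dict[int, CopyState]] = []
    seg_comps: list[np.ndarray] = []
    traces: list[dict[float, float]] = []

    for i in range(n):
        segs = segset[i]
        assignment = assign_segments(segs, model)
        # Share of the cell's unmasked bins per component, and the cell's own
        # bin lists per component.
        density = np.zeros(model.K)
        comp_bins: list[list[np.ndarray]] = [[] for _ in range(model.K)]
        for z, seg in enumerate(segs):
            k = int(assignment[z])
            density[k] += seg.bins.size
            comp_bins[k].append(seg.bins)
        comp_rdr = np.full(model.K, np.nan)
        for k in range(model.K):
            if comp_bins[k]:
                comp_rdr[k] = float(
                    np.median(features.rdr[i, np.concatenate(comp_bins[k])])
                )
        # BAF fold scale from the deficit of the cell's balanced bins below
        # 0.5 (mirrored BAF folds noise downward at 0.5; see
        # folded_mbaf_mean), and a pooled anchor RDR: overlapping components
        # can each hold a slice of the cell's balanced cluster, so the
        # slices are pooled before taking the median (0.1 is well below the
        # RDR spacing of adjacent totals for ploidies under ~8).
        baf_fold_sd = 0.0
        balanced = [
            k
            for k in np.flatnonzero(np.abs(model.means[:, 1] - 0.5) <= balanced_tol)
            if comp_bins[k]
        ]
        if balanced:
            k = max(balanced, key=lambda k: density[k])
            group = [
                g for g in balanced
                if abs(model.means[g, 0] - model.means[k, 0]) <= 0.1
            ]
            gbins = np.concatenate([np.concatenate(comp_bins[g]) for g in group])
            comp_rdr[k] = float(np.median(features.rdr[i, gbins]))
            mb = np.median(features.mbaf[i, gbins])
            # median of |N(0, s)| is 0.6745 s, so the median deficit below
            # 0.5 is a robust scale estimate
            baf_fold_sd = max(0.0, (0.5 - float(mb)) / 0.6745)
        if known_ploidies is not None:
            cell_candidates = np.array([float(known_ploidies[i])])
        else:
            # Per-cell anchoring: each cell is anchored on its own balanced
            # state, with the anchor RDR measured on the cell's bins.
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cell_candidates, _ = candidate_ploidies(
                    model, max_wgd, balanced_tol,
                    density=density, component_rdr=comp_rdr,
                )
        p, states, trace = select_ploidy(
            i, cell_candidates, segs, assignment, model, omega, features,
            baf_fold_sd=baf_fold_sd, refine=known_ploidies is None,
        )
        for z, seg in enumerate(segs):
            st = states[int(assignment[z])]
            c_minor[i, seg.bins] = st.c_minor
            c_major[i, seg.bins] = st.c_major
        unmasked = features.bin_table.unmasked_idx
        ploidy[i] = float((c_minor[i, unmasked] + c_major[i, unmasked]).mean())
        # Snap the record back to the winning candidate (the refined scale
        # may sit between grid points).
        wi = int(np.argmin(np.abs(cell_candidates - p)))
        cand_ploidy[i] = float(cell_candidates[wi])
        wgd[i] = wi if known_ploidies is None else 0
        comp_states.append(states)
        seg_comps.append(assignment)
        traces.append(trace)

    return CallResult(
        cell_ids=list(features.cell_ids),
        ploidy=ploidy,
        candidate_ploidy=cand_ploidy,
        wgd=wgd,
        c_minor=c_minor,
        c_major=c_major,
        component_states=comp_states,
        segment_components=seg_comps,
        bic_trace=traces,
        state_space=omega,
    )
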