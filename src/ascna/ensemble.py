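"""Ensemble breakpoint filtering and segment construction.

The globally fitted mixture yields candidate breakpoints per cell; these are
kept only when shared by at least ``t`` cells (exact index matches), except
that any candidate also found by the cell's own CBS run survives regardless
of its global frequency.  The final set is therefore always a subset of the
candidates, and ``t = 1`` reduces to no filtering.  Segments then tile each
chromosome's unmasked bins between consecutive final breakpoints.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cbs import CbsResult
from .data_model import BinTable, CellBinMatrices
from .gmm_segmentation import BreakpointSets

__all__ = [
    "Segment",
    "SegmentSet",
    "breakpoint_frequency",
    "build_segments",
    "ensemble_breakpoints",
]


def breakpoint_frequency(candidates: BreakpointSets) -> dict[int, int]:
    """Number of cells sharing each genome-wide candidate breakpoint index."""
    counts: Counter[int] = Counter()
    for bps in candidates.cells:
        counts.update(int(b) for b in bps)
    return dict(counts)


def ensemble_breakpoints(
    candidates: BreakpointSets,
    cbs: CbsResult,
    t: int = 5,
) -> BreakpointSets:
    """final_i = {b in candidates_i : freq(b) >= t} | (candidates_i & cbs_i)."""
    if t < 1:
        raise ValueError("t must be >= 1")
    if len(cbs.breakpoints) != candidates.n_cells:
        raise ValueError("candidate and CBS sets cover different cell counts")
    freq = breakpoint_frequency(candidates)
    final = []
    for cand, local in zip(candidates.cells, cbs.breakpoints):
        cand_set = {int(b) for b in cand}
        keep = {b for b in cand_set if freq[b] >= t}
        keep |= cand_set & {int(b) for b in local}
        final.append(np.array(sorted(keep), dtype=int))
    return BreakpointSets(final)


@dataclass
class Segment:
    """A maximal run of bins between breakpoints on one chromosome.

    ``start_bin``/``end_bin`` are genome-wide, half-open; ``bins`` holds the
    unmasked bin indices whose means define ``rdr_mean``/``mbaf_mean``.
    """

    chrom: str
    start_bin: int
    end_bin: int
    bins: np.ndarray
    rdr_mean: float
    mbaf_mean: float


@dataclass
class SegmentSet:
    """Per-cell ordered segment lists tiling the unmasked genome."""

    cells: list[list[Segment]] = field(default_factory=list)

    def __getitem__(self, i: int) -> list[Segment]:
        return self.cells[i]

    def to_frame(self, cell_ids: list[str] | None = None) -> pd.DataFrame:
        rows = []
        for i, segs in enumerate(self.cells):
            cid = cell_ids[i] if cell_ids else i
            for s in segs:
                rows.append(
                    dict(cell=cid, chrom=s.chrom, start_bin=s.start_bin,
                         end_bin=s.end_bin, n_unmasked=len(s.bins),
                         rdr_mean=s.rdr_mean, mbaf_mean=s.mbaf_mean)
                )
        return pd.DataFrame(rows)


def build_segments(
    final: BreakpointSets,
    features: CellBinMatrices,
    bin_table: BinTable,
) -> SegmentSet:
    """Cut each chromosome at the final breakpoints and average per segment.

    A breakpoint ``b`` separates bin ``b`` from the next unmasked bin; the
    right segment starts at ``b + 1`` so interior masked bins fall into the
    right-hand segment (they are excluded from the means either way).
    """
    masked = bin_table.masked
    spans = bin_table.chromosome_spans()
    out = SegmentSet()
    for i in range(features.n_cells):
        bps = set(int(b) for b in final.cells[i])
        segs: list[Segment] = []
        for chrom, lo, hi in spans:
            u = np.flatnonzero(~masked[lo:hi]) + lo
            if u.size == 0:
                continue
            cuts = sorted(b for b in bps if lo <= b < hi)
            bounds = [lo] + [b + 1 for b in cuts] + [hi]
            for s, e in zip(bounds[:-1], bounds[1:]):
                bins = u[(u >= s) & (u < e)]
                if bins.size == 0:
                    continue
                segs.append(
                    Segment(
                        chrom=chrom,
                        start_bin=s,
                        end_bin=e,
                        bins=bins,
                        rdr_mean=float(np.mean(features.rdr[i, bins])),
                        mbaf_mean=float(np.mean(features.mbaf[i, bins])),
                    )
                )
        out.cells.append(segs)
    return out
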