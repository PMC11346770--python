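"""Ground-truthed direct simulation of read-count and BAF matrices.

Emulates single-cell DNA-seq of a clonal tumor population without generating
reads: a random clone tree is grown from a founder genome whose ploidy mode
is configurable (hypodiploid, diploid, triploid, or tetraploid via a founder
whole-genome duplication), CNA events accumulate along branches at a
resolution of whole bins, and cells -- a configurable fraction of them
normal diploid -- draw read counts and BAFs directly from their clone's
allele-specific states.

Read counts are Poisson around ``coverage_scale * total / 2`` with optional
multiplicative Gaussian jitter (``rdr_noise_sd``); BAFs are the true allelic
fraction plus reflected Gaussian noise (``baf_noise_sd``) with random allele
mirroring.  With ``rdr_noise_sd = 0`` counts are the rounded expectation and
with ``baf_noise_sd = 0`` BAFs are exact, so the zero-noise limit is fully
deterministic and the downstream pipeline should recover the truth exactly.

Per-allele copy number is capped (default 4) so simulated states stay inside
the default calling state space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import BinTable
import pandas as pd

__all__ = [
    "SimTruth",
    "load_truth",
    "make_bin_table",
    "simulate_dataset",
    "simulate_matrices",
    "simulate_truth",
    "write_truth",
]

PLOIDY_MODES = ("hypodiploid", "diploid", "triploid", "tetraploid")


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset.

    ``clone_haps`` holds ordered haplotype copy numbers (n_clones, m, 2);
    ``cell_clone`` is -1 for normal cells.  ``cell_minor``/``cell_major``
    are the mirrored per-cell states, ``ploidy`` the per-cell mean total
    copy number over all bins, and ``breakpoints`` the per-cell state-change
    boundaries (0-based left-bin indices, within chromosomes).
    """

    parents: np.ndarray
    clone_haps: np.ndarray
    cell_clone: np.ndarray
    cell_minor: np.ndarray
    cell_major: np.ndarray
    ploidy: np.ndarray
    breakpoints: list[np.ndarray]
    normal_fraction: float
    ploidy_mode: str
    chrom_spans: list[tuple[int, int]]

    @property
    def n_cells(self) -> int:
        return self.cell_clone.size

    @property
    def is_normal(self) -> np.ndarray:
        return self.cell_clone < 0

    @property
    def cell_total(self) -> np.ndarray:
        return self.cell_minor + self.cell_major


def make_bin_table(
    m_bins: int,
    n_chroms: int,
    bin_width: int = 1_000_000,
    gc_range: tuple[float, float] = (0.35, 0.55),
    map_range: tuple[float, float] = (0.92, 1.0),
    seed: int | np.random.SeedSequence = 0,
) -> BinTable:
    """Equal-width bins split as evenly as possible across chromosomes.

    Default GC/mappability ranges keep every bin inside the standard masking
    thresholds; widen them to exercise masking.
    """
    rng = np.random.default_rng(seed)
    sizes = np.full(n_chroms, m_bins // n_chroms)
    sizes[: m_bins % n_chroms] += 1
    rows = []
    for c, size in enumerate(sizes):
        for b in range(size):
            rows.append((f"chr{c + 1}", b * bin_width, (b + 1) * bin_width))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["gc"] = rng.uniform(*gc_range, size=m_bins)
    df["mappability"] = rng.uniform(*map_range, size=m_bins)
    df["masked"] = False
    return BinTable(df)


def _chrom_spans(m_bins: int, n_chroms: int) -> list[tuple[int, int]]:
    sizes = np.full(n_chroms, m_bins // n_chroms)
    sizes[: m_bins % n_chroms] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(n_chroms)]


def _apply_events(
    haps: np.ndarray,
    spans: list[tuple[int, int]],
    n_events: int,
    rng: np.random.Generator,
    event_min_bins: int,
    event_max_bins: int,
    max_allele_copies: int,
) -> None:
    for _ in range(n_events):
        lo, hi = spans[rng.integers(len(spans))]
        size = hi - lo
        length = int(rng.integers(event_min_bins, event_max_bins + 1))
        length = min(length, size)
        start = lo + int(rng.integers(0, size - length + 1))
        hap = int(rng.integers(2))
        mag = 1 if rng.random() < 0.7 else 2
        if rng.random() < 0.5:
            haps[start : start + length, hap] = np.minimum(
                haps[start : start + length, hap] + mag, max_allele_copies
            )
        else:
            haps[start : start + length, hap] = np.maximum(
                haps[start : start + length, hap] - mag, 0
            )


def _profile_breakpoints(
    minor: np.ndarray, major: np.ndarray, spans: list[tuple[int, int]]
) -> np.ndarray:
    bps = []
    for lo, hi in spans:
        change = (minor[lo : hi - 1] != minor[lo + 1 : hi]) | (
            major[lo : hi - 1] != major[lo + 1 : hi]
        )
        bps.extend((np.flatnonzero(change) + lo).tolist())
    return np.array(bps, dtype=int)


def simulate_truth(
    n_cells: int,
    m_bins: int,
    n_chroms: int,
    n_clones: int,
    cna_events_per_clone: int = 4,
    ploidy_mode: str = "diploid",
    normal_fraction: float = 0.25,
    seed: int | np.random.SeedSequence = 0,
    event_min_bins: int = 4,
    event_max_bins: int = 20,
    max_allele_copies: int = 4,
) -> SimTruth:
    """Grow a random clone tree and materialize per-cell true copy states.

    The founder clone receives its ploidy mode (WGD for tetraploid, a
    genome-wide extra copy for triploid, large hemizygous deletions for
    hypodiploid) plus its own CNA events; every descendant clone picks a
    random parent among earlier clones and adds ``cna_events_per_clone``
    events (random segment, random haplotype, gain or loss of 1-2 copies,
    floor at 0, cap at ``max_allele_copies``).  Exactly
    ``round(n_cells * normal_fraction)`` cells are normal diploid; tumor
    cells are spread round-robin over the clones in shuffled order.
    """
    if ploidy_mode not in PLOIDY_MODES:
        raise ValueError(f"ploidy_mode must be one of {PLOIDY_MODES}")
    if not (0 <= normal_fraction < 1):
        raise ValueError("normal_fraction must be in [0, 1)")
    if min(n_cells, m_bins, n_chroms, n_clones) < 1:
        raise ValueError("n_cells, m_bins, n_chroms, n_clones must be positive")
    rng = np.random.default_rng(seed)
    spans = _chrom_spans(m_bins, n_chroms)

    founder = np.ones((m_bins, 2), dtype=int)
    if ploidy_mode == "tetraploid":
        founder *= 2  # whole-genome duplication on the founding branch
    elif ploidy_mode == "triploid":
        founder[:, int(rng.integers(2))] += 1
    elif ploidy_mode == "hypodiploid":
        for lo, hi in spans:
            size = hi - lo
            length = int(round(size * rng.uniform(0.2, 0.5)))
            if length == 0:
                continue
            start = lo + int(rng.integers(0, size - length + 1))
            founder[start : start + length, int(rng.integers(2))] = 0

    parents = np.full(n_clones, -1, dtype=int)
    clone_haps = np.empty((n_clones, m_bins, 2), dtype=int)
    for c in range(n_clones):
        if c == 0:
            haps = founder.copy()
        else:
            parents[c] = int(rng.integers(c))
            haps = clone_haps[parents[c]].copy()
        _apply_events(
            haps, spans, cna_events_per_clone, rng,
            event_min_bins, event_max_bins, max_allele_copies,
        )
        clone_haps[c] = haps

    n_normal = int(round(n_cells * normal_fraction))
    cell_clone = np.empty(n_cells, dtype=int)
    order = rng.permutation(n_cells)
    cell_clone[order[:n_normal]] = -1
    clone_order = rng.permutation(n_clones)
    for r, cell in enumerate(order[n_normal:]):
        cell_clone[cell] = clone_order[r % n_clones]

    normal_hap = np.ones((m_bins, 2), dtype=int)
    cell_minor = np.empty((n_cells, m_bins), dtype=int)
    cell_major = np.empty((n_cells, m_bins), dtype=int)
    breakpoints = []
    for i in range(n_cells):
        haps = normal_hap if cell_clone[i] < 0 else clone_haps[cell_clone[i]]
        cell_minor[i] = haps.min(axis=1)
        cell_major[i] = haps.max(axis=1)
        breakpoints.append(_profile_breakpoints(cell_minor[i], cell_major[i], spans))

    return SimTruth(
        parents=parents,
        clone_haps=clone_haps,
        cell_clone=cell_clone,
        cell_minor=cell_minor,
        cell_major=cell_major,
        ploidy=(cell_minor + cell_major).mean(axis=1),
        breakpoints=breakpoints,
        normal_fraction=normal_fraction,
        ploidy_mode=ploidy_mode,
        chrom_spans=spans,
    )


def simulate_matrices(
    truth: SimTruth,
    coverage_scale: float = 1000.0,
    rdr_noise_sd: float = 0.0,
    baf_noise_sd: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the (read count, BAF) matrices for a given truth.

    ``coverage_scale`` is the expected read count of a copy-neutral bin
    (total 2).  With positive ``rdr_noise_sd`` the Poisson mean carries
    multiplicative Gaussian jitter; at 0 the count is the rounded
    expectation.  BAFs get reflected Gaussian noise and random mirroring.
    """
    if rdr_noise_sd < 0 or baf_noise_sd < 0:
        raise ValueError("noise standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    n, m = truth.cell_minor.shape
    total = truth.cell_total
    # Ordered haplotype fractions give the unmirrored allelic fraction.
    hap1 = np.empty((n, m), dtype=int)
    for i in range(n):
        hap1[i] = (
            np.ones(m, dtype=int)
            if truth.cell_clone[i] < 0
            else truth.clone_haps[truth.cell_clone[i], :, 0]
        )

    mean = coverage_scale * total / 2.0
    if rdr_noise_sd == 0:
        R = np.rint(mean).astype(int)
    else:
        jitter = np.maximum(1.0 + rng.normal(0.0, rdr_noise_sd, size=(n, m)), 0.05)
        R = rng.poisson(mean * jitter)

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, hap1 / np.maximum(total, 1), 0.5)
    baf = frac.astype(float)
    if baf_noise_sd > 0:
        baf = baf + rng.normal(0.0, baf_noise_sd, size=(n, m))
        baf = np.abs(baf)
        baf = 1.0 - np.abs(1.0 - baf)  # reflect into [0, 1]
        baf = np.clip(baf, 0.0, 1.0)
    swap = rng.random((n, m)) < 0.5
    baf = np.where(swap, 1.0 - baf, baf)
    return R.astype(int), baf


def simulate_dataset(
    n_cells: int,
    m_bins: int,
    n_chroms: int,
    n_clones: int,
    cna_events_per_clone: int = 4,
    ploidy_mode: str = "diploid",
    normal_fraction: float = 0.25,
    coverage_scale: float = 1000.0,
    rdr_noise_sd: float = 0.0,
    baf_noise_sd: float = 0.0,
    seed: int = 0,
    **truth_kwargs,
) -> tuple[BinTable, np.ndarray, np.ndarray, SimTruth]:
    """Convenience wrapper: bin table + truth + matrices from one seed."""
    ss = np.random.SeedSequence(seed)
    s_bins, s_truth, s_mat = ss.spawn(3)
    bin_table = make_bin_table(m_bins, n_chroms, seed=s_bins)
    truth = simulate_truth(
        n_cells, m_bins, n_chroms, n_clones,
        cna_events_per_clone=cna_events_per_clone,
        ploidy_mode=ploidy_mode,
        normal_fraction=normal_fraction,
        seed=s_truth,
        **truth_kwargs,
    )
    R, baf = simulate_matrices(
        truth, coverage_scale, rdr_noise_sd, baf_noise_sd, seed=s_mat
    )
    return bin_table, R, baf, truth


# ---------------------------------------------------------------------------
# Truth persistence (TSV, for the evaluate CLI stage)
# ---------------------------------------------------------------------------

def write_truth(outdir, truth: SimTruth, bin_table: BinTable, cell_ids) -> None:
    from pathlib import Path

    from .data_model import write_matrix_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(outdir / "truth_minor.tsv", truth.cell_minor, cell_ids, bin_table)
    write_matrix_tsv(outdir / "truth_major.tsv", truth.cell_major, cell_ids, bin_table)
    pd.DataFrame(
        {"cell": cell_ids, "clone": truth.cell_clone, "ploidy": truth.ploidy}
    ).to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
    rows = [
        (cell_ids[i], int(b))
        for i in range(truth.n_cells)
        for b in truth.breakpoints[i]
    ]
    pd.DataFrame(rows, columns=["cell", "bin"]).to_csv(
        outdir / "truth_breakpoints.tsv", sep="\t", index=False
    )


def load_truth(indir) -> SimTruth:
    """Rebuild a truth object from :func:`write_truth` output.

    The clone tree and haplotype phasing are not stored; only the per-cell
    mirrored states, ploidies, clone labels and breakpoints round-trip.
    """
    from pathlib import Path

    from .data_model import read_matrix_tsv

    indir = Path(indir)
    minor, cell_ids, _ = read_matrix_tsv(indir / "truth_minor.tsv")
    major, _, _ = read_matrix_tsv(indir / "truth_major.tsv")
    cells = pd.read_csv(indir / "truth_cells.tsv", sep="\t")
    bdf = pd.read_csv(indir / "truth_breakpoints.tsv", sep="\t")
    by_cell = {c: g["bin"].to_numpy(dtype=int) for c, g in bdf.groupby("cell")}
    breakpoints = [np.sort(by_cell.get(c, np.empty(0, dtype=int))) for c in cell_ids]
    n_clones = max(1, int(cells["clone"].max()) + 1)
    return SimTruth(
        parents=np.full(n_clones, -1, dtype=int),
        clone_haps=np.zeros((n_clones, minor.shape[1], 2), dtype=int),
        cell_clone=cells["clone"].to_numpy(dtype=int),
        cell_minor=minor.astype(int),
        cell_major=major.astype(int),
        ploidy=cells["ploidy"].to_numpy(dtype=float),
        breakpoints=breakpoints,
        normal_fraction=float(np.mean(cells["clone"].to_numpy() < 0)),
        ploidy_mode="unknown",
        chrom_spans=[],
    )
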