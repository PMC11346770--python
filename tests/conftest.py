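import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ascna.data_model import BinTable, CellBinMatrices


def make_bins(
    n_bins: int,
    chrom: str | list[str] = "chr1",
    gc: float | np.ndarray = 0.45,
    mappability: float | np.ndarray = 0.95,
    width: int = 1_000_000,
) -> BinTable:
    """A simple bin table; ``chrom`` may be a per-bin list for multi-chromosome layouts."""
    chroms = [chrom] * n_bins if isinstance(chrom, str) else list(chrom)
    starts = []
    counters: dict[str, int] = {}
    for c in chroms:
        b = counters.get(c, 0)
        starts.append(b * width)
        counters[c] = b + 1
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": [s + width for s in starts],
            "gc": np.broadcast_to(gc, n_bins).astype(float),
            "mappability": np.broadcast_to(mappability, n_bins).astype(float),
            "masked": False,
        }
    )
    return BinTable(df)


def make_features(
    rdr: np.ndarray, mbaf: np.ndarray, bin_table: BinTable | None = None
) -> CellBinMatrices:
    """Build a CellBinMatrices directly from feature matrices (for unit tests)."""
    rdr = np.atleast_2d(np.asarray(rdr, dtype=float))
    mbaf = np.atleast_2d(np.asarray(mbaf, dtype=float))
    n, m = rdr.shape
    bt = bin_table or make_bins(m)
    masked = bt.masked
    rdr = rdr.copy()
    mbaf = mbaf.copy()
    rdr[:, masked] = np.nan
    mbaf[:, masked] = np.nan
    return CellBinMatrices(
        cell_ids=[f"cell_{i}" for i in range(n)],
        R=np.ones((n, m), dtype=int),
        X=rdr.copy(),
        X_bar=np.ones(n),
        rdr=rdr,
        baf=mbaf.copy(),
        mbaf=mbaf,
        bin_table=bt,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
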