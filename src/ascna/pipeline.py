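"""End-to-end composition of the calling pipeline with per-stage persistence.

Stage order: mask bins -> detect normal cells and normalization factors ->
feature computation -> global mixture segmentation (+ merging) -> per-cell
CBS -> ensemble breakpoints -> segments -> ploidy/state calling -> optional
evaluation against a simulation truth.  The single config seed fans out into
independent per-stage streams (simulation, mixture restarts, CBS
permutations) via a seed sequence, so any stage can be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import CallResult, call_cells
from .cbs import CbsResult, cbs_all_cells
from .config import PipelineConfig, SimulationConfig, save_config_file
from .data_model import BinTable, CellBinMatrices, compute_features, write_matrix_tsv
from .ensemble import SegmentSet, build_segments, ensemble_breakpoints
from .evaluation import EvalReport, evaluate_calls
from .gmm_segmentation import (
    BreakpointSets,
    MixtureModel,
    candidate_breakpoints,
    fit_gmm,
    merge_components,
)
from .preprocessing import (
    NormalizationProfile,
    identify_normal_cells,
    mask_bins,
    normalization_factors,
)
from .synthetic_data import SimTruth, simulate_dataset

logger = logging.getLogger("ascna")

__all__ = ["PipelineResult", "derive_stage_seeds", "run_pipeline", "run_simulated"]


@dataclass
class PipelineResult:
    """Everything the pipeline produced, stage by stage."""

    bin_table: BinTable
    profile: NormalizationProfile
    features: CellBinMatrices
    model: MixtureModel
    merged_model: MixtureModel
    candidates: BreakpointSets
    cbs: CbsResult
    final_breakpoints: BreakpointSets
    segments: SegmentSet
    calls: CallResult
    report: EvalReport | None = None
    truth: SimTruth | None = None


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """Per-stage integer seeds (< 2^31) fanned out from the global seed."""
    state = np.random.SeedSequence(seed).generate_state(3, dtype=np.uint64)
    names = ("simulate", "gmm", "cbs")
    return {n: int(s % (2**31)) for n, s in zip(names, state)}


def _timed(name: str, t0: float) -> None:
    logger.info("stage %-12s %6.1fs", name, time.perf_counter() - t0)


def run_pipeline(
    R: np.ndarray,
    baf: np.ndarray,
    bin_table: BinTable,
    cfg: PipelineConfig | None = None,
    truth: SimTruth | None = None,
    outdir: str | Path | None = None,
    cell_ids: list[str] | None = None,
) -> PipelineResult:
    """Run every stage on in-memory matrices; optionally persist to ``outdir``."""
    cfg = cfg or PipelineConfig()
    seeds = derive_stage_seeds(cfg.seed)

    t0 = time.perf_counter()
    bt = mask_bins(bin_table, cfg.gc_low, cfg.gc_high, cfg.map_min)
    normals = identify_normal_cells(R, cfg.gini_threshold, bt)
    profile, bt = normalization_factors(R, normals, bt, cfg.lowess_frac)
    features = compute_features(R, baf, profile.factors, bt, cell_ids)
    _timed("preprocess", t0)

    t0 = time.perf_counter()
    model = fit_gmm(
        features, cfg.k_min, cfg.k_max, seed=seeds["gmm"], n_restarts=cfg.n_restarts
    )
    merged = merge_components(model, cfg.merge_delta, cfg.baf_weight, features)
    candidates = candidate_breakpoints(merged, bt)
    _timed("gmm", t0)

    t0 = time.perf_counter()
    cbs = cbs_all_cells(
        features, bt, cfg.cbs_alpha, cfg.cbs_n_perm, seeds["cbs"], cfg.cbs_min_width
    )
    _timed("cbs", t0)

    t0 = time.perf_counter()
    final = ensemble_breakpoints(candidates, cbs, cfg.min_cells)
    segments = build_segments(final, features, bt)
    calls = call_cells(
        features, segments, merged, cfg.max_total, cfg.max_wgd, cfg.balanced_tol
    )
    _timed("call", t0)

    report = None
    if truth is not None:
        report = evaluate_calls(truth, calls, final, bt, cfg.tolerance_l)

    result = PipelineResult(
        bin_table=bt,
        profile=profile,
        features=features,
        model=model,
        merged_model=merged,
        candidates=candidates,
        cbs=cbs,
        final_breakpoints=final,
        segments=segments,
        calls=calls,
        report=report,
        truth=truth,
    )
    if outdir is not None:
        persist_result(result, Path(outdir), cfg)
    return result


def run_simulated(
    sim: SimulationConfig | None = None,
    cfg: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Simulate a dataset under ``sim`` and push it through the pipeline."""
    sim = sim or SimulationConfig()
    cfg = cfg or PipelineConfig()
    seeds = derive_stage_seeds(cfg.seed)
    bin_table, R, baf, truth = simulate_dataset(seed=seeds["simulate"], **sim.to_dict())
    return run_pipeline(R, baf, bin_table, cfg, truth=truth, outdir=outdir)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def _breakpoints_frame(
    bps: BreakpointSets, cell_ids: list[str], bin_table: BinTable
) -> pd.DataFrame:
    chrom = bin_table.df["chrom"].to_numpy()
    rows = [
        (cell_ids[i], chrom[b], int(b))
        for i in range(bps.n_cells)
        for b in bps.cells[i]
    ]
    return pd.DataFrame(rows, columns=["cell", "chrom", "bin"])


def model_to_json(model: MixtureModel, path: Path) -> None:
    payload = {
        "weights": model.weights.tolist(),
        "means": model.means.tolist(),
        "covariances": model.covariances.tolist(),
        "loglik": model.loglik,
        "bic": float(model.bic),
        "n_points": model.n_points,
    }
    path.write_text(json.dumps(payload, indent=2))


def persist_result(result: PipelineResult, outdir: Path, cfg: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    ids = result.features.cell_ids
    bt = result.bin_table
    save_config_file(outdir / "config.yaml", cfg)
    bt.to_tsv(outdir / "bins.masked.tsv")
    pd.DataFrame(
        {"bin": bt.bin_ids(), "lambda": result.profile.factors}
    ).to_csv(outdir / "lambda.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "cell": ids,
            "gini": result.profile.gini,
            "is_normal": [i in result.profile.normal_cells for i in range(len(ids))],
        }
    ).to_csv(outdir / "normal_cells.tsv", sep="\t", index=False)
    model_to_json(result.merged_model, outdir / "model.json")
    write_matrix_tsv(outdir / "assignments.tsv", result.merged_model.assignments, ids, bt)
    for name, bps in (
        ("candidate", result.candidates),
        ("cbs", BreakpointSets(result.cbs.breakpoints)),
        ("final", result.final_breakpoints),
    ):
        _breakpoints_frame(bps, ids, bt).to_csv(
            outdir / f"breakpoints_{name}.tsv", sep="\t", index=False
        )
    result.segments.to_frame(ids).to_csv(outdir / "segments.tsv", sep="\t", index=False)
    result.calls.ploidy_frame().to_csv(outdir / "ploidy.tsv", sep="\t", index=False)
    write_matrix_tsv(outdir / "cn_minor.tsv", result.calls.c_minor, ids, bt)
    write_matrix_tsv(outdir / "cn_major.tsv", result.calls.c_major, ids, bt)
    if result.report is not None:
        result.report.to_json(outdir / "report.json")
        pd.DataFrame(
            {
                "cell": ids,
                "total_lsse": result.report.total_lsse,
                "allele_lsse": result.report.allele_lsse,
                "adjusted_lsse": result.report.adjusted_lsse,
                "precision": result.report.precision,
                "recall": result.report.recall,
                "f1": result.report.f1,
            }
        ).to_csv(outdir / "report_per_cell.tsv", sep="\t", index=False)
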