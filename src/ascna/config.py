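"""Pipeline configuration: one flat set of keys, YAML round-trip, strict parsing."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["ConfigError", "PipelineConfig", "SimulationConfig", "load_config_file"]


class ConfigError(ValueError):
    """Raised for unknown or malformed configuration keys."""


@dataclass
class PipelineConfig:
    """Every tunable of the calling pipeline with its default.

    ``seed`` is the single global seed; each stage derives its own stream
    from it so stages are independently reproducible.
    """

    gc_low: float = 0.2
    gc_high: float = 0.8
    map_min: float = 0.9
    gini_threshold: float = 0.02
    lowess_frac: float = 0.3
    k_min: int = 8
    k_max: int = 25
    n_restarts: int = 5
    merge_delta: float = 0.1
    baf_weight: float = 0.5
    cbs_alpha: float = 0.05
    cbs_n_perm: int = 1000
    cbs_min_width: int = 2
    min_cells: int = 5
    max_total: int = 10
    max_wgd: int = 2
    balanced_tol: float = 0.05
    tolerance_l: int = 1
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationConfig:
    """Defaults for the direct simulator (see :mod:`ascna.synthetic_data`)."""

    n_cells: int = 100
    m_bins: int = 200
    n_chroms: int = 2
    n_clones: int = 4
    cna_events_per_clone: int = 4
    ploidy_mode: str = "diploid"
    normal_fraction: float = 0.25
    coverage_scale: float = 1000.0
    rdr_noise_sd: float = 0.0
    baf_noise_sd: float = 0.0
    event_min_bins: int = 4
    event_max_bins: int = 20
    max_allele_copies: int = 4

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config_file(path: str | Path) -> tuple[PipelineConfig, SimulationConfig | None]:
    """Read a YAML config: flat pipeline keys plus an optional ``simulate`` block."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    sim_raw = raw.pop("simulate", None)
    cfg = PipelineConfig.from_dict(raw)
    sim = SimulationConfig.from_dict(sim_raw) if sim_raw is not None else None
    return cfg, sim


def save_config_file(
    path: str | Path,
    cfg: PipelineConfig,
    sim: SimulationConfig | None = None,
) -> None:
    data: dict = cfg.to_dict()
    if sim is not None:
        data["simulate"] = sim.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
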