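"""Run configuration: every pipeline parameter, with the published defaults.

The configuration surfaces each tunable of the quantification pipelines
(segmentation parameters, the calibration multiplier k, the promoter span,
the RPKM cutoff, ...) with the values used in the original analyses as
defaults. Loading rejects unknown keys, and `log_parameters` echoes every
value into the run log so each result is traceable to its settings.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

__all__ = ["RunConfig", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class NeuriteConfig:
    feature_size: int = 10
    smoothing_scale: float = 0.0
    correction_factor: float = 1.3
    k: float = 3.0
    pooled_calibration: bool = False


@dataclass
class Npm1Config:
    dapi_smoothing: float = 0.5
    dapi_correction: float = 2.0
    tubulin_smoothing: float = 1.3488
    tubulin_correction: float = 1.3
    nucleolus_smoothing: float = 1.0
    nucleolus_correction: float = 1.0
    edge_sigma: float = 2.5
    fill_hole_max: int = 50
    nucleus_overlap_min: float = 0.5


@dataclass
class P53Config:
    span: int = 5000
    rpkm_cutoff: float = 0.5
    pseudocount: float = 0.1
    restrict_to_universe: bool = True
    strand_aware: bool = True


@dataclass
class CellCycleConfig:
    edu_quantile: float = 0.995
    min_events: int = 200


@dataclass
class PkConfig:
    dose_nm: float = 1000.0
    hours: float = 120.0
    molar_mass: float = 393.5
    clinical_cmax: float = 45.3
    clinical_auc: float = 3190.0


@dataclass
class RunConfig:
    """Top-level configuration: per-stage parameter blocks + seed + output."""

    neurite: NeuriteConfig = field(default_factory=NeuriteConfig)
    npm1: Npm1Config = field(default_factory=Npm1Config)
    p53: P53Config = field(default_factory=P53Config)
    cellcycle: CellCycleConfig = field(default_factory=CellCycleConfig)
    pk: PkConfig = field(default_factory=PkConfig)
    seed: int = 0
    out_dir: str = "results"

    def log_parameters(self) -> None:
        """Echo every parameter into the run log."""
        for f in fields(self):
            value = getattr(self, f.name)
            if dataclasses.is_dataclass(value):
                for sub in fields(value):
                    logger.info("config %s.%s = %r", f.name, sub.name,
                                getattr(value, sub.name))
            else:
                logger.info("config %s = %r", f.name, value)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_SECTIONS = {
    "neurite": NeuriteConfig,
    "npm1": Npm1Config,
    "p53": P53Config,
    "cellcycle": CellCycleConfig,
    "pk": PkConfig,
}


def _build(cls, data: dict, path: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration key(s) under {path!r}: "
                         f"{sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML configuration, rejecting unknown keys at any level."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError("configuration must be a mapping")
            data = loaded
    if overrides:
        data = {**data, **overrides}
    top_known = set(_SECTIONS) | {"seed", "out_dir"}
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build(cls, dict(data[name]), name)
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "out_dir" in data:
        kwargs["out_dir"] = str(data["out_dir"])
    return RunConfig(**kwargs)
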