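"""Pipeline configuration: readout times, bands, rule thresholds, seeds.

The default configuration reproduces the study's stated constants: 220-s
equilibrium binding readout, 175-s decay readout, per-assay normal bands
(binding 0.9–1.2, DAA 0.9–1.1, CA 0.8–1.2, AP 0.75–1.25) and CES class
bounds (defective < 75, minimal impact > 84).  Configurations round-trip
through YAML and hash stably, so every output table can record the exact
configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .doseresponse import HemolysisRule
from .errors import InvalidParameterError
from .scoring import DEFAULT_BANDS

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class PipelineConfig:
    # SPR readouts (seconds)
    t_eq: float = 220.0
    eq_window: float = 5.0
    t_decay_read: float = 175.0
    # per-assay normal bands (closed intervals)
    bands: dict = field(default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_BANDS.items()})
    # CES classification bounds
    ces_defective_below: float = 75.0
    ces_minimal_above: float = 84.0
    # hemolysis ternary rule thresholds
    hemolysis_negligible_protection: float = 0.90
    hemolysis_negligible_ec50_ratio: float = 0.75
    hemolysis_severe_protection: float = 0.50
    hemolysis_enhanced_lysis_tol: float = 0.05
    # AP EC50 interpolation: level against the control-defined span?
    ap_shared_plateau: bool = True
    # correlation statistic over the five continuous components
    correlation_method: str = "spearman"
    # master seed for any simulation stage run through the pipeline
    seed: int = 0
    # strictness of the CES computation when components are missing
    partial_ces: bool = False

    def __post_init__(self):
        if self.t_eq <= 0 or self.t_decay_read <= 0 or self.eq_window < 0:
            raise InvalidParameterError("readout times must be > 0 and window >= 0")
        for assay, (lo, hi) in dict(self.bands).items():
            if not lo < hi:
                raise InvalidParameterError(f"band for '{assay}' must have lower < upper")
        if not self.ces_defective_below < self.ces_minimal_above:
            raise InvalidParameterError("defective bound must lie below the minimal bound")

    @property
    def hemolysis_rule(self) -> HemolysisRule:
        return HemolysisRule(
            negligible_protection=self.hemolysis_negligible_protection,
            negligible_ec50_ratio=self.hemolysis_negligible_ec50_ratio,
            severe_protection=self.hemolysis_severe_protection,
            enhanced_lysis_tol=self.hemolysis_enhanced_lysis_tol,
        )

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def _to_plain(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["bands"] = {k: list(v) for k, v in d["bands"].items()}
    return d


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=True)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "bands" in raw:
        raw["bands"] = {k: tuple(v) for k, v in raw["bands"].items()}
    return PipelineConfig(**raw)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the full configuration, recorded in every output."""
    blob = json.dumps(_to_plain(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
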