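"""YAML run-configuration schema and validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Raised when a run configuration fails schema validation."""


@dataclass
class RunConfig:
    counts: str = ""
    counts_format: str = "delimited"
    coordinates: str = ""
    composition: str = ""
    composition_mode: str = "proportions"
    reference: str = ""
    bandwidths: Any = "auto"
    include_self: bool = True
    min_type_proportion: float = 0.05
    cap_percentile: float = 99.5
    min_total_count: float = 100.0
    min_pair_obs: int = 30
    expr_percentile: float = 80.0
    max_iter: int = 25
    tol: float = 1e-8
    refit_nb: bool = False
    alpha: float = 0.05
    seed: int = 0
    units_per_pixel: float = 1.0
    lr_prior: str = ""
    lr_pairs: str = ""
    lr_index_type: str = ""
    lr_niche_type: str = ""
    lr_n_targets: int = 50
    lr_max_candidates: int = 50
    lr_alpha: float = 0.05
    log_level: str = "INFO"
    extras: dict = field(default_factory=dict)

    def validate(self, require_inputs: bool = True) -> None:
        errors = []
        if require_inputs:
            for name in ("counts", "coordinates", "composition", "reference"):
                value = getattr(self, name)
                if not value:
                    errors.append(f"inputs.{name}: required")
                elif not Path(value).exists():
                    errors.append(f"inputs.{name}: file not found ({value})")
        if self.counts_format not in ("delimited", "mtx_triplet"):
            errors.append(f"inputs.counts_format: unknown format {self.counts_format!r}")
        if self.composition_mode not in ("proportions", "labels"):
            errors.append(f"inputs.composition_mode: must be proportions or labels")
        if self.bandwidths != "auto":
            try:
                bws = [float(b) for b in self.bandwidths]
            except (TypeError, ValueError):
                errors.append("kernel.bandwidths: must be 'auto' or a list of numbers")
            else:
                if any(b <= 0 for b in bws):
                    errors.append("kernel.bandwidths: bandwidths must be positive")
        if not 0 < self.alpha < 1:
            errors.append(f"alpha: must lie in (0, 1), got {self.alpha}")
        if not 0 <= self.min_type_proportion < 1:
            errors.append("filters.min_type_proportion: must lie in [0, 1)")
        if not 0 < self.cap_percentile <= 100:
            errors.append("filters.cap_percentile: must lie in (0, 100]")
        if errors:
            raise ConfigError("; ".join(errors))

    def to_yaml(self) -> str:
        flat = {k: v for k, v in self.__dict__.items() if k != "extras"}
        return yaml.safe_dump(flat, sort_keys=True)


_SECTION_KEYS = {
    "inputs": {
        "counts": "counts",
        "counts_format": "counts_format",
        "coordinates": "coordinates",
        "composition": "composition",
        "composition_mode": "composition_mode",
        "reference": "reference",
    },
    "kernel": {"bandwidths": "bandwidths", "include_self": "include_self"},
    "filters": {
        "min_type_proportion": "min_type_proportion",
        "cap_percentile": "cap_percentile",
        "min_total_count": "min_total_count",
        "min_pair_obs": "min_pair_obs",
        "expr_percentile": "expr_percentile",
    },
    "fit": {"max_iter": "max_iter", "tol": "tol", "refit_nb": "refit_nb"},
    "lr": {
        "prior": "lr_prior",
        "pairs": "lr_pairs",
        "index_type": "lr_index_type",
        "niche_type": "lr_niche_type",
        "n_targets": "lr_n_targets",
        "max_candidates": "lr_max_candidates",
        "alpha": "lr_alpha",
    },
}
_TOP_KEYS = {"alpha", "seed", "units_per_pixel", "log_level"}


def load_config(path: str | Path, require_inputs: bool = True) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    cfg = RunConfig()
    for section, mapping in _SECTION_KEYS.items():
        block = raw.get(section, {}) or {}
        if not isinstance(block, dict):
            raise ConfigError(f"{section}: must be a mapping")
        for key, attr in mapping.items():
            if key in block:
                setattr(cfg, attr, block[key])
        unknown = set(block) - set(mapping)
        if unknown:
            raise ConfigError(f"{section}: unknown key(s) {sorted(unknown)}")
    for key in _TOP_KEYS:
        if key in raw:
            setattr(cfg, key, raw[key])
    unknown = set(raw) - set(_SECTION_KEYS) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    cfg.validate(require_inputs=require_inputs)
    return cfg
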