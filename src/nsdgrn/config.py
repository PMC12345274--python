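"""Pipeline configuration.

A single :class:`PipelineConfig` carries every threshold the pipeline
applies, mirrored one-to-one by the YAML config file, so a run is fully
described by (input files, config, seed). Defaults reproduce the standard
analysis: two-fold / P<0.05 DEG calling, a 1.5 kb promoter window anchored
at the translation start, a STRING confidence floor of 150, and the
primary-metabolite gates (intensity > 1e6, |log2FC| > 1, +/-0.001 Da,
+/-1.5 retention-time units).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml

from .models import NsdgrnError

_VALID_PEAK_MODES = ("interval", "summit")


@dataclass
class PipelineConfig:
    # differential expression
    deg_p_threshold: float = 0.05
    deg_fold_threshold: float = 2.0  # ratio scale; equivalent to |log2FC| > 1
    deg_pseudocount: float = 0.01  # added to both raw condition means
    deg_test_on_normalized: bool = True
    deg_fdr: bool = False  # Benjamini-Hochberg, off by default (raw P < alpha)

    # promoter / ChIP
    promoter_window: int = 1500
    peak_mode: str = "interval"  # or "summit"

    # network
    ppi_min_confidence: float = 150.0
    core_size_target: int = 30
    keep_isolated_associated: bool = True

    # metabolomics
    metab_p_threshold: float = 0.05
    metab_log2fc_threshold: float = 1.0
    metab_min_intensity: float = 1e6
    mass_tolerance: float = 0.001  # Da, inclusive
    rt_tolerance: float = 1.5  # retention-time units, inclusive
    mass_adduct_shift: float = 0.0  # applied to feature m/z before matching

    # motif
    nre_motif: str = "GATCT"

    rng_seed: int = 7

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = {
            "deg_p_threshold": self.deg_p_threshold,
            "deg_fold_threshold": self.deg_fold_threshold,
            "promoter_window": self.promoter_window,
            "ppi_min_confidence": self.ppi_min_confidence,
            "metab_p_threshold": self.metab_p_threshold,
            "metab_log2fc_threshold": self.metab_log2fc_threshold,
            "metab_min_intensity": self.metab_min_intensity,
            "mass_tolerance": self.mass_tolerance,
            "rt_tolerance": self.rt_tolerance,
            "core_size_target": self.core_size_target,
        }
        for name, value in positive.items():
            if not value > 0:
                raise NsdgrnError(f"config: {name} must be strictly positive, got {value}")
        if not self.nre_motif or set(self.nre_motif.upper()) - set("ACGT"):
            raise NsdgrnError(
                f"config: nre_motif must be a non-empty ACGT string, got {self.nre_motif!r}"
            )
        if self.peak_mode not in _VALID_PEAK_MODES:
            raise NsdgrnError(
                f"config: peak_mode must be one of {_VALID_PEAK_MODES}, got {self.peak_mode!r}"
            )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise NsdgrnError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def replace(self, **overrides: Any) -> "PipelineConfig":
        """Return a copy with the given fields overridden (CLI flags win)."""
        clean = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **clean)
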