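"""Hierarchical plain-text (YAML) run configuration.

A config file can override any phantom, noise, fragmentation or analysis
parameter; unknown keys are rejected by name.  Command-line flags take
precedence over the file, the file over built-in defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Any, Dict, Optional

import yaml

from .panel import PanelEntry, default_panel, read_panel
from .synthetic import FragmentationModel, NoiseModel, PhantomConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the input paths."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    fragmentation: FragmentationModel = field(default_factory=FragmentationModel)
    seed: Optional[int] = None
    tol_ppm: float = 5.0
    lfc_threshold: float = 0.6
    alpha: float = 0.05
    z_scheme: str = "replicate"
    roi_side: int = 3
    rois_per_region: int = 10
    group_a: str = "diseased"
    group_b: str = "healthy"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")


def _build(cls, raw: Dict[str, Any], section: str):
    allowed = {f.name for f in fields(cls)}
    bad = set(raw) - allowed
    if bad:
        raise ValueError(
            f"unknown config key(s) in section {section!r}: {sorted(bad)}"
        )
    return cls(**raw)


def load_config(path: Optional[str] = None,
                overrides: Optional[Dict[str, Any]] = None) -> RunConfig:
    """Build a :class:`RunConfig` from defaults, a YAML file and overrides.

    Top-level sections ``phantom``, ``noise``, ``fragmentation`` map onto
    the corresponding dataclasses; remaining top-level keys map onto
    :class:`RunConfig` fields.  ``phantom.panel_file`` loads a panel table
    in place of the built-in panel.  An unknown key anywhere is an error
    naming the key.
    """
    raw: Dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must be a mapping")
    if overrides:
        for k, v in overrides.items():
            if v is not None:
                raw[k] = v

    ph_raw = dict(raw.pop("phantom", {}) or {})
    panel_file = ph_raw.pop("panel_file", None)
    if "grid_shape" in ph_raw:
        ph_raw["grid_shape"] = tuple(ph_raw["grid_shape"])
    if "scan_range" in ph_raw:
        ph_raw["scan_range"] = tuple(ph_raw["scan_range"])
    phantom = _build(PhantomConfig, ph_raw, "phantom")
    if panel_file:
        phantom.panel = read_panel(panel_file)
    noise = _build(NoiseModel, dict(raw.pop("noise", {}) or {}), "noise")
    frag = _build(FragmentationModel,
                  dict(raw.pop("fragmentation", {}) or {}), "fragmentation")
    run = _build(RunConfig, {"phantom": phantom, "noise": noise,
                             "fragmentation": frag, **raw}, "top level")
    return run
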