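"""Run configuration: validated parameter sets shared by library and CLI.

Defaults encode the pipeline's standard operating point: components
covering the top 50% of total variance enter stepwise selection, the
bootstrap runs 1000 replicates at a one-sided 90% percentile CI, and
the brain mask keeps voxels above 0.35 of each subject's maximum.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Any

import yaml

from .exceptions import ConfigurationError


def _check_unit_interval(name: str, value: float) -> None:
    if not (0.0 < value < 1.0):
        raise ConfigurationError(f"{name} must lie in (0, 1), got {value}")


@dataclass
class DeriveConfig:
    """Parameters of pattern derivation.

    mask_threshold
        Per-subject relative intensity threshold defining the brain
        mask (fraction of each subject's maximum).
    cum_var_threshold
        Cumulative variance fraction selecting candidate components.
    gmp_group
        Group over which the group mean profile is averaged; ``None``
        pools controls and patients.
    mode
        ``"stepwise"`` (AIC-guided combination) or ``"pc1"``.
    """

    mask_threshold: float = 0.35
    cum_var_threshold: float = 0.5
    gmp_group: str | None = None
    mode: str = "stepwise"
    seed: int | None = None

    def __post_init__(self) -> None:
        _check_unit_interval("mask_threshold", self.mask_threshold)
        if not (0.0 < self.cum_var_threshold <= 1.0):
            raise ConfigurationError(
                f"cum_var_threshold must lie in (0, 1], got {self.cum_var_threshold}"
            )
        if self.mode not in ("stepwise", "pc1"):
            raise ConfigurationError(f"mode must be 'stepwise' or 'pc1', got {self.mode!r}")


@dataclass
class BootstrapConfig:
    n_replicates: int = 1000
    ci_level: float = 0.90

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if not (0.5 < self.ci_level < 1.0):
            raise ConfigurationError("ci_level must lie in (0.5, 1)")


def dataclass_from_mapping(cls: type, mapping: dict[str, Any], context: str = "config"):
    """Build a config dataclass from a dict, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigurationError(f"unknown {context} fields: {sorted(unknown)}")
    return cls(**mapping)


def load_yaml_config(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        loaded = yaml.safe_load(fh) or {}
    if not isinstance(loaded, dict):
        raise ConfigurationError(f"config file {path} must hold a mapping")
    return loaded


def config_echo(cfg) -> dict[str, Any]:
    return asdict(cfg)
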