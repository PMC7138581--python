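"""Run configuration: sparsity grid, null/permutation counts, filtering band."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .types import SparsityGrid

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class AnalysisConfig:
    """All tunables of an analysis run.

    Defaults follow the reference protocol: sparsity 0.05-0.40 step 0.01,
    100 degree-preserving null networks, 100 permutations, FDR at 1%,
    10 discarded volumes, 0.01-0.08 Hz band at TR 2 s.
    """

    sparsity_start: float = 0.05
    sparsity_stop: float = 0.40
    sparsity_step: float = 0.01
    n_null_networks: int = 100
    n_rewire_swaps_per_edge: int = 10
    n_permutations: int = 100
    fdr_q: float = 0.01
    alpha: float = 0.05
    discard_volumes: int = 10
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    tr_seconds: float = 2.0
    seed: int = 0
    # documented alternatives behind switches
    use_welch: bool = False
    fdr_pool_metrics: bool = False
    chi2_continuity: bool = False
    strength_stat: str = "sum"  # or "mean"
    hub_scope: str = "group"  # or "subject"

    def __post_init__(self):
        if not (0 < self.sparsity_start <= self.sparsity_stop < 1):
            raise ConfigError(
                "need 0 < sparsity_start <= sparsity_stop < 1, got "
                f"[{self.sparsity_start}, {self.sparsity_stop}]"
            )
        if self.sparsity_step <= 0:
            raise ConfigError(f"sparsity_step must be > 0, got {self.sparsity_step}")
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if not (self.band_low_hz < self.band_high_hz < nyquist):
            raise ConfigError(
                f"need band_low_hz < band_high_hz < {nyquist} Hz (Nyquist), got "
                f"({self.band_low_hz}, {self.band_high_hz})"
            )
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.n_null_networks < 1:
            raise ConfigError("n_null_networks must be >= 1")
        if not (0 < self.fdr_q < 1):
            raise ConfigError(f"fdr_q must be in (0, 1), got {self.fdr_q}")
        if self.discard_volumes < 0:
            raise ConfigError("discard_volumes must be >= 0")
        if self.strength_stat not in ("sum", "mean"):
            raise ConfigError("strength_stat must be 'sum' or 'mean'")
        if self.hub_scope not in ("group", "subject"):
            raise ConfigError("hub_scope must be 'group' or 'subject'")

    def sparsity_grid(self) -> SparsityGrid:
        """Grid from start to stop inclusive in steps of sparsity_step."""
        n_steps = int(np.floor(
            (self.sparsity_stop - self.sparsity_start) / self.sparsity_step + 1e-9
        ))
        levels = self.sparsity_start + self.sparsity_step * np.arange(n_steps + 1)
        return SparsityGrid(tuple(np.round(levels, 10)))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path) -> AnalysisConfig:
    """Read an AnalysisConfig from YAML or JSON (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must hold a mapping")
    return AnalysisConfig.from_dict(data)
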