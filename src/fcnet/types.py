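"""Core value types shared across pipeline stages.

Region order in a :class:`TimeSeriesPanel` is the canonical node order
for every downstream matrix and graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesPanel",
    "ConnectivityMatrix",
    "BinaryGraph",
    "SparsityGrid",
    "MetricProfile",
    "RichClubPartition",
    "SubjectManifest",
    "default_region_labels",
]

METRIC_NAMES = ("Eglo", "Eloc", "Cp", "Lp", "gamma", "lambda", "sigma")


def default_region_labels(n: int) -> list[str]:
    """Synthesized labels R001..RNNN used when a file carries no header."""
    width = max(3, len(str(n)))
    return [f"R{i + 1:0{width}d}" for i in range(n)]


@dataclass
class TimeSeriesPanel:
    """One subject's regions x time matrix of BOLD-like signal."""

    subject_id: str
    region_labels: list[str]
    values: np.ndarray  # shape (n_regions, n_volumes)
    tr_seconds: float = 2.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (regions x time)")
        if len(self.region_labels) != self.values.shape[0]:
            raise ValueError("region_labels length must match row count")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix with zero diagonal."""

    subject_id: str
    region_labels: list[str]
    r: np.ndarray  # shape (n, n), entries in [-1, 1], diagonal 0

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]


@dataclass
class BinaryGraph:
    """Undirected unweighted graph at one sparsity level."""

    region_labels: list[str]
    adjacency: np.ndarray  # shape (n, n), {0, 1}, symmetric, zero diagonal
    sparsity: float

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class SparsityGrid:
    """Strictly increasing sparsity levels for the threshold sweep."""

    levels: tuple

    def __post_init__(self):
        levels = tuple(float(s) for s in self.levels)
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("sparsity levels must be strictly increasing")
        self.levels = levels

    def __len__(self) -> int:
        return len(self.levels)

    def __iter__(self):
        return iter(self.levels)

    @classmethod
    def default(cls) -> "SparsityGrid":
        return cls(tuple(np.round(np.arange(5, 41) * 0.01, 10)))


@dataclass
class MetricProfile:
    """Per-sparsity network metrics for one subject.

    ``records`` holds one row per sparsity level with columns
    Eglo/Eloc/Cp/Lp/gamma/lambda/sigma plus a ``connected`` flag;
    ``degrees`` holds the nodal degree vector per level.
    """

    subject_id: str
    records: pd.DataFrame
    degrees: np.ndarray  # shape (n_levels, n_regions)
    region_labels: list[str] = field(default_factory=list)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format (subject, sparsity, metric, value) table."""
        rows = self.records.melt(
            id_vars=["sparsity"], value_vars=list(METRIC_NAMES),
            var_name="metric", value_name="value",
        )
        rows.insert(0, "subject_id", self.subject_id)
        return rows


@dataclass
class RichClubPartition:
    """Hub set and edge-class bookkeeping for one group."""

    group: str
    hub_regions: set
    hub_rule_threshold: float
    mean_degree_centrality: pd.Series  # indexed by region label
    strengths: Optional[pd.DataFrame] = None  # per-subject class strengths


@dataclass
class SubjectManifest:
    """One subject's row in the study manifest."""

    subject_id: str
    group: str
    age: Optional[float] = None
    sex: Optional[str] = None
    education: Optional[float] = None
    duration: Optional[float] = None
    acth: Optional[float] = None
    ufc: Optional[float] = None
    cortisol_0am: Optional[float] = None
    cortisol_4pm: Optional[float] = None
    cortisol_8am: Optional[float] = None
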