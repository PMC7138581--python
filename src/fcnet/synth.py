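"""Synthetic cohort generator.

Produces region x time panels from a modular latent covariance with
planted hub regions and group-level effects (weaker within-module
clustering and weaker hub-incident connectivity in the patient-like
group), plus clinical covariates with realistic moments.  Volumes are
i.i.d. multivariate-normal draws: the downstream analysis uses only
zero-lag Pearson correlation, so temporal autocorrelation is irrelevant
to every statistic except band-pass filtering, which is exercised
separately with sinusoid fixtures.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import substream
from .errors import DimensionError, NumericError, ParameterError, SpecError
from .types import BinaryGraph, TimeSeriesPanel, default_region_labels

__all__ = [
    "GroundTruthSpec",
    "make_group_covariance",
    "simulate_subject",
    "simulate_cohort",
    "reference_graph",
]

# clinical covariate moments for the synthetic cohort (mean, sd)
PATIENT_MOMENTS = {
    "age": (41.00, 11.23),
    "education": (13.32, 2.14),
    "duration": (4.76, 3.58),
    "acth": (86.10, 58.28),
    "ufc": (659.87, 357.29),
    "cortisol_0am": (17.03, 9.13),
    "cortisol_4pm": (19.66, 9.09),
    "cortisol_8am": (2.43, 13.08),
}
CONTROL_MOMENTS = {
    "age": (47.05, 13.51),
    "education": (13.09, 3.64),
}
# fraction of men per group, matching the reference demographics (4/19, 7/22)
P_MALE = {"patient": 4 / 19, "control": 7 / 22}

DEFAULT_GROUP_EFFECTS = {
    "control": {"clustering_factor": 1.0, "hub_factor": 1.0},
    "patient": {"clustering_factor": 0.7, "hub_factor": 0.6},
}


def _default_modules(n_regions: int, n_modules: int = 6) -> np.ndarray:
    return (np.arange(n_regions) * n_modules) // n_regions


def _default_hubs(modules: np.ndarray, n_hubs: int = 12) -> tuple:
    """Spread hubs evenly over modules: the first regions of each module."""
    module_ids = np.unique(modules)
    hubs: list[int] = []
    per_module = int(np.ceil(n_hubs / module_ids.size))
    for mid in module_ids:
        members = np.flatnonzero(modules == mid)
        hubs.extend(members[:per_module].tolist())
        if len(hubs) >= n_hubs:
            break
    return tuple(sorted(hubs[:n_hubs]))


@dataclass
class GroundTruthSpec:
    """Ground truth for the synthetic cohort."""

    n_regions: int = 90
    n_volumes: int = 210
    module_assignment: Optional[np.ndarray] = None
    hub_regions: Optional[tuple] = None
    r_within: float = 0.45
    r_between: float = 0.10
    r_hub_boost: float = 0.20
    noise_sd: float = 1.0
    tr_seconds: float = 2.0
    group_effects: dict = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_GROUP_EFFECTS.items()}
    )

    def __post_init__(self):
        if self.n_regions < 2:
            raise SpecError("n_regions must be >= 2")
        if self.module_assignment is None:
            self.module_assignment = _default_modules(self.n_regions)
        self.module_assignment = np.asarray(self.module_assignment, dtype=int)
        if self.module_assignment.shape != (self.n_regions,):
            raise SpecError("module_assignment must have one entry per region")
        if self.hub_regions is None:
            self.hub_regions = _default_hubs(self.module_assignment)
        self.hub_regions = tuple(sorted(int(h) for h in self.hub_regions))
        if self.hub_regions and not (
            0 <= min(self.hub_regions) and max(self.hub_regions) < self.n_regions
        ):
            raise SpecError("hub_regions must be valid region indices")

    @classmethod
    def from_dict(cls, data: dict) -> "GroundTruthSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SpecError(f"unknown spec keys: {sorted(unknown)}")
        return cls(**data)


def make_group_covariance(spec: GroundTruthSpec, group: str) -> np.ndarray:
    """Target correlation matrix for one group, repaired to PSD.

    Pairwise targets: r_within / r_between by module co-membership, plus
    r_hub_boost * hub_factor when either region is a hub; the group's
    clustering_factor then scales within-module non-hub entries.  The
    result is repaired to positive semidefinite by clipping negative
    eigenvalues at zero and renormalizing the diagonal to exactly 1.
    """
    if group not in spec.group_effects:
        raise SpecError(f"unknown group {group!r}; spec defines {sorted(spec.group_effects)}")
    effects = spec.group_effects[group]
    clustering_factor = float(effects["clustering_factor"])
    hub_factor = float(effects["hub_factor"])

    modules = spec.module_assignment
    same_module = modules[:, None] == modules[None, :]
    is_hub = np.zeros(spec.n_regions, dtype=bool)
    is_hub[list(spec.hub_regions)] = True
    hub_incident = is_hub[:, None] | is_hub[None, :]

    target = np.where(same_module, spec.r_within, spec.r_between).astype(float)
    target = target + hub_incident * (spec.r_hub_boost * hub_factor)
    within_nonhub = same_module & ~hub_incident
    target[within_nonhub] *= clustering_factor
    np.fill_diagonal(target, 1.0)

    off = target[~np.eye(spec.n_regions, dtype=bool)]
    if off.size and (off.min() <= -1 or off.max() >= 1):
        raise SpecError(
            f"target correlations outside (-1, 1): range "
            f"[{off.min():.3g}, {off.max():.3g}]"
        )

    eigvals, eigvecs = np.linalg.eigh(target)
    cov = (eigvecs * np.clip(eigvals, 0.0, None)) @ eigvecs.T
    d = np.sqrt(np.diag(cov))
    cov = cov / np.outer(d, d)
    cov = (cov + cov.T) / 2.0
    np.fill_diagonal(cov, 1.0)
    return cov


def simulate_subject(
    cov: np.ndarray,
    n_volumes: int,
    noise_sd: float,
    seed: int,
    subject_id: str = "sim",
    tr_seconds: float = 2.0,
    region_labels: Optional[list] = None,
) -> TimeSeriesPanel:
    """Draw i.i.d. volumes from N(0, cov) plus independent observation noise."""
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    eigvals, eigvecs = np.linalg.eigh((cov + cov.T) / 2.0)
    if eigvals.min() < -1e-8:
        raise NumericError(
            f"covariance is not PSD (min eigenvalue {eigvals.min():.3g})"
        )
    sqrt_cov = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
    rng = substream(seed, "subject", subject_id)
    latent = sqrt_cov @ rng.standard_normal((n, n_volumes))
    values = latent + noise_sd * rng.standard_normal((n, n_volumes))
    if region_labels is None:
        region_labels = default_region_labels(n)
    return TimeSeriesPanel(
        subject_id=subject_id, region_labels=region_labels,
        values=values, tr_seconds=tr_seconds,
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal(mean, sd) with negative draws clipped to 0.

    Clipping rather than rejection keeps the sample mean within a few
    percent of the nominal mean even when the mass below zero is
    non-negligible.
    """
    return np.clip(rng.normal(mean, sd, size), 0.0, None)


def simulate_cohort(
    spec: GroundTruthSpec, n_per_group, seed: int,
) -> tuple[list[TimeSeriesPanel], pd.DataFrame]:
    """Panels and manifest for a two-group cohort.

    ``n_per_group`` is either one count shared by both groups or a
    (n_patients, n_controls) pair.  Patient clinical covariates are
    drawn with the reference moments; control disease covariates are
    left missing.
    """
    if isinstance(n_per_group, (tuple, list)):
        n_patient, n_control = (int(v) for v in n_per_group)
    else:
        n_patient = n_control = int(n_per_group)
    if min(n_patient, n_control) < 2:
        raise DimensionError(f"need >= 2 subjects per group, got {n_per_group}")
    panels: list[TimeSeriesPanel] = []
    rows: list[dict] = []
    labels = default_region_labels(spec.n_regions)
    for group, prefix, n in (("patient", "P", n_patient), ("control", "C", n_control)):
        cov = make_group_covariance(spec, group)
        demo_rng = substream(seed, "clinical", group)
        demo: dict[str, np.ndarray] = {}
        moments = dict(CONTROL_MOMENTS) if group == "control" else dict(PATIENT_MOMENTS)
        for col in ("age", "education", "duration", "acth", "ufc",
                    "cortisol_0am", "cortisol_4pm", "cortisol_8am"):
            if col in moments:
                mean, sd = moments[col]
                demo[col] = _truncated_normal(demo_rng, mean, sd, n)
            else:
                demo[col] = np.full(n, np.nan)
        sex = np.where(demo_rng.random(n) < P_MALE[group], "M", "F")
        for i in range(n):
            subject_id = f"{prefix}{i + 1:03d}"
            panels.append(simulate_subject(
                cov, spec.n_volumes, spec.noise_sd,
                seed=seed, subject_id=subject_id,
                tr_seconds=spec.tr_seconds, region_labels=labels,
            ))
            rows.append({
                "subject_id": subject_id,
                "group": group,
                "age": demo["age"][i],
                "sex": sex[i],
                "education": demo["education"][i],
                "duration": demo["duration"][i],
                "acth": demo["acth"][i],
                "ufc": demo["ufc"][i],
                "cortisol_0am": demo["cortisol_0am"][i],
                "cortisol_4pm": demo["cortisol_4pm"][i],
                "cortisol_8am": demo["cortisol_8am"][i],
            })
    return panels, pd.DataFrame(rows)


def reference_graph(
    kind: str,
    n: int,
    k: Optional[int] = None,
    p: Optional[float] = None,
    rewire_p: Optional[float] = None,
    seed: Optional[int] = None,
) -> BinaryGraph:
    """Standard test-bed graphs: ring_lattice, erdos_renyi, watts_strogatz,
    star, complete, path."""
    if n < 2:
        raise ParameterError("n must be >= 2")
    if kind in ("ring_lattice", "watts_strogatz"):
        if k is None or k >= n or k < 2:
            raise ParameterError(f"need 2 <= k < n for {kind}, got k={k}")
    if kind == "erdos_renyi":
        if p is None or not (0 <= p <= 1):
            raise ParameterError(f"need 0 <= p <= 1 for erdos_renyi, got p={p}")
    if kind == "ring_lattice":
        g = nx.watts_strogatz_graph(n, k, 0.0)
    elif kind == "watts_strogatz":
        if rewire_p is None or not (0 <= rewire_p <= 1):
            raise ParameterError(f"need 0 <= rewire_p <= 1, got {rewire_p}")
        rng = substream(seed if seed is not None else 0, "watts_strogatz")
        g = nx.watts_strogatz_graph(n, k, rewire_p, seed=int(rng.integers(2**31)))
    elif kind == "erdos_renyi":
        rng = substream(seed if seed is not None else 0, "erdos_renyi")
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    elif kind == "star":
        g = nx.star_graph(n - 1)
    elif kind == "complete":
        g = nx.complete_graph(n)
    elif kind == "path":
        g = nx.path_graph(n)
    else:
        raise ParameterError(f"unknown reference graph kind {kind!r}")
    adjacency = nx.to_numpy_array(g, nodelist=range(n), dtype=np.uint8)
    n_pairs = n * (n - 1) // 2
    return BinaryGraph(
        region_labels=default_region_labels(n),
        adjacency=adjacency,
        sparsity=g.number_of_edges() / n_pairs,
    )
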