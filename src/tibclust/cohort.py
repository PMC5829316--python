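"""Synthetic cohort generation.

The study's raw 484-subject table was never deposited, so analyses are run
against synthetic cohorts that carry its categorical structure. Two modes:

``table_exact``
    The generator is driven by per-rotation 3x3 type-by-cluster count tables.
    Applying the labelling rules to the output reproduces those tables
    exactly: each subject's attributes are drawn uniformly within the
    defining range of its cluster and each typed angle uniformly within its
    type's interval. When several rotation panels are given they must share
    column sums (each subject has a single physical cluster); type labels are
    then assigned independently per rotation within each cluster.

``parametric``
    Cluster and per-rotation type memberships are drawn at random with given
    proportions (defaults: the study's observed proportions); attribute and
    angle draws are as above.

Uniform-within-cell sampling is a declared assumption, not an inference: the
study reports only thresholds and counts, never attribute distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import reference_tables as ref
from .subjects import ROTATIONS, Subject
from .typing_rules import NARROW_THRESHOLD, WIDE_THRESHOLD

__all__ = [
    "CohortSpec",
    "SpecificationError",
    "generate_cohort",
    "well_separated_blobs",
    "study_cohort_spec",
]


class SpecificationError(ValueError):
    """A cohort specification is inconsistent or infeasible."""


# Per-cluster sampling ranges (half-open on the left where the rule threshold
# is exclusive). Cluster 1 is unconstrained in weight/height, so it spans the
# full plausible range.
AGE_RANGES = {1: (31.0, 60.0), 2: (18.0, 30.0), 3: (18.0, 30.0)}
WEIGHT_RANGES = {1: (45.0, 100.0), 2: (45.0, 60.0), 3: (61.0, 100.0)}
HEIGHT_RANGES = {1: (1.50, 1.95), 2: (1.50, 1.70), 3: (1.71, 1.95)}

# Per-type angle intervals (degrees). Types 2 and 3 exclude their left
# endpoint, matching the classification rule.
ANGLE_RANGES = {
    1: (0.0, NARROW_THRESHOLD, True),
    2: (NARROW_THRESHOLD, WIDE_THRESHOLD, False),
    3: (WIDE_THRESHOLD, 90.0, False),
}


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort.

    Parameters
    ----------
    n_subjects : int
        Cohort size.
    mode : {"table_exact", "parametric"}
        Sampling mode (see module docstring).
    joint_counts : mapping of rotation -> 3x3 array, optional
        Type-by-cluster count panels for ``table_exact`` mode. Rotations not
        listed receive Type 2 angles.
    cluster_proportions : tuple of 3 floats, optional
        Cluster membership probabilities for ``parametric`` mode; must sum
        to 1. Default: the study's 52/249/183 split.
    type_proportions : mapping of rotation -> 3 floats, optional
        Per-rotation type probabilities for ``parametric`` mode. Default:
        the study's observed per-rotation type frequencies.
    seed : int
        Seed for the single random stream driving all draws.
    """

    n_subjects: int = ref.N_SUBJECTS
    mode: str = "table_exact"
    joint_counts: Mapping[str, np.ndarray] | None = None
    cluster_proportions: tuple[float, float, float] | None = None
    type_proportions: Mapping[str, Sequence[float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise SpecificationError("n_subjects must be at least 1")
        if self.mode not in ("table_exact", "parametric"):
            raise SpecificationError(f"unknown mode {self.mode!r}")
        if self.mode == "table_exact":
            self._validate_table_exact()
        else:
            self._validate_parametric()

    def _validate_table_exact(self) -> None:
        if not self.joint_counts:
            raise SpecificationError("table_exact mode requires joint_counts")
        column_sums = None
        for rotation, panel in self.joint_counts.items():
            if rotation.upper() not in ROTATIONS:
                raise SpecificationError(f"unknown rotation {rotation!r}")
            panel = np.asarray(panel)
            if panel.shape != (3, 3):
                raise SpecificationError(
                    f"{rotation}: joint counts must be 3x3, got {panel.shape}"
                )
            if (panel < 0).any():
                raise SpecificationError(f"{rotation}: counts must be non-negative")
            if panel.sum() != self.n_subjects:
                raise SpecificationError(
                    f"{rotation}: counts sum to {panel.sum()}, "
                    f"but n_subjects is {self.n_subjects}"
                )
            sums = panel.sum(axis=0)
            if column_sums is None:
                column_sums = sums
            elif not np.array_equal(column_sums, sums):
                raise SpecificationError(
                    "rotation panels disagree on cluster sizes (column sums); "
                    "each subject has a single physical cluster"
                )

    def _validate_parametric(self) -> None:
        if self.cluster_proportions is not None:
            p = np.asarray(self.cluster_proportions, dtype=float)
            if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise SpecificationError(
                    "cluster_proportions must be 3 non-negative values summing to 1"
                )

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortSpec":
        """Load a spec from a YAML (or JSON) config file."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise SpecificationError(f"{path}: expected a mapping at top level")
        if "joint_counts" in raw and raw["joint_counts"] is not None:
            raw["joint_counts"] = {
                rot: np.asarray(panel, dtype=int)
                for rot, panel in raw["joint_counts"].items()
            }
        if "cluster_proportions" in raw and raw["cluster_proportions"] is not None:
            raw["cluster_proportions"] = tuple(raw["cluster_proportions"])
        return cls(**raw)


def study_cohort_spec(seed: int = 0) -> CohortSpec:
    """The table-exact spec reproducing the study's published panels."""
    return CohortSpec(
        n_subjects=ref.N_SUBJECTS,
        mode="table_exact",
        joint_counts=ref.REAL_COUNTS,
        seed=seed,
    )


def _draw_open_left(rng: np.random.Generator, low: float, high: float, n: int):
    """Uniform draws in (low, high): nudge the lower bound one ulp up."""
    return rng.uniform(np.nextafter(low, high), high, size=n)


def _draw_angles(rng: np.random.Generator, types: np.ndarray) -> np.ndarray:
    angles = np.empty(types.shape[0], dtype=float)
    for t, (low, high, closed_left) in ANGLE_RANGES.items():
        mask = types == t
        n = int(mask.sum())
        if n == 0:
            continue
        if closed_left:
            angles[mask] = rng.uniform(low, high, size=n)
        else:
            angles[mask] = _draw_open_left(rng, low, high, n)
    return angles


def _draw_attributes(rng: np.random.Generator, cluster: int, n: int):
    age_low, age_high = AGE_RANGES[cluster]
    w_low, w_high = WEIGHT_RANGES[cluster]
    h_low, h_high = HEIGHT_RANGES[cluster]
    age = rng.uniform(age_low, age_high, size=n)
    weight = rng.uniform(w_low, w_high, size=n)
    height = rng.uniform(h_low, h_high, size=n)
    return age, weight, height


def generate_cohort(spec: CohortSpec) -> list[Subject]:
    """Generate a synthetic cohort; deterministic given ``spec.seed``.

    In ``table_exact`` mode, labelling the result with the package's rules
    and tabulating reproduces ``spec.joint_counts`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "table_exact":
        clusters, types_by_rotation = _table_exact_memberships(spec, rng)
    else:
        clusters, types_by_rotation = _parametric_memberships(spec, rng)

    n = spec.n_subjects
    age = np.empty(n)
    weight = np.empty(n)
    height = np.empty(n)
    for c in (1, 2, 3):
        mask = clusters == c
        if mask.any():
            age[mask], weight[mask], height[mask] = _draw_attributes(
                rng, c, int(mask.sum())
            )
    angles = {
        rot: _draw_angles(rng, types_by_rotation[rot]) for rot in ROTATIONS
    }
    order = rng.permutation(n)
    return [
        Subject(
            age=float(age[i]),
            weight=float(weight[i]),
            height=float(height[i]),
            rter=float(angles["RTER"][i]),
            rtir=float(angles["RTIR"][i]),
            lter=float(angles["LTER"][i]),
            ltir=float(angles["LTIR"][i]),
        )
        for i in order
    ]


def _table_exact_memberships(spec: CohortSpec, rng: np.random.Generator):
    panels = {rot.upper(): np.asarray(p) for rot, p in spec.joint_counts.items()}
    cluster_sizes = next(iter(panels.values())).sum(axis=0)
    clusters = np.repeat([1, 2, 3], cluster_sizes)
    types_by_rotation: dict[str, np.ndarray] = {}
    for rot in ROTATIONS:
        types = np.empty(spec.n_subjects, dtype=int)
        offset = 0
        for c in range(3):
            size = int(cluster_sizes[c])
            if rot in panels:
                column = panels[rot][:, c]
                block = np.repeat([1, 2, 3], column)
            else:
                block = np.full(size, 2)
            rng.shuffle(block)
            types[offset : offset + size] = block
            offset += size
        types_by_rotation[rot] = types
    return clusters, types_by_rotation


def _parametric_memberships(spec: CohortSpec, rng: np.random.Generator):
    if spec.cluster_proportions is not None:
        cluster_p = np.asarray(spec.cluster_proportions, dtype=float)
    else:
        cluster_p = np.array(ref.CLUSTER_SIZES, dtype=float) / ref.N_SUBJECTS
    clusters = rng.choice([1, 2, 3], size=spec.n_subjects, p=cluster_p)
    types_by_rotation = {}
    for rot in ROTATIONS:
        if spec.type_proportions and rot in spec.type_proportions:
            type_p = np.asarray(spec.type_proportions[rot], dtype=float)
            type_p = type_p / type_p.sum()
        else:
            type_p = ref.type_totals(rot).astype(float) / ref.N_SUBJECTS
        types_by_rotation[rot] = rng.choice([1, 2, 3], size=spec.n_subjects, p=type_p)
    return clusters, types_by_rotation


def well_separated_blobs(
    k: int,
    n_per_cluster: int,
    separation: float = 10.0,
    noise_sd: float = 0.5,
    p: int = 2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Isotropic Gaussian clusters around mutually distant centers.

    Centers sit at ``j * separation`` on every coordinate, so consecutive
    centers are ``separation * sqrt(p)`` apart. Returns the data matrix, the
    true labels (1-based, one per point) and the true centers — ground truth
    for center-recovery tests of the clustering engines.
    """
    if k < 1 or n_per_cluster < 1:
        raise ValueError("k and n_per_cluster must be at least 1")
    if separation <= 0 or noise_sd < 0:
        raise ValueError("separation must be positive and noise_sd non-negative")
    rng = np.random.default_rng(seed)
    centers = np.outer(np.arange(k, dtype=float), np.ones(p)) * separation
    labels = np.repeat(np.arange(1, k + 1), n_per_cluster)
    X = centers[labels - 1] + rng.normal(0.0, noise_sd, size=(k * n_per_cluster, p))
    return X, labels, centers
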