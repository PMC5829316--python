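"""Rule-based labelling of subjects.

Two categorical rules drive the whole analysis:

* a tibial-rotation angle maps to Type 1 (abnormally narrow, <= 20 deg),
  Type 2 (normal, 20-65 deg) or Type 3 (abnormally wide, > 65 deg) — Types 1
  and 3 are the pathological ones;
* a subject's physical attributes map to one of three strata: Cluster 1
  (age > 30), Cluster 2 (age <= 30 and weight <= 60 kg) or Cluster 3
  (age <= 30 and weight > 60 kg).

The cluster rule uses age and weight only. Height stays in the data model
(and in clustering features) but does not enter the rule: the published
thresholds for weight and height are concordant for typical subjects, and
age/weight are the declared stratification criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .subjects import ROTATIONS, Subject

#: Angle thresholds (degrees): Type 1 is [0, NARROW], Type 2 is (NARROW, WIDE],
#: Type 3 is (WIDE, 90].
NARROW_THRESHOLD = 20.0
WIDE_THRESHOLD = 65.0

#: Cluster rule thresholds.
AGE_THRESHOLD = 30.0
WEIGHT_THRESHOLD = 60.0
HEIGHT_THRESHOLD = 1.70


class DomainError(ValueError):
    """Input outside the domain of a labelling rule."""


@dataclass(frozen=True)
class TypeLabel:
    """Rotation type 1, 2 or 3; types 1 and 3 are pathological."""

    value: int

    def __post_init__(self) -> None:
        if self.value not in (1, 2, 3):
            raise DomainError(f"rotation type must be 1, 2 or 3, got {self.value!r}")

    @property
    def pathological(self) -> bool:
        return self.value in (1, 3)


@dataclass(frozen=True)
class ClusterLabel:
    """Physical-attribute stratum 1, 2 or 3."""

    value: int

    def __post_init__(self) -> None:
        if self.value not in (1, 2, 3):
            raise DomainError(f"cluster must be 1, 2 or 3, got {self.value!r}")


def classify_rotation_type(angle: float) -> TypeLabel:
    """Classify one rotation angle (degrees) into Type 1/2/3.

    The boundaries are inclusive on the left interval: exactly 20 degrees is
    Type 1 and exactly 65 degrees is Type 2.

    Raises
    ------
    DomainError
        If ``angle`` lies outside [0, 90].
    """
    if not 0 <= angle <= 90:
        raise DomainError(f"rotation angle {angle!r} lies outside [0, 90] degrees")
    if angle <= NARROW_THRESHOLD:
        return TypeLabel(1)
    if angle <= WIDE_THRESHOLD:
        return TypeLabel(2)
    return TypeLabel(3)


def classify_physical_cluster(subject: Subject) -> ClusterLabel:
    """Classify a subject into Cluster 1/2/3 from age and weight.

    Age above 30 years is Cluster 1 regardless of build; otherwise weight at
    most 60 kg is Cluster 2 and heavier subjects are Cluster 3. Every valid
    subject receives exactly one cluster.
    """
    if subject.age > AGE_THRESHOLD:
        return ClusterLabel(1)
    if subject.weight <= WEIGHT_THRESHOLD:
        return ClusterLabel(2)
    return ClusterLabel(3)


def label_cohort(
    subjects: Sequence[Subject], rotation: str
) -> tuple[list[TypeLabel], list[ClusterLabel]]:
    """Label every subject with its rotation type and physical cluster.

    Parameters
    ----------
    subjects : sequence of Subject
        Non-empty cohort.
    rotation : str
        Which rotation component to type: one of ``RTER``, ``RTIR``,
        ``LTER``, ``LTIR``.

    Returns
    -------
    (types, clusters)
        One :class:`TypeLabel` and one :class:`ClusterLabel` per subject,
        order preserved.
    """
    if len(subjects) == 0:
        raise DomainError("cannot label an empty cohort")
    rotation = rotation.upper()
    if rotation not in ROTATIONS:
        raise DomainError(f"unknown rotation {rotation!r}; expected one of {ROTATIONS}")
    types: list[TypeLabel] = []
    clusters: list[ClusterLabel] = []
    for i, subject in enumerate(subjects):
        try:
            types.append(classify_rotation_type(subject.angle(rotation)))
            clusters.append(classify_physical_cluster(subject))
        except DomainError as exc:
            raise DomainError(f"subject {i}: {exc}") from exc
    return types, clusters
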