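"""Numeric feature matrices for clustering.

Clustering runs on the physical attributes (age, weight, height). The raw
scales are wildly unbalanced — height in metres spans ~0.45 while weight in
kilograms spans ~55 — so features are z-standardised by default and the
scaling parameters are kept so that fitted centers can be reported back in
original units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .subjects import Subject

DEFAULT_FEATURES = ("age", "weight", "height")


@dataclass
class FeatureMatrix:
    """An N x p matrix of clustering features with optional scaling record.

    Attributes
    ----------
    values : ndarray of shape (N, p)
        The (possibly standardised) feature values; finite, no missing data.
    feature_names : tuple of str
        Column labels.
    mean_, scale_ : ndarray of shape (p,) or None
        Standardisation parameters; ``None`` when the matrix is raw.
    """

    values: np.ndarray
    feature_names: tuple[str, ...]
    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("feature matrix must be 2-D with N >= 1 and p >= 1")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must match the number of columns")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_subjects(
        cls,
        subjects: Sequence[Subject],
        features: Sequence[str] = DEFAULT_FEATURES,
        standardize: bool = True,
    ) -> "FeatureMatrix":
        """Assemble (and optionally z-standardise) attributes of a cohort."""
        raw = np.array(
            [[getattr(s, name) for name in features] for s in subjects], dtype=float
        )
        fm = cls(raw, tuple(features))
        return fm.standardized() if standardize else fm

    def standardized(self) -> "FeatureMatrix":
        """Return a z-scored copy (zero-spread columns are left unscaled)."""
        mean = self.values.mean(axis=0)
        scale = self.values.std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)
        return FeatureMatrix(
            (self.values - mean) / scale, self.feature_names, mean, scale
        )

    def to_original_units(self, points: np.ndarray) -> np.ndarray:
        """Map points (e.g. cluster centers) back to the raw feature scale."""
        points = np.asarray(points, dtype=float)
        if self.mean_ is None:
            return points.copy()
        return points * self.scale_ + self.mean_
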