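"""Fitted cluster model container and JSON serialisation."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class ClusterModel:
    """K cluster centers plus the bookkeeping of the fit that produced them.

    ``centers`` live in the feature space the engine saw (usually z-scored);
    ``centers_original`` are the same centers in raw units when a scaling
    record was available. ``labels`` are 1-based cluster numbers, one per
    input point, assigned to the nearest center.
    """

    centers: np.ndarray
    k: int
    objective: float
    n_iterations: int
    converged: bool
    method: str
    seed: int | None = None
    labels: np.ndarray | None = None
    centers_original: np.ndarray | None = None
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if self.objective < 0 or not np.isfinite(self.centers).all():
            raise ValueError("objective must be >= 0 and centers finite")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["centers"] = self.centers.tolist()
        d["labels"] = None if self.labels is None else np.asarray(self.labels).tolist()
        if self.centers_original is not None:
            d["centers_original"] = np.asarray(self.centers_original).tolist()
        if self.feature_names is not None:
            d["feature_names"] = list(self.feature_names)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "ClusterModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        if d.get("labels") is not None:
            d["labels"] = np.asarray(d["labels"], dtype=int)
        if d.get("centers_original") is not None:
            d["centers_original"] = np.asarray(d["centers_original"], dtype=float)
        if d.get("feature_names") is not None:
            d["feature_names"] = tuple(d["feature_names"])
        return cls(**d)
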