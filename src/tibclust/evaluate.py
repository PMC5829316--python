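"""Contingency tables, percentage tables and the accuracy-rate statistic.

The study summarises each rotation as a 3x3 type-by-cluster contingency
table, converts it to row-wise percentages, and scores a clustering method
per cell with

    accuracy = 100 * min(real%, predicted%) / max(real%, predicted%)

so identical percentages score 100 and a method that puts weight where none
belongs (or none where some belongs) scores 0. Both operands are the
2-decimal rounded percentages; rounding is half-up throughout, matching the
published arithmetic. A cell where both percentages are zero is undefined
and renders as "-".
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .typing_rules import ClusterLabel, TypeLabel

__all__ = [
    "round_half_up",
    "CountTable",
    "PercentTable",
    "contingency_table",
    "row_percentages",
    "accuracy_rate",
    "accuracy_table",
    "compare_methods",
    "align_labels",
    "apply_alignment",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _as_values(labels: Sequence, kind) -> np.ndarray:
    return np.array(
        [lab.value if isinstance(lab, kind) else int(lab) for lab in labels]
    )


@dataclass
class CountTable:
    """3x3 type-by-cluster counts (rows Type 1..3, columns Cluster 1..3)."""

    counts: np.ndarray
    rotation: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3):
            raise ValueError(f"counts must be 3x3, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts,
            index=[f"Type {t}" for t in (1, 2, 3)],
            columns=[f"Cluster {c}" for c in (1, 2, 3)],
        )
        df["Total"] = self.row_totals
        df.loc["Total"] = df.sum(axis=0)
        return df


@dataclass
class PercentTable:
    """Row-wise percentages of a :class:`CountTable`, rounded half-up to 2 dp.

    Cells of a zero-total row are NaN (undefined). ``counts`` is retained so
    text rendering can print "-" for zero-count cells, the published
    convention.
    """

    percents: np.ndarray
    counts: np.ndarray | None = None
    rotation: str | None = None

    def __post_init__(self) -> None:
        self.percents = np.asarray(self.percents, dtype=float)
        if self.percents.shape != (3, 3):
            raise ValueError(f"percents must be 3x3, got {self.percents.shape}")

    def to_frame(self, dash_zero_cells: bool = False) -> pd.DataFrame:
        def fmt(i, j):
            v = self.percents[i, j]
            if np.isnan(v):
                return "-"
            if (
                dash_zero_cells
                and self.counts is not None
                and self.counts[i, j] == 0
            ):
                return "-"
            return f"{v:.2f}"

        return pd.DataFrame(
            [[fmt(i, j) for j in range(3)] for i in range(3)],
            index=[f"Type {t}" for t in (1, 2, 3)],
            columns=[f"Cluster {c}" for c in (1, 2, 3)],
        )


def contingency_table(
    type_labels: Sequence[TypeLabel | int],
    cluster_labels: Sequence[ClusterLabel | int],
    rotation: str | None = None,
) -> CountTable:
    """Cross-tabulate rotation types against clusters.

    Cell (t, c) counts subjects with Type t and Cluster c; the grand total
    equals the number of subjects.
    """
    t = _as_values(type_labels, TypeLabel)
    c = _as_values(cluster_labels, ClusterLabel)
    if t.shape != c.shape:
        raise ValueError(
            f"label lists differ in length: {t.shape[0]} vs {c.shape[0]}"
        )
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (t - 1, c - 1), 1)
    return CountTable(counts, rotation)


def row_percentages(table: CountTable) -> PercentTable:
    """Percentage of each row's total per cell, half-up rounded to 2 dp.

    Rows with zero total yield NaN cells.
    """
    percents = np.full((3, 3), np.nan)
    totals = table.row_totals
    for i in range(3):
        if totals[i] > 0:
            for j in range(3):
                percents[i, j] = round_half_up(100.0 * table.counts[i, j] / totals[i])
    return PercentTable(percents, table.counts.copy(), table.rotation)


def accuracy_rate(real_pct: float, predicted_pct: float) -> float:
    """Agreement score 100 * min / max of two percentages, 2-dp rounded.

    NaN (undefined) when both are zero; 0.0 when exactly one is zero.
    Symmetric; equals 100 iff the operands are equal and nonzero.
    """
    for name, v in (("real_pct", real_pct), ("predicted_pct", predicted_pct)):
        if np.isnan(v) or not 0 <= v <= 100:
            if np.isnan(v):
                continue
            raise ValueError(f"{name} must lie in [0, 100], got {v!r}")
    a = 0.0 if np.isnan(real_pct) else float(real_pct)
    b = 0.0 if np.isnan(predicted_pct) else float(predicted_pct)
    if a == 0.0 and b == 0.0:
        return float("nan")
    if a == 0.0 or b == 0.0:
        return 0.0
    return round_half_up(100.0 * min(a, b) / max(a, b))


def accuracy_table(real: PercentTable, predicted: PercentTable) -> np.ndarray:
    """Elementwise accuracy rates of a predicted table against the real one."""
    if real.percents.shape != predicted.percents.shape:
        raise ValueError("percentage tables differ in shape")
    out = np.full((3, 3), np.nan)
    for i in range(3):
        for j in range(3):
            out[i, j] = accuracy_rate(real.percents[i, j], predicted.percents[i, j])
    return out


def compare_methods(
    real: PercentTable, km: PercentTable, ga: PercentTable
) -> dict[str, np.ndarray]:
    """Accuracy tables for both methods against the rule-based reference."""
    return {"GA": accuracy_table(real, ga), "KM": accuracy_table(real, km)}


def align_labels(
    reference: Sequence[ClusterLabel | int], predicted: Sequence[int]
) -> dict[int, int]:
    """Best permutation matching arbitrary predicted cluster indices to 1..3.

    Exhaustive search over all 3! permutations, maximising agreement with the
    reference labels; ties resolve to the lexicographically smallest
    permutation. Returns a mapping predicted label -> reference label.
    """
    r = _as_values(reference, ClusterLabel)
    p = np.asarray(list(predicted), dtype=int)
    if r.shape != p.shape:
        raise ValueError(f"label lists differ in length: {r.size} vs {p.size}")
    pred_values = sorted(set(p.tolist()))
    if len(pred_values) > 3:
        raise ValueError("predicted labels take more than 3 distinct values")
    best_perm = None
    best_agreement = -1
    for perm in permutations((1, 2, 3)):
        mapping = dict(zip(pred_values, perm))
        agreement = int(np.sum([mapping[v] for v in p] == r))
        if agreement > best_agreement:
            best_agreement = agreement
            best_perm = dict(zip(pred_values, perm))
    return best_perm


def apply_alignment(labels: Sequence[int], mapping: Mapping[int, int]) -> np.ndarray:
    """Relabel predictions through an alignment mapping."""
    return np.array([mapping[int(v)] for v in labels])
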