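"""End-to-end study pipeline: cohort -> clustering -> per-rotation report.

Ties the pieces together the way the study is organised: rule-based labels
give the "real" tables, K-Means and the GA cluster the physical attributes
(z-scored age/weight/height), their arbitrary cluster indices are aligned to
the rule-based clusters, and each method is scored per rotation with the
accuracy-rate statistic.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluate import (
    CountTable,
    PercentTable,
    accuracy_table,
    align_labels,
    apply_alignment,
    contingency_table,
    row_percentages,
)
from .features import FeatureMatrix
from .ga import GAConfig, ga_cluster_fit
from .kmeans import kmeans_fit
from .subjects import ROTATIONS, Subject
from .typing_rules import label_cohort

__all__ = ["run_study", "report_to_files"]


def run_study(
    subjects: Sequence[Subject],
    k: int = 3,
    seed: int | None = None,
    ga_config: GAConfig | None = None,
    features: Sequence[str] = ("age", "weight", "height"),
) -> dict:
    """Cluster a cohort with both engines and build the full table report.

    Returns a nested dict with, per rotation: the real/KM/GA count and
    percentage tables and both accuracy tables, plus the fitted models and
    the aligned label vectors.
    """
    fm = FeatureMatrix.from_subjects(subjects, features=features)
    km_model = kmeans_fit(fm, k=k, seed=seed)
    ga_config = ga_config or GAConfig(seed=seed)
    ga_model = ga_cluster_fit(fm, k=k, config=ga_config)

    # rule-based clusters are identical across rotations; align once
    _, rule_clusters = label_cohort(subjects, "RTER")
    rule_values = np.array([c.value for c in rule_clusters])
    aligned = {}
    for name, model in (("KM", km_model), ("GA", ga_model)):
        mapping = align_labels(rule_clusters, model.labels)
        aligned[name] = apply_alignment(model.labels, mapping)

    report: dict = {
        "models": {"KM": km_model, "GA": ga_model},
        "aligned_labels": aligned,
        "rule_clusters": rule_values,
        "rotations": {},
    }
    for rotation in ROTATIONS:
        types, _ = label_cohort(subjects, rotation)
        real_counts = contingency_table(types, rule_values, rotation)
        real_pct = row_percentages(real_counts)
        entry = {"real": {"counts": real_counts, "percents": real_pct}}
        for name in ("KM", "GA"):
            counts = contingency_table(types, aligned[name], rotation)
            pct = row_percentages(counts)
            entry[name] = {
                "counts": counts,
                "percents": pct,
                "accuracy": accuracy_table(real_pct, pct),
            }
        report["rotations"][rotation] = entry
    return report


def _accuracy_frame(entry: dict) -> pd.DataFrame:
    frames = {}
    for name in ("GA", "KM"):
        acc = entry[name]["accuracy"]
        frames[name] = pd.DataFrame(
            [["-" if np.isnan(v) else f"{v:.2f}" for v in row] for row in acc],
            index=[f"Type {t}" for t in (1, 2, 3)],
            columns=[f"Cluster {c} {name}" for c in (1, 2, 3)],
        )
    return pd.concat([frames["GA"], frames["KM"]], axis=1)


def report_to_files(report: dict, out_dir: str | Path) -> None:
    """Write per-rotation CSV tables and a machine-readable JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"rotations": {}}
    for rotation, entry in report["rotations"].items():
        entry["real"]["counts"].to_frame().to_csv(out / f"{rotation}_real_counts.csv")
        entry["real"]["percents"].to_frame(dash_zero_cells=True).to_csv(
            out / f"{rotation}_real_percents.csv"
        )
        for name in ("KM", "GA"):
            entry[name]["counts"].to_frame().to_csv(
                out / f"{rotation}_{name.lower()}_counts.csv"
            )
            entry[name]["percents"].to_frame(dash_zero_cells=True).to_csv(
                out / f"{rotation}_{name.lower()}_percents.csv"
            )
        _accuracy_frame(entry).to_csv(out / f"{rotation}_accuracy.csv")
        summary["rotations"][rotation] = {
            "real_counts": entry["real"]["counts"].counts.tolist(),
            "real_percents": _jsonable(entry["real"]["percents"]),
            "km_percents": _jsonable(entry["KM"]["percents"]),
            "ga_percents": _jsonable(entry["GA"]["percents"]),
            "km_accuracy": _jsonable_array(entry["KM"]["accuracy"]),
            "ga_accuracy": _jsonable_array(entry["GA"]["accuracy"]),
        }
    summary["km_objective"] = report["models"]["KM"].objective
    summary["ga_objective"] = report["models"]["GA"].objective
    (out / "summary.json").write_text(json.dumps(summary, indent=2), encoding="utf-8")


def _jsonable(pct: PercentTable) -> list:
    return _jsonable_array(pct.percents)


def _jsonable_array(a: np.ndarray) -> list:
    return [[None if np.isnan(v) else v for v in row] for row in np.asarray(a)]
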