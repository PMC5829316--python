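"""Published summary tables of the original 484-subject study.

The raw subject-level data behind the study was never deposited; what survives
are its summary tables: per-rotation type-by-cluster contingency tables for
the rule-based ("real") labels and for the K-Means and GA cluster outputs.
These serve two purposes here: the real table parameterises the synthetic
cohort generator (table-exact mode), and the method tables are the inputs to
the accuracy-rate arithmetic.

Rows are Type 1..3, columns are Cluster 1..3. Marginal totals are always
recomputed from the cells — the published marginals contain typos (one row
total is printed as 24 where its cells sum to 54).
"""

from __future__ import annotations

import numpy as np

#: Total cohort size.
N_SUBJECTS = 484

#: Rule-based ("real") type-by-cluster counts, one 3x3 panel per rotation.
REAL_COUNTS: dict[str, np.ndarray] = {
    "RTER": np.array([[0, 17, 22], [50, 183, 158], [2, 49, 3]]),
    "RTIR": np.array([[1, 7, 25], [48, 223, 152], [3, 19, 6]]),
    "LTER": np.array([[1, 16, 20], [47, 160, 150], [4, 73, 13]]),
    "LTIR": np.array([[3, 14, 34], [49, 218, 147], [0, 17, 2]]),
}

#: GA cluster-output counts per rotation, aligned to Clusters 1..3.
GA_COUNTS: dict[str, np.ndarray] = {
    "RTER": np.array([[0, 17, 22], [30, 205, 156], [1, 48, 5]]),
    "RTIR": np.array([[1, 2, 30], [59, 226, 138], [2, 21, 5]]),
    "LTER": np.array([[1, 13, 23], [38, 161, 158], [1, 75, 14]]),
    "LTIR": np.array([[1, 17, 33], [9, 222, 183], [0, 17, 2]]),
}

#: K-Means cluster-output counts per rotation, aligned to Clusters 1..3.
KM_COUNTS: dict[str, np.ndarray] = {
    "RTER": np.array([[0, 2, 37], [42, 207, 142], [4, 43, 7]]),
    "RTIR": np.array([[0, 1, 32], [36, 263, 124], [2, 23, 3]]),
    "LTER": np.array([[1, 1, 35], [36, 242, 79], [2, 67, 21]]),
    "LTIR": np.array([[1, 3, 47], [36, 251, 127], [0, 19, 0]]),
}

#: Cluster sizes implied by every rotation panel's column sums.
CLUSTER_SIZES = (52, 249, 183)

_ = np.nan  # "-" in the published tables (zero-count cells)

#: Published row-wise percentage tables. These are primary inputs to the
#: accuracy-rate arithmetic, so the source's own 2-dp rounding is preserved
#: verbatim — including a handful of cells that differ by 0.01 from what the
#: count tables above imply.
REAL_PERCENTS: dict[str, np.ndarray] = {
    "RTER": np.array([[_, 43.59, 56.41], [12.79, 46.80, 40.41], [3.70, 90.74, 5.56]]),
    "RTIR": np.array([[3.03, 21.21, 75.76], [11.35, 52.72, 35.93], [10.71, 67.86, 21.43]]),
    "LTER": np.array([[2.70, 43.24, 54.06], [13.17, 44.82, 42.01], [4.44, 81.11, 14.45]]),
    "LTIR": np.array([[5.88, 27.45, 66.67], [11.84, 52.66, 35.50], [_, 89.47, 10.53]]),
}

GA_PERCENTS: dict[str, np.ndarray] = {
    "RTER": np.array([[_, 43.59, 56.41], [7.67, 52.43, 39.90], [1.85, 88.89, 9.26]]),
    "RTIR": np.array([[3.03, 6.06, 90.91], [13.95, 53.43, 32.62], [7.14, 75.00, 17.86]]),
    "LTER": np.array([[2.70, 35.14, 62.16], [10.64, 45.10, 44.26], [1.11, 83.33, 15.56]]),
    "LTIR": np.array([[1.96, 33.33, 64.71], [2.17, 53.62, 44.20], [_, 89.47, 10.53]]),
}

KM_PERCENTS: dict[str, np.ndarray] = {
    "RTER": np.array([[_, 5.13, 94.87], [10.74, 52.94, 36.32], [7.41, 79.63, 12.96]]),
    "RTIR": np.array([[_, 3.03, 96.97], [8.51, 62.18, 29.31], [7.14, 82.14, 10.72]]),
    "LTER": np.array([[2.70, 2.70, 94.60], [10.08, 67.79, 22.13], [2.22, 74.45, 23.33]]),
    "LTIR": np.array([[1.96, 5.88, 92.16], [8.70, 60.63, 30.67], [_, 100.00, _]]),
}


def type_totals(rotation: str) -> np.ndarray:
    """Per-type subject counts for one rotation, recomputed from cells."""
    return REAL_COUNTS[rotation].sum(axis=1)
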