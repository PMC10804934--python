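"""Metrics and statistics for the three-setting comparison.

Dice similarity for segmentation, AUROC for classification, bootstrap spread
(1000 redraws by default), and normality-gated paired tests: Shapiro-Wilk on
the paired differences chooses between the two-tailed paired t-test and the
Wilcoxon signed-rank test; p <= 0.05 is reported as significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "MetricSummary",
    "dice_score",
    "auroc",
    "bootstrap_spread",
    "paired_compare",
    "comparison_table",
]

ALPHA = 0.05


@dataclass(frozen=True)
class MetricSummary:
    point: float
    sd: float
    n: int
    method: str  # "bootstrap" | "per-case"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def dice_score(predicted: np.ndarray, reference: np.ndarray) -> float:
    """Dice overlap ``2|A n B| / (|A| + |B|)`` of the foreground voxels.

    Inputs are boolean (or {0,1}) masks of identical shape.  Two empty masks
    score 1.0 by convention (perfect agreement on "nothing to segment").
    """
    a = np.asarray(predicted).astype(bool)
    b = np.asarray(reference).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / total)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve; equals the normalized Mann-Whitney U
    statistic with midrank tie handling."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def bootstrap_spread(
    metric, *arrays, redraws: int = 1000, seed=0
) -> MetricSummary:
    """Mean and sd of ``metric(*resampled arrays)`` over patient redraws.

    Cases (rows of every array, jointly) are resampled with replacement;
    redraws where the metric is undefined (e.g. a single-class resample for
    AUROC) are redrawn.  Deterministic given the seed.
    """
    if redraws < 1:
        raise ValueError("redraws must be >= 1")
    arrays = [np.asarray(a) for a in arrays]
    n = arrays[0].shape[0]
    if n == 0:
        raise ValueError("empty data")
    rng = np.random.default_rng(seed)
    values = []
    attempts = 0
    while len(values) < redraws and attempts < 50 * redraws:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        try:
            values.append(float(metric(*(a[idx] for a in arrays))))
        except ValueError:
            continue
    if not values:
        raise ValueError("metric undefined on every bootstrap redraw")
    values = np.asarray(values)
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return MetricSummary(
        point=float(values.mean()), sd=sd, n=n, method="bootstrap"
    )


def paired_compare(sample_a, sample_b) -> dict:
    """Normality-gated paired test between two matched samples.

    Shapiro-Wilk on the paired differences at alpha = 0.05 selects the test:
    normal differences -> two-tailed paired t-test; otherwise Wilcoxon
    signed-rank.  All-zero differences short-circuit to a degenerate Wilcoxon
    (no difference, p = 1), flagged in the result.
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("samples must be matched 1-D arrays")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    diffs = a - b
    if np.all(diffs == 0):
        return {
            "test": "wilcoxon",
            "statistic": 0.0,
            "p": 1.0,
            "normality_p": np.nan,
            "significant": False,
            "degenerate": True,
        }
    norm_p = float(stats.shapiro(diffs).pvalue)
    if norm_p >= ALPHA:
        res = stats.ttest_rel(a, b)
        test = "paired-t"
    else:
        res = stats.wilcoxon(a, b)
        test = "wilcoxon"
    p = float(res.pvalue)
    return {
        "test": test,
        "statistic": float(res.statistic),
        "p": p,
        "normality_p": norm_p,
        "significant": p <= ALPHA,
        "degenerate": False,
    }


def comparison_table(per_case_metrics: dict[str, np.ndarray], reference: str):
    """Mean +/- sd per setting with p-values versus the reference setting.

    ``per_case_metrics`` maps a setting name (site / FL / secure FL) to its
    per-case metric vector; all vectors must be matched case-for-case.
    """
    import pandas as pd

    ref = np.asarray(per_case_metrics[reference], dtype=np.float64)
    rows = []
    for name, vals in per_case_metrics.items():
        vals = np.asarray(vals, dtype=np.float64)
        row = {
            "setting": name,
            "mean": vals.mean(),
            "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
            "n": len(vals),
        }
        if name != reference and len(vals) >= 3:
            cmp = paired_compare(vals, ref)
            row["p_vs_" + reference] = cmp["p"]
            row["test"] = cmp["test"]
        rows.append(row)
    return pd.DataFrame(rows)
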