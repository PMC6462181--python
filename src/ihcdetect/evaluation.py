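"""Patch-level classification statistics and multi-rater count agreement.

Two evaluation levels mirror how a detection pipeline is judged in
practice:

* **patch level** — a confusion matrix over positive/negative patches
  with per-class normalized rates (sensitivity = 100 − FNR,
  specificity = 100 − FPR, both in percent);
* **count level** — per-image cell counts of several raters (human
  observers and the model) compared through relative differences to the
  cross-rater mean: ``diff = (mean − count) / mean``, summarized per
  rater by mean, median and interquartile range.  Over-counting raters
  get negative differences under this sign convention (flippable).

A greedy nearest-first matcher pairs detections with ground-truth
centers within a physical tolerance, which turns planted synthetic
truth into precision/recall/F1 numbers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .imaging_io import Detection, ImageMetadata, um_to_px

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# confusion statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionStats:
    """Binary confusion counts plus per-class normalized percentages.

    Rates for an absent class are NaN ("undefined"), never 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else math.nan

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else math.nan

    @property
    def fnr(self) -> float:
        pos = self.tp + self.fn
        return 100.0 * self.fn / pos if pos else math.nan

    @property
    def fpr(self) -> float:
        neg = self.tn + self.fp
        return 100.0 * self.fp / neg if neg else math.nan

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n if self.n else math.nan


def confusion_stats(
    labels: Sequence[int] | np.ndarray, predictions: Sequence[int] | np.ndarray
) -> ConfusionStats:
    """Confusion statistics of binary predictions against binary labels."""
    y = np.asarray(labels).astype(bool)
    p = np.asarray(predictions).astype(bool)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("labels and predictions must be equal-length vectors")
    if y.size < 1:
        raise ValueError("need at least one sample")
    return ConfusionStats(
        tp=int(np.sum(y & p)),
        fp=int(np.sum(~y & p)),
        fn=int(np.sum(y & ~p)),
        tn=int(np.sum(~y & ~p)),
    )


# ---------------------------------------------------------------------------
# detection-to-truth matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchResult:
    n_matched: int
    n_false_positive: int
    n_missed: int
    pairing: tuple[tuple[int, int, float], ...]  # (det_idx, truth_idx, dist_px)

    @property
    def precision(self) -> float:
        d = self.n_matched + self.n_false_positive
        return self.n_matched / d if d else math.nan

    @property
    def recall(self) -> float:
        t = self.n_matched + self.n_missed
        return self.n_matched / t if t else math.nan

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if math.isnan(p) or math.isnan(r) or p + r == 0:
            return math.nan
        return 2 * p * r / (p + r)


def match_detections(
    detections: Sequence[Detection] | Sequence[tuple[float, float]],
    truth: Sequence[tuple[float, float]],
    tol_um: float = 4.0,
    meta: ImageMetadata | None = None,
) -> MatchResult:
    """Greedy nearest-first one-to-one matching within ``tol_um``.

    Candidate pairs closer than the tolerance are taken in order of
    (distance, detection y, detection x, truth y, truth x); each
    detection and each truth point matches at most once.  The default
    4 µm tolerance is the maximum nucleus radius of the detection
    radius range.
    """
    if tol_um <= 0:
        raise ValueError("tol_um must be > 0")
    if meta is None:
        meta = ImageMetadata()
    tol_px = um_to_px(tol_um, meta)
    det_xy = [
        (d.x, d.y) if isinstance(d, Detection) else (float(d[0]), float(d[1]))
        for d in detections
    ]
    candidates = []
    for di, (dx, dy) in enumerate(det_xy):
        for ti, (tx, ty) in enumerate(truth):
            dist = math.hypot(dx - tx, dy - ty)
            if dist <= tol_px:
                candidates.append((dist, dy, dx, ty, tx, di, ti))
    candidates.sort()
    used_det: set[int] = set()
    used_truth: set[int] = set()
    pairing: list[tuple[int, int, float]] = []
    for dist, _dy, _dx, _ty, _tx, di, ti in candidates:
        if di in used_det or ti in used_truth:
            continue
        used_det.add(di)
        used_truth.add(ti)
        pairing.append((di, ti, dist))
    n_matched = len(pairing)
    return MatchResult(
        n_matched=n_matched,
        n_false_positive=len(det_xy) - n_matched,
        n_missed=len(truth) - n_matched,
        pairing=tuple(pairing),
    )


# ---------------------------------------------------------------------------
# relative count differences
# ---------------------------------------------------------------------------


@dataclass
class RelativeDifferenceTable:
    """Per-image, per-rater relative differences and per-rater summaries.

    ``differences``: image × rater DataFrame of (mean − count)/mean;
    ``summary``: per-rater mean / median / q25 / q75 / mean_abs;
    ``excluded_images``: image ids dropped because their mean count was
    zero (a zero mean makes the statistic undefined).
    """

    differences: pd.DataFrame
    summary: pd.DataFrame
    excluded_images: list[str] = field(default_factory=list)

    def iqr(self, rater: str) -> tuple[float, float]:
        row = self.summary.loc[rater]
        return float(row["q25"]), float(row["q75"])


def relative_differences(
    table: pd.DataFrame,
    mean_columns: Sequence[str] | None = None,
    sign: int = 1,
) -> RelativeDifferenceTable:
    """Relative count differences to the cross-rater mean.

    For each image, ``diff(rater) = sign · (mean − count(rater)) / mean``
    where ``mean`` is taken over ``mean_columns`` (default: all columns,
    i.e. observers *and* the model together).  With the default column
    set the differences of each image sum to zero across raters.
    Images whose mean count is zero are excluded with a warning.

    Summaries per rater use the mean, median and linear-interpolation
    (type-7) 25th/75th percentiles; ``mean_abs`` is the mean absolute
    difference, the headline human-agreement number for a model column.
    """
    if table.shape[0] < 1 or table.shape[1] < 1:
        raise ValueError("count table must have ≥ 1 image and ≥ 1 rater")
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    cols = list(table.columns) if mean_columns is None else list(mean_columns)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"mean_columns not in table: {missing}")
    means = table[cols].mean(axis=1)
    zero = means == 0
    excluded = [str(i) for i in table.index[zero]]
    if excluded:
        logger.warning(
            "excluding %d image(s) with zero mean count: %s", len(excluded), excluded
        )
    kept = table.loc[~zero]
    m = means[~zero]
    diffs = sign * kept.rsub(m, axis=0).div(m, axis=0)
    summary = pd.DataFrame(
        {
            "mean": diffs.mean(axis=0),
            "median": diffs.median(axis=0),
            "q25": diffs.quantile(0.25, interpolation="linear"),
            "q75": diffs.quantile(0.75, interpolation="linear"),
            "mean_abs": diffs.abs().mean(axis=0),
        }
    )
    return RelativeDifferenceTable(
        differences=diffs, summary=summary, excluded_images=excluded
    )


def count_agreement_report(
    table: pd.DataFrame, model_column: str = "model"
) -> dict[str, float]:
    """Headline agreement numbers for a count table containing a model column.

    Reports the model's signed mean and mean absolute relative
    difference (both are quoted in practice and they differ whenever the
    model is not unbiased) plus its IQR bounds.
    """
    rd = relative_differences(table)
    if model_column not in rd.summary.index:
        raise ValueError(f"no column {model_column!r} in the count table")
    row = rd.summary.loc[model_column]
    return {
        "model_mean_diff": float(row["mean"]),
        "model_mean_abs_diff": float(row["mean_abs"]),
        "model_q25": float(row["q25"]),
        "model_q75": float(row["q75"]),
    }


__all__ = [
    "ConfusionStats",
    "confusion_stats",
    "MatchResult",
    "match_detections",
    "RelativeDifferenceTable",
    "relative_differences",
    "count_agreement_report",
]
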