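"""Confusion-matrix metrics, accessibility correlations, and cross-dataset summaries.

Each residue class is evaluated one-vs-rest on the three-class truth:
the class of interest supplies the positive samples and everything else the
negatives.  Cross-dataset summaries are unweighted arithmetic means of the
per-dataset values; rounding happens only at presentation time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from mutsense.classify import PredictionTable
from mutsense.dms_io import RESIDUE_CLASSES, ResidueTruth
from mutsense.errors import DegenerateDataError, InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred: PredictionTable, truth: ResidueTruth, positive_class: str) -> ConfusionCounts:
    """One-vs-rest confusion counts over positions carrying both a prediction
    and a truth label.

    For the buried class, truth-level exclusions are dropped from the
    evaluation entirely (they are special-cased out of the buried call too).
    """
    if positive_class not in RESIDUE_CLASSES:
        raise ValueError(f"unknown class {positive_class!r}")
    pred_map = pred.as_dict()
    truth_map = truth.as_dict()
    common = sorted(set(pred_map) & set(truth_map))
    skipped = sorted(set(truth_map) - set(pred_map))
    if skipped:
        logger.info("%d labeled position(s) without a prediction excluded: %s", len(skipped), skipped)
    if positive_class == "buried" and truth.exclusions:
        common = [p for p in common if p not in truth.exclusions]
    if not common:
        raise InsufficientDataError("no position has both a prediction and a truth label")
    tp = fp = tn = fn = 0
    for pos in common:
        actual = truth_map[pos] == positive_class
        called = pred_map[pos] == positive_class
        if actual and called:
            tp += 1
        elif actual:
            fn += 1
        elif called:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, accuracy and MCC from one confusion matrix.

    Any zero factor in the MCC denominator yields mcc = 0; sensitivity and
    specificity with an empty positive/negative class are likewise 0.
    """
    if c.total <= 0:
        raise InsufficientDataError("empty confusion matrix")
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    specificity = tn / (tn + fp) if (tn + fp) else 0.0
    accuracy = (tp + tn) / c.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return {"sensitivity": sensitivity, "specificity": specificity, "accuracy": accuracy, "mcc": mcc}


def pearson(x, y) -> float:
    """Product-moment correlation between two equal-length sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise InsufficientDataError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateDataError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def summarize_datasets(rows: pd.DataFrame | list[dict]) -> pd.Series:
    """Unweighted per-column mean across datasets (numeric columns only)."""
    df = pd.DataFrame(rows)
    if df.empty:
        raise InsufficientDataError("no dataset rows to summarize")
    return df.mean(numeric_only=True)


def evaluate_all_classes(pred: PredictionTable, truth: ResidueTruth) -> pd.DataFrame:
    """Metrics for all three classes of one dataset, one row per class."""
    out = []
    for cls in RESIDUE_CLASSES:
        m = metrics(confusion(pred, truth, cls))
        out.append({"class": cls, **m})
    return pd.DataFrame(out)


def write_report(rows: pd.DataFrame, path: str | Path, percent: bool = True) -> None:
    """Write a per-dataset metrics table plus an unweighted-mean summary row.

    Rates are printed as percentages to 1 dp and MCC to 2 dp, mirroring the
    conventional benchmark-table layout.
    """
    df = rows.copy()
    summary = summarize_datasets(df)
    label_col = next((c for c in df.columns if df[c].dtype == object), None)
    summary_row = {c: summary.get(c, "") for c in df.columns}
    if label_col is not None:
        summary_row[label_col] = "mean"
    df = pd.concat([df, pd.DataFrame([summary_row])], ignore_index=True)
    for col in df.columns:
        if col in ("sensitivity", "specificity", "accuracy"):
            df[col] = df[col].map(lambda v: f"{100 * v:.1f}" if percent else f"{v:.4f}")
        elif col == "mcc":
            df[col] = df[col].map(lambda v: f"{v:.2f}")
    df.to_csv(path, sep="\t", index=False)
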