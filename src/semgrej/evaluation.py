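"""Open-set evaluation: binary rates, (M+1)-way confusion, ROC/AUC.

Conventions: in the binary target-vs-unrelated problem the *positive*
event is "a target sample is accepted", so TPR is the fraction of target
samples accepted and FPR the fraction of unrelated samples accepted.
Rates with a zero denominator are reported as NaN ("undefined"), never as
a silent zero, so they can be excluded from averages.  Per-class
summaries are macro-averaged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .rejector import Decision

REJECT = "reject"
UNRELATED_ROW = "unrelated"


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class BinaryCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise EvaluationError("all counts are zero")


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def _nanmean(values) -> float:
    arr = np.asarray(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    return float(finite.mean()) if finite.size else math.nan


def binary_metrics(counts: BinaryCounts, as_percent: bool = False) -> dict[str, float]:
    """Accuracy, precision, recall (TPR), FPR and F-score from the four counts.

    Undefined rates (zero denominator) come back as NaN.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        fscore = math.nan
    else:
        fscore = 2.0 * precision * recall / (precision + recall)
    out = {
        "accuracy": _ratio(tp + tn, tp + fp + tn + fn),
        "precision": precision,
        "recall": recall,
        "fpr": _ratio(fp, fp + tn),
        "fscore": fscore,
    }
    if as_percent:
        out = {k: v * 100.0 for k, v in out.items()}
    return out


@dataclass
class OpenSetReport:
    """Confusion over {target classes..., unrelated} x {target classes..., reject}."""

    confusion: pd.DataFrame
    per_class: pd.DataFrame  # precision / recall / fscore per target class
    mean_target_accuracy: float  # macro over target rows
    sample_target_accuracy: float  # micro over target samples
    rejection_rate: float  # unrelated row, reject column
    overall_accuracy: float  # correct-label targets + rejected unrelated, over all
    macro_fscore: float
    roc_points: pd.DataFrame | None = None
    auc: float | None = None

    def to_json(self) -> str:
        doc = {
            "confusion": {
                "rows": list(self.confusion.index),
                "columns": list(self.confusion.columns),
                "matrix": self.confusion.to_numpy().tolist(),
            },
            "per_class": self.per_class.to_dict(orient="index"),
            "mean_target_accuracy": self.mean_target_accuracy,
            "sample_target_accuracy": self.sample_target_accuracy,
            "rejection_rate": self.rejection_rate,
            "overall_accuracy": self.overall_accuracy,
            "macro_fscore": self.macro_fscore,
            "auc": self.auc,
        }

        def _clean(o):
            if isinstance(o, float) and math.isnan(o):
                return None
            if isinstance(o, dict):
                return {k: _clean(v) for k, v in o.items()}
            if isinstance(o, list):
                return [_clean(v) for v in o]
            return o

        return json.dumps(_clean(doc), indent=2)

    def to_text(self) -> str:
        """Aligned table in the style of a per-movement results summary."""
        lines = ["Open-set evaluation", "=" * 19, "", "Confusion (rows = truth, cols = prediction):"]
        lines.append(self.confusion.to_string())
        lines.append("")
        lines.append("Per-class metrics:")
        lines.append(self.per_class.to_string(float_format=lambda v: f"{v:7.3f}"))
        lines.append("")
        lines.append(f"Mean target accuracy (macro): {self.mean_target_accuracy:.3f}")
        lines.append(f"Target accuracy (per-sample): {self.sample_target_accuracy:.3f}")
        lines.append(f"Unrelated rejection rate:     {self.rejection_rate:.3f}")
        n_def = int(self.per_class["fscore"].notna().sum())
        lines.append(
            f"Macro F-score:                {self.macro_fscore:.3f} "
            f"(over {n_def}/{len(self.per_class)} classes with defined F)"
        )
        if self.auc is not None:
            lines.append(f"Open-set ROC AUC:             {self.auc:.3f}")
        return "\n".join(lines)

    def write(self, json_path: str | Path, text_path: str | Path | None = None) -> None:
        Path(json_path).write_text(self.to_json() + "\n")
        if text_path is not None:
            Path(text_path).write_text(self.to_text() + "\n")


def open_set_confusion(
    truths: Sequence[tuple[str, bool]],
    decisions: Sequence[Decision],
    class_names: Sequence[str] | None = None,
) -> OpenSetReport:
    """Build the (M+1)x(M+1) confusion and all per-class metrics.

    ``truths`` pairs each sample's true label with an is-unrelated flag;
    all unrelated truths share one row.  Rejections land in the reject
    column regardless of the CNN's internal class guess.
    """
    if len(truths) != len(decisions):
        raise EvaluationError(f"{len(truths)} truths vs {len(decisions)} decisions")
    if class_names is None:
        class_names = sorted({label for label, unrel in truths if not unrel})
    rows = list(class_names) + [UNRELATED_ROW]
    cols = list(class_names) + [REJECT]
    mat = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for (label, unrel), dec in zip(truths, decisions):
        row = UNRELATED_ROW if unrel else label
        col = REJECT if not dec.accepted else dec.label
        if col not in mat.columns:
            raise EvaluationError(f"decision label {col!r} is not a known class")
        mat.loc[row, col] += 1

    # per-target-class one-vs-rest counts over all decisions
    per_class = {}
    diag_acc = []
    for cname in class_names:
        tp = int(mat.loc[cname, cname])
        fp = int(mat[cname].sum() - tp)
        fn = int(mat.loc[cname].sum() - tp)
        tn = int(mat.to_numpy().sum() - tp - fp - fn)
        m = binary_metrics(BinaryCounts(tp, fp, tn, fn))
        per_class[cname] = {k: m[k] for k in ("precision", "recall", "fscore")}
        row_total = mat.loc[cname].sum()
        diag_acc.append(_ratio(tp, row_total))

    target_rows = mat.loc[class_names]
    n_target = int(target_rows.to_numpy().sum())
    n_unrel = int(mat.loc[UNRELATED_ROW].sum())
    target_correct = int(np.trace(target_rows[class_names].to_numpy()))
    rejected_unrel = int(mat.loc[UNRELATED_ROW, REJECT])

    per_class_df = pd.DataFrame(per_class).T
    macro_f = _nanmean(per_class_df["fscore"]) if len(per_class_df) else math.nan
    return OpenSetReport(
        confusion=mat,
        per_class=per_class_df,
        mean_target_accuracy=_nanmean(diag_acc) if diag_acc else math.nan,
        sample_target_accuracy=_ratio(target_correct, n_target),
        rejection_rate=_ratio(rejected_unrel, n_unrel),
        overall_accuracy=_ratio(target_correct + rejected_unrel, n_target + n_unrel),
        macro_fscore=macro_f,
    )


def roc_auc(
    scores: Sequence[float],
    is_unrelated: Sequence[bool],
) -> tuple[pd.DataFrame, float]:
    """ROC of the reconstruction error as a target-vs-unrelated score.

    Sweeps every distinct error threshold (ties grouped into one step);
    positive = "target sample accepted", i.e. its error at or below the
    threshold.  AUC by the trapezoidal rule.
    """
    scores = np.asarray(scores, dtype=float)
    unrel = np.asarray(is_unrelated, dtype=bool)
    if scores.shape != unrel.shape:
        raise EvaluationError("scores and flags must have equal length")
    if unrel.all() or (~unrel).all():
        raise EvaluationError("ROC needs both target and unrelated samples")
    # low error should mean target, so score the *negated* error for the
    # standard higher-is-positive sweep
    fpr, tpr, thr = _roc_curve(~unrel, -scores, drop_intermediate=False)
    points = pd.DataFrame({"threshold": -thr, "fpr": fpr, "tpr": tpr})
    return points, float(_trapezoid_auc(fpr, tpr))
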