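"""Contingency counts and classification performance measures.

Wear is the positive class throughout: TP = truly worn and classified
worn, TN = truly off and classified off. Recall measures recovery of wear
time; specificity measures rejection of non-wear; precision measures how
much classified wear time is real; accuracy is overall agreement.
Undefined ratios (zero denominators, e.g. specificity on an all-wear day)
are reported as NaN markers and excluded from corpus summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .records import LabelSeries, ValidationError

logger = logging.getLogger(__name__)

#: Marker for a metric whose denominator is zero.
UNDEFINED = math.nan


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def N(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class MetricsReport:
    recall: float
    specificity: float
    precision: float
    accuracy: float

    def as_dict(self) -> dict:
        return {
            "recall": self.recall,
            "specificity": self.specificity,
            "precision": self.precision,
            "accuracy": self.accuracy,
        }


def confusion(truth: LabelSeries, estimated: LabelSeries) -> ConfusionCounts:
    """Epoch-level contingency counts of estimated against true wear labels."""
    if len(truth) != len(estimated):
        raise ValidationError(
            f"misaligned labels: {len(truth)} vs {len(estimated)} epochs"
        )
    t = truth.as_bool()
    e = estimated.as_bool()
    return ConfusionCounts(
        TP=int(np.count_nonzero(t & e)),
        FP=int(np.count_nonzero(~t & e)),
        FN=int(np.count_nonzero(t & ~e)),
        TN=int(np.count_nonzero(~t & ~e)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den else UNDEFINED


def compute_metrics(c: ConfusionCounts, printed_accuracy_variant: bool = False) -> MetricsReport:
    """Recall, specificity, precision and accuracy from contingency counts.

    ``printed_accuracy_variant=True`` swaps standard accuracy (TP+TN)/N for
    the predicted-positive rate (TP+FP)/N, kept available for forensic
    comparison with reports that use that formula under the name accuracy.
    """
    acc_num = c.TP + c.FP if printed_accuracy_variant else c.TP + c.TN
    return MetricsReport(
        recall=_ratio(c.TP, c.TP + c.FN),
        specificity=_ratio(c.TN, c.TN + c.FP),
        precision=_ratio(c.TP, c.TP + c.FP),
        accuracy=_ratio(acc_num, c.N),
    )


def evaluate(truth: LabelSeries, estimated: LabelSeries, **kw) -> MetricsReport:
    """Convenience: confusion + compute_metrics in one call."""
    return compute_metrics(confusion(truth, estimated), **kw)


def summarize_corpus(reports) -> dict:
    """Per-metric {median, min, max, n_defined} over a corpus of reports.

    Undefined (NaN) values are excluded with a logged count; a metric
    undefined everywhere yields NaN summaries with ``n_defined`` 0.
    """
    reports = list(reports)
    if not reports:
        raise ValidationError("need at least one report to summarize")
    out: dict[str, dict] = {}
    for name in ("recall", "specificity", "precision", "accuracy"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        defined = vals[~np.isnan(vals)]
        n_excluded = vals.size - defined.size
        if n_excluded:
            logger.info("%s: excluded %d undefined values from summary", name, n_excluded)
        if defined.size:
            out[name] = {
                "median": float(np.median(defined)),
                "min": float(defined.min()),
                "max": float(defined.max()),
                "n_defined": int(defined.size),
            }
        else:
            out[name] = {"median": UNDEFINED, "min": UNDEFINED, "max": UNDEFINED,
                         "n_defined": 0}
    return out
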