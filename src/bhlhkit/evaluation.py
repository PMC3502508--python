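"""Confusion matrices and one-vs-all classification metrics.

Predictions may include UNCLASSIFIED (e.g. gap-containing sequences under
CVA, or decision-tree fallthrough), so the confusion matrix has a fourth
prediction column.  Because an unclassified call can be scored either as an
error or excluded, both accuracy conventions are reported explicitly:
``overall`` counts unclassified as incorrect; ``among_classified`` restricts
to sequences the model actually assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import KINGDOMS, UNCLASSIFIED


def confusion(y_true, y_pred, classes: tuple[str, ...] = KINGDOMS) -> pd.DataFrame:
    """Counts by (true class, predicted class or UNCLASSIFIED)."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) != len(y_pred):
        raise ValueError("truth and prediction vectors differ in length")
    bad = sorted({str(t) for t in y_true} - set(classes))
    if bad:
        raise ValueError(f"truth labels outside {classes}: {bad}")
    cols = list(classes) + [UNCLASSIFIED]
    cm = pd.DataFrame(0, index=list(classes), columns=cols, dtype=int)
    for t, p in zip(y_true, y_pred):
        p = p if p in classes else UNCLASSIFIED
        cm.at[t, p] += 1
    return cm


@dataclass
class MetricsReport:
    """One-vs-all metrics; rates are NaN where the denominator is zero."""

    sensitivity: pd.Series
    specificity: pd.Series
    recall_among_classified: pd.Series
    accuracy_overall: float
    accuracy_among_classified: float
    n_unclassified: int
    n_total: int

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity.to_dict(),
            "specificity": self.specificity.to_dict(),
            "recall_among_classified": self.recall_among_classified.to_dict(),
            "accuracy_overall": self.accuracy_overall,
            "accuracy_among_classified": self.accuracy_among_classified,
            "n_unclassified": self.n_unclassified,
            "n_total": self.n_total,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        return cls(
            sensitivity=pd.Series(d["sensitivity"], dtype=float),
            specificity=pd.Series(d["specificity"], dtype=float),
            recall_among_classified=pd.Series(d["recall_among_classified"], dtype=float),
            accuracy_overall=d["accuracy_overall"],
            accuracy_among_classified=d["accuracy_among_classified"],
            n_unclassified=d["n_unclassified"],
            n_total=d["n_total"],
        )


def _rate(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(cm: pd.DataFrame) -> MetricsReport:
    """One-vs-all sensitivity/specificity plus both accuracy conventions.

    UNCLASSIFIED counts as a negative prediction for every class, so an
    unclassified positive is a false negative and an unclassified negative
    a true negative.
    """
    classes = list(cm.index)
    total = int(cm.to_numpy().sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    sens, spec, recall_cls = {}, {}, {}
    for g in classes:
        tp = int(cm.at[g, g])
        fn = int(cm.loc[g].sum()) - tp
        fp = int(cm[g].sum()) - tp
        tn = total - tp - fn - fp
        sens[g] = _rate(tp, tp + fn)
        spec[g] = _rate(tn, tn + fp)
        classified_g = int(cm.loc[g, classes].sum())
        recall_cls[g] = _rate(tp, classified_g)
    diag = sum(int(cm.at[g, g]) for g in classes)
    n_unclassified = int(cm[UNCLASSIFIED].sum()) if UNCLASSIFIED in cm.columns else 0
    return MetricsReport(
        sensitivity=pd.Series(sens),
        specificity=pd.Series(spec),
        recall_among_classified=pd.Series(recall_cls),
        accuracy_overall=_rate(diag, total),
        accuracy_among_classified=_rate(diag, total - n_unclassified),
        n_unclassified=n_unclassified,
        n_total=total,
    )


def evaluate(y_true, y_pred, classes: tuple[str, ...] = KINGDOMS) -> MetricsReport:
    return metrics(confusion(y_true, y_pred, classes))
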