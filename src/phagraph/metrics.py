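"""Macro-averaged evaluation with an explicit rejection convention.

Each class is scored one-vs-rest.  A contig reported as
``unclassified`` counts as a false negative for its true class and as a
true negative for every other class; a class that is never predicted
gets precision 0.  Macro metrics average the per-class values with
equal weight, so rare families count as much as common ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = ["ClassCounts", "EvalReport", "evaluate", "UNCLASSIFIED"]

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClassCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.tn) / total if total else 0.0

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0


@dataclass
class EvalReport:
    per_class: dict[str, ClassCounts]
    macro_accuracy: float
    macro_precision: float
    macro_recall: float

    @property
    def n_class(self) -> int:
        return len(self.per_class)

    def as_dict(self) -> dict:
        return {
            "macro_accuracy": self.macro_accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "n_class": self.n_class,
            "per_class": {
                k: {"tp": v.tp, "fp": v.fp, "fn": v.fn, "tn": v.tn}
                for k, v in self.per_class.items()
            },
        }


def evaluate(
    predictions: Mapping[str, str],
    truth: Mapping[str, str],
    classes: Sequence[str] | None = None,
) -> EvalReport:
    """Macro accuracy/precision/recall of predictions against the truth.

    ``predictions`` maps every truth id to a class name or
    ``"unclassified"``; ``classes`` defaults to the classes present in
    the truth.  Predictions with a class outside the class list raise.
    """
    if classes is None:
        classes = sorted(set(truth.values()))
    class_set = set(classes)
    missing = sorted(set(truth) - set(predictions))
    if missing:
        raise ValueError(f"truth ids without predictions: {missing[:5]}")
    for sid in truth:
        p = predictions[sid]
        if p != UNCLASSIFIED and p not in class_set:
            raise ValueError(f"prediction {p!r} for {sid!r} not in class list")

    per_class: dict[str, ClassCounts] = {}
    for cls in classes:
        tp = fp = fn = tn = 0
        for sid, t in truth.items():
            p = predictions[sid]
            if t == cls:
                if p == cls:
                    tp += 1
                else:  # wrong class or unclassified -> FN
                    fn += 1
            else:
                if p == cls:
                    fp += 1
                else:  # other class or unclassified -> TN
                    tn += 1
        per_class[cls] = ClassCounts(tp, fp, fn, tn)

    n = len(classes)
    return EvalReport(
        per_class=per_class,
        macro_accuracy=sum(c.accuracy for c in per_class.values()) / n,
        macro_precision=sum(c.precision for c in per_class.values()) / n,
        macro_recall=sum(c.recall for c in per_class.values()) / n,
    )
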