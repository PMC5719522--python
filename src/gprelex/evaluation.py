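"""Instance-level precision / recall / F-measure scoring.

Precision is the percentage of predicted relationships that are correct,
recall the percentage of gold relationships found, and the F-measure their
harmonic mean; all three are reported on the 0-100 scale.  Degenerate 0/0
ratios are defined as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from gprelex.corpus_io import RelationInstance


@dataclass(frozen=True)
class Metrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f_measure: float

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "precision": round(self.precision, 2),
            "recall": round(self.recall, 2),
            "f_measure": round(self.f_measure, 2),
        }


def f_measure(p: float, r: float) -> float:
    """Harmonic mean of a precision and a recall on the 0-100 scale."""
    for name, value in (("precision", p), ("recall", r)):
        if not (0.0 <= value <= 100.0):
            raise ValueError(f"{name} {value} outside [0, 100]")
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> Metrics:
    if tp + fp == 0 or tp + fn == 0:
        warnings.warn("degenerate 0/0 ratio in precision or recall; reporting 0")
    precision = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    recall = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    return Metrics(tp, fp, fn, tn, precision, recall, f_measure(precision, recall))


def score(
    predicted: Sequence[RelationInstance], gold: Sequence[RelationInstance]
) -> Metrics:
    """Confusion counts over instances aligned by (sentence, geno, pheno) key."""
    gold_by_key = {}
    for inst in gold:
        gold_by_key[inst.key] = inst.label
    tp = fp = fn = tn = 0
    seen = set()
    for inst in predicted:
        if inst.key not in gold_by_key:
            raise ValueError(f"predicted instance {inst.key} absent from gold")
        if inst.key in seen:
            raise ValueError(f"duplicate predicted instance {inst.key}")
        seen.add(inst.key)
        g = gold_by_key[inst.key]
        if inst.label == "positive":
            tp += g == "positive"
            fp += g == "negative"
        else:
            fn += g == "positive"
            tn += g == "negative"
    # gold instances never predicted count as misses of their gold class
    for key, g in gold_by_key.items():
        if key not in seen:
            fn += g == "positive"
            tn += g == "negative"
    return metrics_from_counts(tp, fp, fn, tn)
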