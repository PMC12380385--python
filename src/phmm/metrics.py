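"""Multi-class latent-state-calling evaluation.

Six criteria computed from one-vs-rest confusion counts per class:
macro-averaged accuracy and error rate, micro-precision (= micro-recall
= micro F-score when every item gets exactly one label), macro precision
and recall, and an F-score defined as P*R/(P+R) — half the conventional
harmonic mean; the conventional 2PR/(P+R) is available via
``f_score="harmonic"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
import warnings

import numpy as np

__all__ = ["ConfusionTable", "confusion_counts", "classification_metrics",
           "align_labels"]


@dataclass
class ConfusionTable:
    """Per-class one-vs-rest counts; labels are 1..C."""

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    def __post_init__(self) -> None:
        for f in ("tp", "tn", "fp", "fn"):
            setattr(self, f, np.asarray(getattr(self, f), dtype=np.int64))
        totals = self.tp + self.tn + self.fp + self.fn
        if len(set(totals.tolist())) > 1:
            raise ValueError("per-class totals must be identical")

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    @property
    def total(self) -> int:
        return int(self.tp[0] + self.tn[0] + self.fp[0] + self.fn[0])


def confusion_counts(truth, predicted, n_classes: int) -> ConfusionTable:
    """One-vs-rest confusion counts for 1-based labels."""
    truth = np.asarray(truth, dtype=int).ravel()
    predicted = np.asarray(predicted, dtype=int).ravel()
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    for name, arr in (("truth", truth), ("predicted", predicted)):
        if arr.size and (arr.min() < 1 or arr.max() > n_classes):
            raise ValueError(f"{name} labels must lie in 1..{n_classes}")
    n = truth.size
    tp = np.empty(n_classes, dtype=np.int64)
    fp = np.empty(n_classes, dtype=np.int64)
    fn = np.empty(n_classes, dtype=np.int64)
    for z in range(1, n_classes + 1):
        t, p = truth == z, predicted == z
        tp[z - 1] = int((t & p).sum())
        fp[z - 1] = int((~t & p).sum())
        fn[z - 1] = int((t & ~p).sum())
    tn = n - tp - fp - fn
    return ConfusionTable(tp=tp, tn=tn, fp=fp, fn=fn)


def classification_metrics(ct: ConfusionTable,
                           f_score: str = "halved") -> dict:
    """The six state-calling criteria from a confusion table.

    Zero per-class denominators contribute 0 to the macro averages with a
    warning. ``f_score="halved"`` uses P*R/(P+R); ``"harmonic"`` the
    conventional 2PR/(P+R).
    """
    if ct.total <= 0:
        raise ValueError("empty confusion table")
    if f_score not in ("halved", "harmonic"):
        raise ValueError("f_score must be 'halved' or 'harmonic'")
    C = ct.n_classes
    tp, tn, fp, fn = (x.astype(float) for x in (ct.tp, ct.tn, ct.fp, ct.fn))
    total = tp + tn + fp + fn

    accuracy = float(((tp + tn) / total).mean())
    error_rate = float(((fp + fn) / total).mean())

    denom_micro = (tp + fp).sum()
    micro_precision = float(tp.sum() / denom_micro) if denom_micro > 0 else 0.0

    def macro(num, den, label):
        vals = np.zeros(C)
        ok = den > 0
        if not ok.all():
            warnings.warn(f"zero denominator in per-class {label}; "
                          "affected terms set to 0", RuntimeWarning)
        vals[ok] = num[ok] / den[ok]
        return float(vals.mean())

    precision = macro(tp, tp + fp, "precision")
    recall = macro(tp, tp + fn, "recall")
    if precision + recall > 0:
        f = precision * recall / (precision + recall)
        if f_score == "harmonic":
            f *= 2.0
    else:
        f = 0.0
    return {"accuracy": accuracy, "error_rate": error_rate,
            "micro_precision": micro_precision, "precision": precision,
            "recall": recall, "f_score": float(f)}


def align_labels(truth, predicted, n_classes: int) -> np.ndarray:
    """Relabel predictions by the permutation maximizing agreement.

    Latent labels are arbitrary, so predictions are aligned to the truth
    over all C! permutations before scoring. Returns the relabelled
    prediction array (1-based).
    """
    truth = np.asarray(truth, dtype=int).ravel()
    predicted = np.asarray(predicted, dtype=int).ravel()
    tab = np.zeros((n_classes, n_classes))
    np.add.at(tab, (predicted - 1, truth - 1), 1.0)
    best, best_perm = -1.0, None
    for perm in permutations(range(n_classes)):
        score = sum(tab[i, perm[i]] for i in range(n_classes))
        if score > best:
            best, best_perm = score, perm
    mapping = np.asarray(best_perm)
    return mapping[predicted - 1] + 1
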