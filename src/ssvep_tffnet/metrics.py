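"""Classification accuracy and information transfer rate (ITR).

ITR follows the Wolpaw formula: with G selectable targets, accuracy P
and a decision every T seconds, the bits conveyed per selection are

    B = log2(G) + P log2(P) + (1 - P) log2((1 - P) / (G - 1))

and ITR = B * 60 / T bits per minute. The formula is negative below
chance (P < 1/G); such values are clamped to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["accuracy", "itr", "FoldResult", "SummaryReport", "summarize"]


def accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Exact fraction of correct predictions."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    m = labels.size
    if m == 0:
        raise ValueError("cannot compute accuracy of zero samples")
    return float(int((predictions == labels).sum()) / m)


def itr(G: int, P: float, T: float) -> float:
    """Information transfer rate in bits/min; clamped to 0 at or below chance."""
    if G < 2:
        raise ValueError("need at least two targets")
    if not 0.0 <= P <= 1.0:
        raise ValueError(f"accuracy {P} outside [0, 1]")
    if T <= 0:
        raise ValueError("window length must be positive")
    if P <= 1.0 / G:
        return 0.0
    bits = math.log2(G)
    if P > 0.0:
        bits += P * math.log2(P)
    if P < 1.0:
        bits += (1.0 - P) * math.log2((1.0 - P) / (G - 1))
    return bits * 60.0 / T


@dataclass
class FoldResult:
    """Outcome of one leave-one-subject-out fold."""

    held_out_subject: int | str
    window_s: float
    accuracy: float
    itr: float
    n_test_trials: int
    seed: int | None = None
    loss_history: list[float] = field(default_factory=list)


@dataclass
class SummaryReport:
    """Across-subject mean +/- sample SD, in the conventional units."""

    window_s: float
    mean_accuracy_pct: float
    sd_accuracy_pct: float
    mean_itr: float
    sd_itr: float
    n_folds: int
    single_fold: bool
    per_subject: list[FoldResult] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "window_s": self.window_s,
            "mean_accuracy_pct": self.mean_accuracy_pct,
            "sd_accuracy_pct": self.sd_accuracy_pct,
            "mean_itr_bits_per_min": self.mean_itr,
            "sd_itr_bits_per_min": self.sd_itr,
            "n_folds": self.n_folds,
            "single_fold": self.single_fold,
            "per_subject": [
                {"subject": f.held_out_subject, "accuracy": f.accuracy,
                 "itr": f.itr, "n_test_trials": f.n_test_trials}
                for f in self.per_subject
            ],
        }


def summarize(folds: list[FoldResult]) -> SummaryReport:
    """Across-subject summary; mean ITR is the mean of per-fold ITRs.

    The SD uses the sample (n-1) denominator; a single fold reports
    SD = 0 with the ``single_fold`` flag set.
    """
    if not folds:
        raise ValueError("no folds to summarize")
    accs = np.array([f.accuracy for f in folds]) * 100.0
    itrs = np.array([f.itr for f in folds])
    single = len(folds) == 1
    sd_acc = 0.0 if single else float(accs.std(ddof=1))
    sd_itr = 0.0 if single else float(itrs.std(ddof=1))
    return SummaryReport(
        window_s=folds[0].window_s,
        mean_accuracy_pct=float(accs.mean()),
        sd_accuracy_pct=sd_acc,
        mean_itr=float(itrs.mean()),
        sd_itr=sd_itr,
        n_folds=len(folds),
        single_fold=single,
        per_subject=list(folds),
    )
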