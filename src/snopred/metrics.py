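"""Binary-classification metrics: Sn, Sp, Acc, MCC from confusion counts.

Degenerate ratios (0/0) are defined as 0 with a logged warning, so an
all-one-class prediction yields Sp = 0 and MCC = 0 rather than NaN.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion counts and the four derived performance measures."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sn(self) -> float:
        """Sensitivity tp / (tp + fn)."""
        return _ratio(self.tp, self.tp + self.fn, "Sn")

    @property
    def sp(self) -> float:
        """Specificity tn / (tn + fp)."""
        return _ratio(self.tn, self.tn + self.fp, "Sp")

    @property
    def acc(self) -> float:
        return _ratio(self.tp + self.tn, self.total, "Acc")

    @property
    def mcc(self) -> float:
        """Matthews correlation coefficient; 0 when the denominator is 0."""
        denom = math.sqrt(
            float(self.tp + self.fp) * (self.tp + self.fn) * (self.tn + self.fp) * (self.tn + self.fn)
        )
        if denom == 0.0:
            warnings.warn("MCC denominator is 0; defining MCC = 0")
            return 0.0
        return (self.tp * self.tn - self.fp * self.fn) / denom

    def __add__(self, other: "EvalMetrics") -> "EvalMetrics":
        return EvalMetrics(self.tp + other.tp, self.fp + other.fp,
                           self.tn + other.tn, self.fn + other.fn)

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "sn": self.sn, "sp": self.sp, "acc": self.acc, "mcc": self.mcc}


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} denominator is 0; defining {name} = 0")
        return 0.0
    return num / den


def compute_metrics(y_true, y_pred) -> EvalMetrics:
    """Confusion counts and Sn/Sp/Acc/MCC for binary label vectors."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ValueError("empty inputs")
    return EvalMetrics(
        tp=int(((t == 1) & (p == 1)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )
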