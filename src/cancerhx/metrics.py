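"""Performance and inter-annotator agreement statistics.

Report classification is evaluated as a binary task per question against a
reference standard (the 2-of-3 majority vote of three annotators):
accuracy, precision, recall and F-measure from the 2x2 confusion table,
with Wilson score intervals for the proportions.  Annotator agreement is
summarised by observed agreement, positive/negative specific agreement
(2a/(2a+b+c) and 2d/(2d+b+c)), and Cohen's kappa.  With two categories,
weighted kappa coincides with unweighted Cohen's kappa, so the plain
(po - pe)/(1 - pe) form is implemented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "AgreementStats",
    "ConfusionCounts",
    "accuracy",
    "confusion",
    "f_measure",
    "majority_vote",
    "pairwise_agreement",
    "precision",
    "recall",
    "round3",
    "wilson_interval",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class AgreementStats:
    observed: float
    pos_specific: float
    neg_specific: float
    kappa: float

    def __post_init__(self):
        for name in ("observed", "pos_specific", "neg_specific"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not -1.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [-1, 1]")


def _check_aligned(a: Sequence[bool], b: Sequence[bool]) -> None:
    if len(a) != len(b):
        raise ValueError(f"sequence length mismatch: {len(a)} != {len(b)}")


def confusion(pred: Sequence[bool], gold: Sequence[bool]) -> ConfusionCounts:
    """Standard 2x2 counts for aligned prediction/reference sequences."""
    _check_aligned(pred, gold)
    tp = sum(1 for p, g in zip(pred, gold) if p and g)
    fp = sum(1 for p, g in zip(pred, gold) if p and not g)
    tn = sum(1 for p, g in zip(pred, gold) if not p and not g)
    fn = sum(1 for p, g in zip(pred, gold) if not p and g)
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, defining result as 0", stacklevel=3)
        return 0.0
    return num / den


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total."""
    return _ratio(c.tp + c.tn, c.total, "accuracy")


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP) — exactness."""
    return _ratio(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN) — completeness."""
    return _ratio(c.tp, c.tp + c.fn, "recall")


def f_measure(c: ConfusionCounts | None = None, p: float | None = None,
              r: float | None = None) -> float:
    """Harmonic mean 2PR/(P+R), from counts or directly from P and R."""
    if c is not None:
        p, r = precision(c), recall(c)
    if p is None or r is None:
        raise ValueError("f_measure needs either counts or both p and r")
    return _ratio(2 * p * r, p + r, "f_measure")


def wilson_interval(count: int, nobs: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def pairwise_agreement(a: Sequence[bool], b: Sequence[bool]) -> AgreementStats:
    """Observed/specific agreement and Cohen's kappa for one annotator pair.

    From the pair's 2x2 table (a_ = both positive, d = both negative,
    b_/c_ = disagreements): observed = (a_+d)/n, positive specific
    agreement = 2a_/(2a_+b_+c_), negative = 2d/(2d+b_+c_), and kappa =
    (po - pe)/(1 - pe) with chance agreement pe from the marginals.  When
    pe = 1 (both annotators constant) kappa is defined as 1 if po = 1 else
    0, with a warning.
    """
    _check_aligned(a, b)
    n = len(a)
    if n == 0:
        raise ValueError("cannot compute agreement on empty sequences")
    both_pos = sum(1 for x, y in zip(a, b) if x and y)
    both_neg = sum(1 for x, y in zip(a, b) if not x and not y)
    a_only = sum(1 for x, y in zip(a, b) if x and not y)
    b_only = sum(1 for x, y in zip(a, b) if not x and y)

    po = (both_pos + both_neg) / n
    pos_specific = _ratio(2 * both_pos, 2 * both_pos + a_only + b_only, "pos_specific")
    neg_specific = _ratio(2 * both_neg, 2 * both_neg + a_only + b_only, "neg_specific")

    p_a_pos = (both_pos + a_only) / n
    p_b_pos = (both_pos + b_only) / n
    pe = p_a_pos * p_b_pos + (1 - p_a_pos) * (1 - p_b_pos)
    if pe == 1.0:
        warnings.warn("degenerate marginals (pe = 1); kappa defined by convention",
                      stacklevel=2)
        kappa = 1.0 if po == 1.0 else 0.0
    else:
        kappa = (po - pe) / (1 - pe)
    return AgreementStats(po, pos_specific, neg_specific, kappa)


def majority_vote(
    a1: Sequence[bool], a2: Sequence[bool], a3: Sequence[bool]
) -> list[bool]:
    """Per-position 2-of-3 majority of three annotators' answers."""
    _check_aligned(a1, a2)
    _check_aligned(a1, a3)
    return [sum((x, y, z)) >= 2 for x, y, z in zip(a1, a2, a3)]


def round3(value: float) -> float:
    """Half-up rounding to 3 decimals, matching tabular presentation."""
    return float(Decimal(repr(value)).quantize(Decimal("0.001"), ROUND_HALF_UP))
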