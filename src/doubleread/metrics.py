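"""Team and reader performance metrics.

All metrics are expressed in percent.  The positive class is *abnormal*:
sensitivity is computed over abnormal gold cases, specificity over normal
ones.  Efficiency divides the count of correct team decisions by the total
number of single judgments elicited, so it penalizes protocols that consult
more readers; it can never exceed accuracy because every case costs at
least one judgment.  Two composites summarize the trade-offs: the harmonic
mean of sensitivity and specificity, and the efficiency-weighted
F2-style mean of accuracy and efficiency,
``5 * acc * eff / (acc + 4 * eff)``.

A metric whose denominator is empty (e.g. sensitivity on a panel with no
abnormal gold cases) is returned as NaN rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .panel import ABNORMAL, NORMAL, ValidationError

#: Metric names in study reporting order.
METRIC_NAMES = (
    "accuracy",
    "sensitivity",
    "specificity",
    "hm_sens_spec",
    "f2_acc_eff",
    "efficiency",
)


@dataclass(frozen=True)
class MetricSet:
    """The six performance numbers for one team under one protocol (%)."""

    accuracy: float
    sensitivity: float
    specificity: float
    efficiency: float
    hm_sens_spec: float
    f2_acc_eff: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion_metrics(decisions, gold) -> tuple[float, float, float]:
    """Accuracy, sensitivity, specificity (%) of decisions against gold.

    A class absent from gold leaves the corresponding rate NaN.
    """
    decisions = np.asarray(decisions)
    gold = np.asarray(gold)
    if decisions.shape != gold.shape or decisions.size == 0:
        raise ValidationError("decisions and gold must be equal-length, nonempty")
    correct = decisions == gold
    pos = gold == ABNORMAL
    neg = gold == NORMAL
    accuracy = 100.0 * correct.mean()
    sensitivity = 100.0 * correct[pos].mean() if pos.any() else float("nan")
    specificity = 100.0 * correct[neg].mean() if neg.any() else float("nan")
    return float(accuracy), float(sensitivity), float(specificity)


def efficiency(n_correct: int, total_judgments: int) -> float:
    """Correct decisions per single judgment elicited, in percent."""
    if total_judgments <= 0:
        raise ValidationError("total_judgments must be positive")
    if n_correct < 0 or n_correct > total_judgments:
        raise ValidationError("n_correct must lie in [0, total_judgments]")
    return 100.0 * n_correct / total_judgments


def harmonic_mean_1(sens: float, spec: float) -> float:
    """Plain harmonic mean 2ab/(a+b); 0 if either rate is 0."""
    if sens < 0 or spec < 0:
        raise ValidationError("rates must be nonnegative")
    if sens == 0 or spec == 0:
        return 0.0
    return 2.0 * sens * spec / (sens + spec)


def f2_acc_eff(acc: float, eff: float) -> float:
    """Order-2 harmonic mean 5*acc*eff/(acc + 4*eff), weighting efficiency
    four times as much as accuracy; 0 at the origin limit."""
    if acc < 0 or eff < 0:
        raise ValidationError("rates must be nonnegative")
    if acc == 0 and eff == 0:
        return 0.0
    if acc == 0 or eff == 0:
        return 0.0
    return 5.0 * acc * eff / (acc + 4.0 * eff)


def metric_set(decisions, judgments, gold) -> MetricSet:
    """Assemble the full six-metric summary from per-case team decisions
    and judgment counts."""
    decisions = np.asarray(decisions)
    judgments = np.asarray(judgments)
    gold = np.asarray(gold)
    acc, sens, spec = confusion_metrics(decisions, gold)
    n_correct = int((decisions == gold).sum())
    eff = efficiency(n_correct, int(judgments.sum()))
    hm = (
        harmonic_mean_1(sens, spec)
        if np.isfinite(sens) and np.isfinite(spec)
        else float("nan")
    )
    return MetricSet(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        efficiency=eff,
        hm_sens_spec=hm,
        f2_acc_eff=f2_acc_eff(acc, eff),
    )
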