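"""The eight double-reading interaction protocols.

All protocols operate on an ordered three-reader team reading one case; the
second reader is the machine in every study configuration, but nothing here
depends on reader kind.  Escalation to the third reader (the pseudo-
arbiter) is protocol-specific; when only two readers are involved and they
agree, the team decision is that unanimous call, and whenever a third is
involved the decision is the majority of the three (unless the protocol
says otherwise).  Each protocol also reports how many single judgments it
elicited, the denominator of the efficiency metric.

Scalar entry points (``simple_majority`` etc.) take :class:`Reading`
objects and return a :class:`ProtocolOutcome`; :func:`apply_protocol`
evaluates one protocol for one team across a whole panel on numpy arrays.
Both paths share the same vector kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .panel import ABNORMAL, NORMAL, Panel, Reading, ValidationError

#: Canonical protocol identifiers, in the order the study reports them.
PROTOCOL_NAMES = (
    "majority",
    "acc_weighted",
    "conf_weighted",
    "specific",
    "sensitive",
    "cautious",
    "presumptuous",
    "or_rule",
)

ABNORMAL_WINS = "abnormal_wins"
NORMAL_WINS = "normal_wins"


@dataclass(frozen=True)
class Team:
    """Ordered reading team; the machine sits second in the study design."""

    first: str
    second: str
    third: str

    def __post_init__(self) -> None:
        if len({self.first, self.second, self.third}) != 3:
            raise ValidationError("team members must be pairwise distinct")

    @property
    def members(self) -> tuple[str, str, str]:
        return (self.first, self.second, self.third)


@dataclass(frozen=True)
class ProtocolParams:
    """Tunable protocol inputs.

    tau, delta : float in [0, 1]
        Cautious-protocol thresholds on the first-two confidence gap and
        mean perceived complexity.
    accuracies : mapping reader_id -> accuracy fraction
        Weights for the accuracy-weighted majority.
    tie_rule : str
        How an exact weight tie is resolved; default errs toward calling
        the case abnormal (the screening-relevant direction).
    """

    tau: float = 0.0
    delta: float = 1.0
    accuracies: Mapping[str, float] = field(default_factory=dict)
    tie_rule: str = ABNORMAL_WINS

    def __post_init__(self) -> None:
        for name in ("tau", "delta"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v!r}")
        if self.tie_rule not in (ABNORMAL_WINS, NORMAL_WINS):
            raise ValidationError(f"unknown tie_rule {self.tie_rule!r}")


@dataclass(frozen=True)
class ProtocolOutcome:
    """Team decision on one case plus the judgments it cost."""

    case_id: str
    decision: int
    judgments: int
    involved: tuple[str, ...]
    note: str | None = None

    def __post_init__(self) -> None:
        if self.judgments != len(self.involved):
            raise ValidationError("judgments must equal len(involved)")


# ---------------------------------------------------------------------
# vector kernels: decisions/confidences/complexities as aligned arrays
# ---------------------------------------------------------------------

def _maj3(d1, d2, d3):
    return ((d1 + d2 + d3) >= 2).astype(np.int64)


def _kernel_majority(d1, d2, d3):
    agree = d1 == d2
    dec = np.where(agree, d1, _maj3(d1, d2, d3))
    return dec, np.where(agree, 2, 3)


def _kernel_weighted(d1, d2, d3, w1, w2, w3, tie_rule):
    agree = d1 == d2
    w_pos = w1 * d1 + w2 * d2 + w3 * d3
    w_neg = w1 * (1 - d1) + w2 * (1 - d2) + w3 * (1 - d3)
    tie_dec = ABNORMAL if tie_rule == ABNORMAL_WINS else NORMAL
    weighted = np.where(w_pos > w_neg, ABNORMAL,
                        np.where(w_neg > w_pos, NORMAL, tie_dec))
    zero = (w1 + w2 + w3) == 0
    fallback = _maj3(d1, d2, d3)
    dec = np.where(agree, d1, np.where(zero, fallback, weighted))
    return dec, np.where(agree, 2, 3), (~agree) & zero


def _kernel_specific(d1, d2, d3):
    dec = np.where(d1 == NORMAL, NORMAL,
                   np.where(d2 == ABNORMAL, ABNORMAL, _maj3(d1, d2, d3)))
    j = np.where(d1 == NORMAL, 1, np.where(d2 == ABNORMAL, 2, 3))
    return dec, j


def _kernel_sensitive(d1, d2, d3):
    dec = np.where(d1 == ABNORMAL, ABNORMAL,
                   np.where(d2 == NORMAL, NORMAL, _maj3(d1, d2, d3)))
    j = np.where(d1 == ABNORMAL, 1, np.where(d2 == NORMAL, 2, 3))
    return dec, j


def _kernel_cautious(d1, d2, d3, c1, c2, k1, k2, tau, delta):
    # the confident-reader shortcut needs a strictly more confident reader;
    # at an exact confidence tie (possible only when tau == 0) the case
    # escalates to the arbiter like any unresolved disagreement
    shortcut = (np.abs(c1 - c2) >= tau) & ((k1 + k2) / 2.0 <= delta) & (c1 != c2)
    dec = np.where(shortcut, np.where(c1 > c2, d1, d2), _maj3(d1, d2, d3))
    return dec, np.where(shortcut, 2, 3)


def _kernel_presumptuous(d1, d2, d3, c1, c2):
    tie = c1 == c2
    dec = np.where(tie, _maj3(d1, d2, d3), np.where(c1 > c2, d1, d2))
    return dec, np.where(tie, 3, 2)


def _kernel_or(d1, d2):
    return np.where(d1 == ABNORMAL, ABNORMAL, d2), np.where(d1 == ABNORMAL, 1, 2)


# ---------------------------------------------------------------------
# scalar protocol operations on Reading objects
# ---------------------------------------------------------------------

def _check_readings(*readings: Reading) -> None:
    case_ids = {r.case_id for r in readings}
    if len(case_ids) != 1:
        raise ValidationError(f"readings span multiple cases: {sorted(case_ids)}")
    reader_ids = [r.reader_id for r in readings]
    if len(set(reader_ids)) != len(reader_ids):
        raise ValidationError("readings must come from distinct readers")


def _scalar(kernel_result, readings, n_short, note=None):
    dec, j = kernel_result
    j = int(j[0])
    involved = tuple(r.reader_id for r in readings[:j])
    return ProtocolOutcome(
        case_id=readings[0].case_id,
        decision=int(dec[0]),
        judgments=j,
        involved=involved,
        note=note,
    )


def _arr(*vals):
    return [np.asarray([v]) for v in vals]


def simple_majority(r1: Reading, r2: Reading, r3: Reading) -> ProtocolOutcome:
    """Arbiter involved iff the first two disagree; best-of-three decision."""
    _check_readings(r1, r2, r3)
    return _scalar(_kernel_majority(*_arr(r1.decision, r2.decision, r3.decision)),
                   (r1, r2, r3), 2)


def weighted_majority(
    r1: Reading,
    r2: Reading,
    r3: Reading,
    weights: Mapping[str, float],
    tie_rule: str = ABNORMAL_WINS,
) -> ProtocolOutcome:
    """Majority protocol with per-reader vote weights (accuracy or
    confidence).  An exact weight tie falls to ``tie_rule``; all-zero
    weights fall back to the simple majority of the involved readers, noted
    on the outcome."""
    _check_readings(r1, r2, r3)
    w = [float(weights[r.reader_id]) for r in (r1, r2, r3)]
    if any(not np.isfinite(x) or x < 0 for x in w):
        raise ValidationError(f"weights must be finite and >= 0, got {w}")
    dec, j, zero = _kernel_weighted(
        *_arr(r1.decision, r2.decision, r3.decision), *_arr(*w), tie_rule
    )
    note = "zero_weights_fallback" if bool(zero[0]) else None
    return _scalar((dec, j), (r1, r2, r3), 2, note=note)


def specificity_oriented(r1: Reading, r2: Reading, r3: Reading) -> ProtocolOutcome:
    """Second reader consulted only on an abnormal first call."""
    _check_readings(r1, r2, r3)
    return _scalar(_kernel_specific(*_arr(r1.decision, r2.decision, r3.decision)),
                   (r1, r2, r3), 1)


def sensitivity_oriented(r1: Reading, r2: Reading, r3: Reading) -> ProtocolOutcome:
    """Mirror image of the specificity-oriented protocol: the second reader
    is consulted only on a normal first call."""
    _check_readings(r1, r2, r3)
    return _scalar(_kernel_sensitive(*_arr(r1.decision, r2.decision, r3.decision)),
                   (r1, r2, r3), 1)


def cautious(
    r1: Reading, r2: Reading, r3: Reading, tau: float, delta: float
) -> ProtocolOutcome:
    """Trust the more confident of the first two readers when their
    confidence gap is at least ``tau`` and the case looks simple (mean
    reported complexity at most ``delta``); otherwise arbitrate."""
    _check_readings(r1, r2, r3)
    return _scalar(
        _kernel_cautious(
            *_arr(r1.decision, r2.decision, r3.decision),
            *_arr(r1.confidence, r2.confidence, r1.complexity, r2.complexity),
            tau, delta,
        ),
        (r1, r2, r3), 2,
    )


def presumptuous(r1: Reading, r2: Reading, r3: Reading) -> ProtocolOutcome:
    """Always trust the strictly more confident of the first two readers;
    arbitrate only on an exact confidence tie."""
    _check_readings(r1, r2, r3)
    return _scalar(
        _kernel_presumptuous(
            *_arr(r1.decision, r2.decision, r3.decision),
            *_arr(r1.confidence, r2.confidence),
        ),
        (r1, r2, r3), 2,
    )


def or_rule(r1: Reading, r2: Reading) -> ProtocolOutcome:
    """Team flags abnormal iff either of the first two readers does; the
    third reader is never consulted."""
    _check_readings(r1, r2)
    return _scalar(_kernel_or(*_arr(r1.decision, r2.decision)), (r1, r2), 1)


def majority_panel(readings: Sequence[Reading]) -> int:
    """Simple-majority decision of an odd-sized reader group, all readers
    always consulted."""
    if len(readings) % 2 == 0 or len(readings) == 0:
        raise ValidationError(
            f"majority_panel needs an odd number of readings, got {len(readings)}"
        )
    _check_readings(*readings)
    votes = sum(r.decision for r in readings)
    return ABNORMAL if 2 * votes > len(readings) else NORMAL


# ---------------------------------------------------------------------
# threshold formulas
# ---------------------------------------------------------------------

def compute_tau(panel: Panel, reader_ids: Sequence[str]) -> float:
    """Mean over cases of the mean pairwise absolute difference in
    normalized confidence across the given readers."""
    ids = list(reader_ids)
    if len(ids) < 2:
        raise ValidationError("compute_tau needs at least two readers")
    conf = np.vstack([panel.reader_arrays(r)["confidence"] for r in ids])
    pairs = list(combinations(range(len(ids)), 2))
    gaps = np.mean([np.abs(conf[i] - conf[j]) for i, j in pairs], axis=0)
    return float(gaps.mean())


def compute_delta(panel: Panel, reader_ids: Sequence[str]) -> float:
    """Mean normalized complexity over the given readers and all cases."""
    ids = list(reader_ids)
    if len(ids) < 1:
        raise ValidationError("compute_delta needs at least one reader")
    compl = np.vstack([panel.reader_arrays(r)["complexity"] for r in ids])
    return float(compl.mean())


# ---------------------------------------------------------------------
# panel-wide team evaluation
# ---------------------------------------------------------------------

def apply_protocol(
    panel: Panel,
    team: Team,
    name: str,
    params: ProtocolParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate one protocol for one team over every case of a panel.

    Returns ``(decisions, judgments)`` aligned to the panel's canonical
    case order.
    """
    params = params or ProtocolParams()
    a1 = panel.reader_arrays(team.first)
    a2 = panel.reader_arrays(team.second)
    a3 = panel.reader_arrays(team.third)
    d1, d2, d3 = a1["decision"], a2["decision"], a3["decision"]

    if name == "majority":
        dec, j = _kernel_majority(d1, d2, d3)
    elif name == "acc_weighted":
        try:
            w = [float(params.accuracies[m]) for m in team.members]
        except KeyError as exc:
            raise ValidationError(
                f"missing accuracy weight for reader {exc.args[0]!r}"
            ) from exc
        dec, j, _ = _kernel_weighted(
            d1, d2, d3,
            np.full_like(d1, w[0], dtype=float),
            np.full_like(d1, w[1], dtype=float),
            np.full_like(d1, w[2], dtype=float),
            params.tie_rule,
        )
    elif name == "conf_weighted":
        dec, j, _ = _kernel_weighted(
            d1, d2, d3, a1["confidence"], a2["confidence"], a3["confidence"],
            params.tie_rule,
        )
    elif name == "specific":
        dec, j = _kernel_specific(d1, d2, d3)
    elif name == "sensitive":
        dec, j = _kernel_sensitive(d1, d2, d3)
    elif name == "cautious":
        dec, j = _kernel_cautious(
            d1, d2, d3, a1["confidence"], a2["confidence"],
            a1["complexity"], a2["complexity"], params.tau, params.delta,
        )
    elif name == "presumptuous":
        dec, j = _kernel_presumptuous(
            d1, d2, d3, a1["confidence"], a2["confidence"]
        )
    elif name == "or_rule":
        dec, j = _kernel_or(d1, d2)
    else:
        raise ValidationError(f"unknown protocol {name!r}")
    return np.asarray(dec, dtype=np.int64), np.asarray(j, dtype=np.int64)


def majority_panel_decisions(decision_matrix: np.ndarray) -> np.ndarray:
    """Vectorized all-readers majority: rows are readers, columns cases."""
    k = decision_matrix.shape[0]
    if k % 2 == 0 or k == 0:
        raise ValidationError("majority needs an odd number of readers")
    return (decision_matrix.sum(axis=0) * 2 > k).astype(np.int64)
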