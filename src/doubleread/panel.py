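"""Core containers for reader-panel annotation data.

A *panel* is the complete record of a multi-reader multi-case study: a set of
cases with gold-standard labels, a set of readers (human or machine) with
their generative operating characteristics, and exactly one reading — binary
decision plus ordinal confidence and perceived complexity — per (reader,
case) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Decision encoding used throughout: abnormal (pathological) is the
#: positive class, per the sensitivity definition over abnormal gold cases.
NORMAL = 0
ABNORMAL = 1

CONFIDENCE_LEVELS = 5
COMPLEXITY_LEVELS = 4


class ValidationError(ValueError):
    """Raised when inputs violate a declared contract."""


def normalize_level(level: int | np.ndarray, n_levels: int):
    """Map ordinal level k of L onto the grid {0, 1/(L-1), ..., 1}."""
    return (np.asarray(level) - 1) / (n_levels - 1)


@dataclass(frozen=True)
class ReaderProfile:
    """Generative operating characteristics of one reader.

    Parameters
    ----------
    reader_id : str
        Opaque label, unique within a panel.
    kind : str
        ``"human"`` or ``"machine"``.
    sensitivity, specificity : float
        Probability of a correct call on abnormal / normal cases, in [0, 1].
    difficulty_slope : float
        Nonnegative; how strongly latent case difficulty concentrates this
        reader's errors on hard cases.
    confidence_bias : float
        Additive shift of the latent confidence scale (positive = more
        confident self-reports).
    """

    reader_id: str
    kind: str
    sensitivity: float
    specificity: float
    difficulty_slope: float = 0.0
    confidence_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("human", "machine"):
            raise ValidationError(f"unknown reader kind {self.kind!r}")
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v!r}")
        if not np.isfinite(self.difficulty_slope) or self.difficulty_slope < 0:
            raise ValidationError(
                f"difficulty_slope must be >= 0, got {self.difficulty_slope!r}"
            )

    @property
    def accuracy(self) -> float:
        """Expected accuracy on a balanced case mix."""
        return 0.5 * (self.sensitivity + self.specificity)


@dataclass(frozen=True)
class CaseRecord:
    """One case: gold label plus the latent difficulty that drives errors,
    complexity ratings and inter-reader correlation."""

    case_id: str
    gold: int
    difficulty: float

    def __post_init__(self) -> None:
        if self.gold not in (NORMAL, ABNORMAL):
            raise ValidationError(f"gold must be 0/1, got {self.gold!r}")
        if not 0.0 <= self.difficulty <= 1.0:
            raise ValidationError(
                f"difficulty must be in [0, 1], got {self.difficulty!r}"
            )


@dataclass(frozen=True)
class Reading:
    """A single reader's interpretation of a single case."""

    reader_id: str
    case_id: str
    decision: int
    confidence_level: int
    complexity_level: int

    def __post_init__(self) -> None:
        if self.decision not in (NORMAL, ABNORMAL):
            raise ValidationError(f"decision must be 0/1, got {self.decision!r}")
        if not 1 <= self.confidence_level <= CONFIDENCE_LEVELS:
            raise ValidationError(
                f"confidence level must be 1..{CONFIDENCE_LEVELS}, "
                f"got {self.confidence_level!r}"
            )
        if not 1 <= self.complexity_level <= COMPLEXITY_LEVELS:
            raise ValidationError(
                f"complexity level must be 1..{COMPLEXITY_LEVELS}, "
                f"got {self.complexity_level!r}"
            )

    @property
    def confidence(self) -> float:
        """Confidence normalized onto {0, 0.25, 0.5, 0.75, 1}."""
        return float(normalize_level(self.confidence_level, CONFIDENCE_LEVELS))

    @property
    def complexity(self) -> float:
        """Complexity normalized onto {0, 1/3, 2/3, 1}."""
        return float(normalize_level(self.complexity_level, COMPLEXITY_LEVELS))


@dataclass
class Panel:
    """A complete reader-panel dataset.

    Attributes
    ----------
    cases : pandas.DataFrame
        Columns ``case_id``, ``gold`` (0/1), ``difficulty``; one row per case.
    readings : pandas.DataFrame
        Columns ``reader_id, case_id, decision, confidence_level,
        complexity_level``; exactly one row per (reader, case).
    profiles : dict
        ``reader_id -> ReaderProfile`` for every reader in the table.
    seed : int or None
        Root seed if the panel was simulated.
    """

    cases: pd.DataFrame
    readings: pd.DataFrame
    profiles: dict[str, ReaderProfile]
    seed: int | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    # -- construction / validation ------------------------------------

    def validate(self) -> "Panel":
        case_ids = self.cases["case_id"]
        if case_ids.duplicated().any():
            raise ValidationError("duplicate case_id in cases table")
        if not self.cases["gold"].isin([NORMAL, ABNORMAL]).all():
            raise ValidationError("gold labels must be 0/1")
        dup = self.readings.duplicated(subset=["reader_id", "case_id"])
        if dup.any():
            raise ValidationError(
                f"duplicate (reader_id, case_id) reading at row {dup.idxmax()}"
            )
        unknown = ~self.readings["case_id"].isin(set(case_ids))
        if unknown.any():
            raise ValidationError(
                f"reading references unknown case_id at row {unknown.idxmax()}"
            )
        unknown_r = ~self.readings["reader_id"].isin(self.profiles.keys())
        if unknown_r.any():
            raise ValidationError(
                f"reading references unknown reader_id at row {unknown_r.idxmax()}"
            )
        n_expected = len(self.profiles) * len(self.cases)
        if len(self.readings) != n_expected:
            raise ValidationError(
                f"expected one reading per (reader, case): "
                f"{n_expected} rows, found {len(self.readings)}"
            )
        bad_conf = ~self.readings["confidence_level"].isin(
            range(1, CONFIDENCE_LEVELS + 1)
        )
        if bad_conf.any():
            raise ValidationError(
                f"confidence level out of 1..{CONFIDENCE_LEVELS} at row "
                f"{bad_conf.idxmax()}"
            )
        bad_compl = ~self.readings["complexity_level"].isin(
            range(1, COMPLEXITY_LEVELS + 1)
        )
        if bad_compl.any():
            raise ValidationError(
                f"complexity level out of 1..{COMPLEXITY_LEVELS} at row "
                f"{bad_compl.idxmax()}"
            )
        if not self.readings["decision"].isin([NORMAL, ABNORMAL]).all():
            bad = ~self.readings["decision"].isin([NORMAL, ABNORMAL])
            raise ValidationError(f"unknown decision code at row {bad.idxmax()}")
        return self

    # -- accessors -----------------------------------------------------

    @property
    def reader_ids(self) -> list[str]:
        return list(self.profiles.keys())

    @property
    def case_ids(self) -> list[str]:
        return self.cases["case_id"].tolist()

    @property
    def gold(self) -> np.ndarray:
        """Gold labels (0/1) in canonical case order."""
        return self.cases["gold"].to_numpy()

    @property
    def difficulty(self) -> np.ndarray:
        return self.cases["difficulty"].to_numpy()

    def human_ids(self) -> list[str]:
        return [r for r, p in self.profiles.items() if p.kind == "human"]

    def machine_ids(self) -> list[str]:
        return [r for r, p in self.profiles.items() if p.kind == "machine"]

    def reader_arrays(self, reader_id: str) -> dict[str, np.ndarray]:
        """Per-reader arrays aligned to canonical case order.

        Returns a dict with ``decision`` (0/1 int), ``confidence`` and
        ``complexity`` (normalized floats), and ``correct`` (bool).
        Cached, since team evaluation reuses the same readers many times.
        """
        key = ("arrays", reader_id)
        if key not in self._cache:
            if reader_id not in self.profiles:
                raise ValidationError(f"unknown reader_id {reader_id!r}")
            sub = self.readings[self.readings["reader_id"] == reader_id]
            sub = sub.set_index("case_id").loc[self.case_ids]
            decision = sub["decision"].to_numpy(dtype=np.int64)
            self._cache[key] = {
                "decision": decision,
                "confidence": normalize_level(
                    sub["confidence_level"].to_numpy(), CONFIDENCE_LEVELS
                ),
                "complexity": normalize_level(
                    sub["complexity_level"].to_numpy(), COMPLEXITY_LEVELS
                ),
                "correct": decision == self.gold,
            }
        return self._cache[key]

    def reading(self, reader_id: str, case_id: str) -> Reading:
        row = self.readings[
            (self.readings["reader_id"] == reader_id)
            & (self.readings["case_id"] == case_id)
        ]
        if len(row) != 1:
            raise ValidationError(
                f"expected exactly one reading for ({reader_id!r}, {case_id!r})"
            )
        r = row.iloc[0]
        return Reading(
            reader_id=reader_id,
            case_id=case_id,
            decision=int(r["decision"]),
            confidence_level=int(r["confidence_level"]),
            complexity_level=int(r["complexity_level"]),
        )

    def reader_accuracy(self, reader_id: str) -> float:
        """Empirical accuracy (fraction) of one reader against gold."""
        return float(self.reader_arrays(reader_id)["correct"].mean())

    def reader_sens_spec(self, reader_id: str) -> tuple[float, float]:
        arr = self.reader_arrays(reader_id)
        gold = self.gold
        pos, neg = gold == ABNORMAL, gold == NORMAL
        sens = float(arr["correct"][pos].mean()) if pos.any() else float("nan")
        spec = float(arr["correct"][neg].mean()) if neg.any() else float("nan")
        return sens, spec

    def reader_accuracies(self, reader_ids: Iterable[str] | None = None
                          ) -> dict[str, float]:
        ids = list(reader_ids) if reader_ids is not None else self.reader_ids
        return {r: self.reader_accuracy(r) for r in ids}
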