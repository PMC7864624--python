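"""Synthetic reader-panel generator.

Emulates a multi-reader multi-case annotation study: a roughly balanced set
of cases with a latent difficulty each, and a mixed panel of human and
machine readers whose binary calls, ordinal confidences (5 levels) and
ordinal perceived complexities (4 levels) carry the statistical structure
real panels show — reader-specific operating points, errors concentrated on
difficult cases (hence positively correlated across readers), confidence
higher on correct and easy cases, complexity tracking difficulty.

Correctness is sampled by *balanced incidence*: each reader's number of
correct calls within each gold class is fixed to the (stochastically
rounded) expected count implied by their operating point, and the errors are
allocated preferentially to difficult cases via a Gumbel-perturbed ranking
scaled by the reader's difficulty slope.  This behaves like a per-case
Bernoulli model conditioned on its marginal totals: marginal sensitivity and
specificity match the profile exactly up to rounding, while the
per-case error probability still decreases smoothly with difficulty.  With
slope 0 the error set is a uniform random subset, recovering (conditional)
independence between readers.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import (
    ABNORMAL,
    COMPLEXITY_LEVELS,
    CONFIDENCE_LEVELS,
    NORMAL,
    Panel,
    ReaderProfile,
    ValidationError,
)
from . import study

#: Default strength of the shared-difficulty effect on error allocation.
DEFAULT_SLOPE = 0.35

# Latent-scale coefficients for the ordinal self-reports.  Chosen so that
# the panel-computed cautious-protocol thresholds land near the study's
# printed values (mean pairwise confidence gap ~0.17, mean complexity ~0.70)
# while keeping confidence increasing in correctness and decreasing in
# difficulty, and complexity increasing in difficulty.
_CONF_BASE = 0.62
_CONF_CORRECT = 0.05
_CONF_DIFFICULTY = 0.35
_CONF_NOISE = 0.15
_COMPL_BASE = 0.35
_COMPL_DIFFICULTY = 0.72
_COMPL_NOISE = 0.12
_GUMBEL_SCALE = 0.11
# Machine latent score margin m = |s - 0.5|: confidence = 2m on [0, 1].
_MACH_MARGIN_BASE = 0.33
_MACH_MARGIN_CORRECT = 0.10
_MACH_MARGIN_DIFFICULTY = 0.22
_MACH_NOISE = 0.08

_CASE_STREAM = 0xCA5E


def _reader_rng(seed: int, reader_id: str) -> np.random.Generator:
    # keyed by a hash of the reader_id so that adding/removing readers
    # never perturbs the substreams of the others
    return np.random.default_rng(
        np.random.SeedSequence([seed, 1, zlib.crc32(reader_id.encode())])
    )


def _quantize(latent: np.ndarray, n_levels: int) -> np.ndarray:
    """Clip a latent [0,1] value and snap it to ordinal levels 1..L."""
    z = np.clip(latent, 0.0, 1.0)
    return np.rint(z * (n_levels - 1)).astype(np.int64) + 1


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def generate_panel(
    profiles: list[ReaderProfile],
    n_cases: int,
    prevalence: float = 0.5,
    seed: int = 0,
) -> Panel:
    """Simulate a full reader panel.

    Parameters
    ----------
    profiles : list of ReaderProfile
        Readers to simulate; at least one.
    n_cases : int
        Number of cases; the abnormal count is ``round(prevalence *
        n_cases)`` (half rounds up, so 427 balanced cases split 214/213).
    prevalence : float
        Fraction of abnormal (positive) cases, in [0, 1].
    seed : int
        Root seed.  Identical arguments reproduce the panel bit-exactly;
        each reader draws from its own substream keyed by reader_id.
    """
    if n_cases < 1:
        raise ValidationError(f"n_cases must be >= 1, got {n_cases}")
    if not np.isfinite(prevalence) or not 0.0 <= prevalence <= 1.0:
        raise ValidationError(f"prevalence must be in [0, 1], got {prevalence!r}")
    if not profiles:
        raise ValidationError("at least one reader profile is required")
    ids = [p.reader_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValidationError("reader_ids must be unique")

    case_rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), 0, _CASE_STREAM])
    )
    n_pos = round_half_up(prevalence * n_cases)
    gold = np.zeros(n_cases, dtype=np.int64)
    gold[case_rng.permutation(n_cases)[:n_pos]] = ABNORMAL
    difficulty = case_rng.beta(2.0, 2.0, size=n_cases)

    width = max(4, len(str(n_cases)))
    cases = pd.DataFrame(
        {
            "case_id": [f"case_{i:0{width}d}" for i in range(n_cases)],
            "gold": gold,
            "difficulty": difficulty,
        }
    )

    frames = []
    for prof in profiles:
        rng = _reader_rng(int(seed), prof.reader_id)
        correct = _sample_correctness(prof, gold, difficulty, rng)
        decision = np.where(correct, gold, 1 - gold)
        if prof.kind == "machine":
            conf_level, compl_level = _machine_reports(
                prof, correct, difficulty, rng
            )
        else:
            conf_level, compl_level = _human_reports(
                prof, correct, difficulty, rng
            )
        frames.append(
            pd.DataFrame(
                {
                    "reader_id": prof.reader_id,
                    "case_id": cases["case_id"],
                    "decision": decision,
                    "confidence_level": conf_level,
                    "complexity_level": compl_level,
                }
            )
        )

    panel = Panel(
        cases=cases,
        readings=pd.concat(frames, ignore_index=True),
        profiles={p.reader_id: p for p in profiles},
        seed=int(seed),
    )
    return panel.validate()


def _sample_correctness(
    prof: ReaderProfile,
    gold: np.ndarray,
    difficulty: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Balanced-incidence correctness: exact expected count per gold class,
    errors ranked onto difficult cases."""
    correct = np.zeros(len(gold), dtype=bool)
    for cls, p in ((ABNORMAL, prof.sensitivity), (NORMAL, prof.specificity)):
        idx = np.flatnonzero(gold == cls)
        if idx.size == 0:
            continue
        target = p * idx.size
        k = int(np.floor(target))
        if rng.random() < target - k:
            k += 1
        k = min(k, idx.size)
        n_wrong = idx.size - k
        # higher score -> more error-prone; slope 0 makes this pure noise
        score = prof.difficulty_slope * difficulty[idx] + rng.gumbel(
            0.0, _GUMBEL_SCALE, size=idx.size
        )
        wrong = idx[np.argsort(score)[::-1][:n_wrong]]
        correct[idx] = True
        correct[wrong] = False
    return correct


def _human_reports(prof, correct, difficulty, rng):
    n = len(correct)
    conf_latent = (
        _CONF_BASE
        + _CONF_CORRECT * correct
        - _CONF_DIFFICULTY * difficulty
        + prof.confidence_bias
        + rng.normal(0.0, _CONF_NOISE, size=n)
    )
    compl_latent = (
        _COMPL_BASE
        + _COMPL_DIFFICULTY * difficulty
        + rng.normal(0.0, _COMPL_NOISE, size=n)
    )
    return (
        _quantize(conf_latent, CONFIDENCE_LEVELS),
        _quantize(compl_latent, COMPLEXITY_LEVELS),
    )


def _machine_reports(prof, correct, difficulty, rng):
    # machine emits a latent abnormality score s in [0,1]; the reported
    # confidence is 2|s - 0.5| and complexity its complement, both snapped
    # to the ordinal grids
    n = len(correct)
    margin = np.clip(
        _MACH_MARGIN_BASE
        + _MACH_MARGIN_CORRECT * correct
        - _MACH_MARGIN_DIFFICULTY * difficulty
        + prof.confidence_bias
        + rng.normal(0.0, _MACH_NOISE, size=n),
        0.0,
        0.5,
    )
    conf = 2.0 * margin
    return (
        _quantize(conf, CONFIDENCE_LEVELS),
        _quantize(1.0 - conf, COMPLEXITY_LEVELS),
    )


def default_study_profiles(
    slope: float = DEFAULT_SLOPE,
) -> list[ReaderProfile]:
    """The twelve study readers: ten humans at the published accuracies,
    a MobileNet-style second-reader machine (accuracy 81.72%) and an
    InceptionV3-style benchmark machine (sensitivity 94.76%, specificity
    76.27%).

    Human operating points are taken symmetric (sensitivity = specificity =
    accuracy), the simplest point consistent with a published accuracy on a
    balanced case mix; the same convention covers the MobileNet-style
    machine, whose class-conditional split is unpublished.
    """
    profiles = [
        ReaderProfile(
            reader_id=f"reader_{i + 1:02d}",
            kind="human",
            sensitivity=acc / 100.0,
            specificity=acc / 100.0,
            difficulty_slope=slope,
        )
        for i, acc in enumerate(study.TABLE1_ACCURACIES)
    ]
    profiles.append(
        ReaderProfile(
            reader_id="machine_mobilenet",
            kind="machine",
            sensitivity=study.WEAK_MACHINE_ACCURACY / 100.0,
            specificity=study.WEAK_MACHINE_ACCURACY / 100.0,
            difficulty_slope=slope,
        )
    )
    profiles.append(
        ReaderProfile(
            reader_id="machine_inceptionv3",
            kind="machine",
            sensitivity=study.STRONG_MACHINE_SENSITIVITY / 100.0,
            specificity=study.STRONG_MACHINE_SPECIFICITY / 100.0,
            difficulty_slope=slope,
        )
    )
    return profiles


@dataclass(frozen=True)
class AssociationSummary:
    """Rank correlations between per-case panel behaviour and success rate.

    ``confidence_success`` / ``complexity_success`` are Spearman
    correlations of the per-case mean confidence / complexity with the
    per-case fraction of readers answering correctly; each is NaN with the
    matching ``*_defined`` flag False when its column is degenerate.
    """

    confidence_success: float
    complexity_success: float
    confidence_defined: bool
    complexity_defined: bool


def check_association_structure(
    panel: Panel, reader_ids: list[str] | None = None
) -> AssociationSummary:
    """Diagnostic for the generator's intended metadata structure:
    confidence should associate positively, complexity negatively, with the
    per-case success rate."""
    ids = reader_ids if reader_ids is not None else panel.reader_ids
    if not ids or len(panel.cases) == 0:
        raise ValidationError("panel must contain readers and cases")
    arrays = [panel.reader_arrays(r) for r in ids]
    success = np.mean([a["correct"] for a in arrays], axis=0)
    conf = np.mean([a["confidence"] for a in arrays], axis=0)
    compl = np.mean([a["complexity"] for a in arrays], axis=0)

    def _corr(x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return float("nan"), False
        rho = sps.spearmanr(x, y).statistic
        return float(rho), bool(np.isfinite(rho))

    conf_rho, conf_ok = _corr(conf, success)
    compl_rho, compl_ok = _corr(compl, success)
    return AssociationSummary(conf_rho, compl_rho, conf_ok, compl_ok)
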