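"""Readers and writers for panels, configs and experiment results.

Storage conventions: decisions are encoded 0 = normal, 1 = abnormal
(abnormal is the positive class); ordinal levels are stored as integers
(confidence 1..5, complexity 1..4); metric tables carry a 2-decimal
presentation column alongside a full-precision twin so reports are readable
without losing reproducibility.  Schema violations are rejected with the
offending row number, never coerced.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .experiments import Experiment1Result, Experiment2Result
from .metrics import METRIC_NAMES
from .panel import (
    ABNORMAL,
    COMPLEXITY_LEVELS,
    CONFIDENCE_LEVELS,
    NORMAL,
    Panel,
    ReaderProfile,
    ValidationError,
)

READINGS_COLUMNS = [
    "reader_id",
    "case_id",
    "decision",
    "confidence_level",
    "complexity_level",
]


# ---------------------------------------------------------------------
# panel I/O
# ---------------------------------------------------------------------

def write_panel(panel: Panel, out_dir: str | Path) -> dict[str, Path]:
    """Write a panel as plain CSV/YAML: readings, gold labels (with latent
    difficulty when simulated) and reader profiles."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "readings": out / "readings.csv",
        "gold": out / "gold.csv",
        "profiles": out / "profiles.yaml",
    }
    panel.readings[READINGS_COLUMNS].to_csv(paths["readings"], index=False)
    panel.cases.to_csv(paths["gold"], index=False)
    write_profiles(list(panel.profiles.values()), paths["profiles"])
    return paths


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def read_panel(
    readings_csv: str | Path,
    gold_csv: str | Path,
    profiles_yaml: str | Path | None = None,
) -> Panel:
    """Load and validate a panel from CSV.

    The gold file needs ``case_id, gold`` (0/1); a ``difficulty`` column is
    optional (simulated panels carry it, collected ones do not).  Without a
    profiles file, descriptive profiles are reconstructed from the data
    itself (kind defaults to human).
    """
    readings = pd.read_csv(readings_csv)
    gold = pd.read_csv(gold_csv)
    _require_columns(readings, READINGS_COLUMNS, readings_csv)
    _require_columns(gold, ["case_id", "gold"], gold_csv)

    # row-numbered schema checks (header is line 1, data starts at line 2)
    def _bad_row(mask: pd.Series) -> int:
        return int(mask.idxmax()) + 2

    for col, lo, hi in (
        ("decision", NORMAL, ABNORMAL),
        ("confidence_level", 1, CONFIDENCE_LEVELS),
        ("complexity_level", 1, COMPLEXITY_LEVELS),
    ):
        bad = ~readings[col].isin(range(lo, hi + 1))
        if bad.any():
            raise ValidationError(
                f"{readings_csv}: {col} out of range [{lo}, {hi}] "
                f"at line {_bad_row(bad)}"
            )
    dup = readings.duplicated(subset=["reader_id", "case_id"])
    if dup.any():
        raise ValidationError(
            f"{readings_csv}: duplicate (reader_id, case_id) at line {_bad_row(dup)}"
        )
    orphan = ~readings["case_id"].isin(set(gold["case_id"]))
    if orphan.any():
        raise ValidationError(
            f"{readings_csv}: unknown case_id at line {_bad_row(orphan)}"
        )

    cases = gold.copy()
    if "difficulty" not in cases.columns:
        cases["difficulty"] = np.nan

    if profiles_yaml is not None:
        profiles = {p.reader_id: p for p in read_profiles(profiles_yaml)}
    else:
        profiles = {}
        gold_by_case = cases.set_index("case_id")["gold"]
        for reader_id, sub in readings.groupby("reader_id", sort=False):
            g = gold_by_case.loc[sub["case_id"]].to_numpy()
            d = sub["decision"].to_numpy()
            pos, neg = g == ABNORMAL, g == NORMAL
            profiles[reader_id] = ReaderProfile(
                reader_id=reader_id,
                kind="human",
                sensitivity=float((d[pos] == ABNORMAL).mean()) if pos.any() else 0.5,
                specificity=float((d[neg] == NORMAL).mean()) if neg.any() else 0.5,
            )
    return Panel(cases=cases, readings=readings, profiles=profiles).validate()


def write_profiles(profiles: list[ReaderProfile], path: str | Path) -> None:
    data = {
        p.reader_id: {
            "kind": p.kind,
            "sensitivity": float(p.sensitivity),
            "specificity": float(p.specificity),
            "difficulty_slope": float(p.difficulty_slope),
            "confidence_bias": float(p.confidence_bias),
        }
        for p in profiles
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_profiles(path: str | Path) -> list[ReaderProfile]:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: profiles file must map reader_id to fields")
    return [
        ReaderProfile(
            reader_id=rid,
            kind=spec.get("kind", "human"),
            sensitivity=float(spec["sensitivity"]),
            specificity=float(spec["specificity"]),
            difficulty_slope=float(spec.get("difficulty_slope", 0.0)),
            confidence_bias=float(spec.get("confidence_bias", 0.0)),
        )
        for rid, spec in data.items()
    ]


# ---------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------

def load_config(path: str | Path) -> dict[str, Any]:
    cfg = yaml.safe_load(Path(path).read_text())
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a flat key-value mapping")
    return cfg


def save_config(cfg: Mapping[str, Any], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dict(cfg), sort_keys=True))


# ---------------------------------------------------------------------
# results
# ---------------------------------------------------------------------

def _with_presentation(df: pd.DataFrame) -> pd.DataFrame:
    """Round metric columns to 2 decimals and keep full-precision twins."""
    out = df.copy()
    for col in df.columns:
        if col in METRIC_NAMES or col in ("mean", "ci_low", "ci_high",
                                          "team_mean", "benchmark"):
            out[col + "_full"] = df[col]
            out[col] = df[col].round(2)
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(
    out: Path, files: list[Path], seed, config: Mapping[str, Any] | None
) -> Path:
    manifest = {
        "seed": seed,
        "config": dict(config) if config else {},
        "created": datetime.now(timezone.utc).isoformat(),
        "outputs": [
            {"file": f.name, "sha256": _sha256(f)} for f in sorted(files)
        ],
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path


def write_experiment1_results(
    result: Experiment1Result,
    out_dir: str | Path,
    seed: int | None = None,
    config: Mapping[str, Any] | None = None,
) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for name, df in (
        ("metrics_by_team.csv", result.metrics_by_team),
        ("aggregates.csv", result.aggregates),
        ("tests.csv", result.tests),
    ):
        path = out / name
        _with_presentation(df).to_csv(path, index=False)
        files.append(path)
    bench = pd.DataFrame([result.benchmark.as_dict()])
    path = out / "benchmark.csv"
    _with_presentation(bench).to_csv(path, index=False)
    files.append(path)
    files.append(_write_manifest(out, files, seed, config))
    return files


def write_experiment2_results(
    result: Experiment2Result,
    out_dir: str | Path,
    seed: int | None = None,
    config: Mapping[str, Any] | None = None,
) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for name, df in (
        ("metrics_by_team.csv", result.metrics_by_team),
        ("aggregates.csv", result.aggregates),
    ):
        path = out / name
        _with_presentation(df).to_csv(path, index=False)
        files.append(path)
    for metric, mat in result.ks_pvalues.items():
        path = out / f"ks_matrix_{metric}.csv"
        mat.to_csv(path, index_label="strong\\weak")
        files.append(path)
    files.append(_write_manifest(out, files, seed, config))
    return files


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _with_presentation(df).to_csv(path, index=False)
    return path
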