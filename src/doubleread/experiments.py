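"""The two team-performance experiments.

Experiment 1 contrasts every 3-reader team (two humans around a fixed
machine second reader) against a stronger benchmark machine: all eight
protocols are evaluated on all ordered human pairs, and each (protocol,
metric) distribution of team scores is tested against the benchmark's
scalar with a one-sample t test, Bonferroni-corrected within the metric's
family of protocols.

Experiment 2 splits the humans into a weak half and a strong half by panel
accuracy, evaluates the eight protocols on each side's ordered pairs (same
machine second reader), and compares every strong-protocol score
distribution against every weak-protocol distribution with the two-sample
Kolmogorov-Smirnov test, Bonferroni-corrected over the full protocol x
protocol family per metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from . import stats
from .metrics import METRIC_NAMES, MetricSet, metric_set
from .panel import Panel, ValidationError
from .protocols import (
    PROTOCOL_NAMES,
    ProtocolParams,
    Team,
    apply_protocol,
    compute_delta,
    compute_tau,
    majority_panel_decisions,
)

#: Metrics the benchmark comparison of experiment 1 covers by default.
EXPERIMENT1_TEST_METRICS = ("accuracy", "sensitivity", "specificity", "hm_sens_spec")


@dataclass
class ExperimentConfig:
    """Configuration shared by both experiments.

    tau/delta default to None, meaning "compute from the panel's human
    readers" exactly as the study derived its thresholds; set them to fix
    the published constants instead.  Family sizes default to each
    result table's visible comparison family: one row of protocols for
    experiment 1, the full 8x8 grid for experiment 2.
    """

    machine_member: str = "machine_mobilenet"
    benchmark_machine: str = "machine_inceptionv3"
    tau: float | None = None
    delta: float | None = None
    tie_rule: str = "abnormal_wins"
    include_machine_in_thresholds: bool = False
    family_experiment1: int | None = None   # default: number of protocols
    family_experiment2: int | None = None   # default: protocols squared
    test_efficiency: bool = False
    protocols: Sequence[str] = PROTOCOL_NAMES

    def __post_init__(self) -> None:
        if self.machine_member == self.benchmark_machine:
            raise ValidationError(
                "machine_member and benchmark_machine must differ"
            )


def trim_outlier_readers(accuracies: Mapping[str, float]) -> list[str]:
    """Drop exactly the single most and single least accurate reader.

    Ties at either extreme are surfaced as an error rather than silently
    resolved.
    """
    if len(accuracies) < 3:
        raise ValidationError("need at least three readers to trim outliers")
    vals = list(accuracies.values())
    lo, hi = min(vals), max(vals)
    if vals.count(lo) > 1 or vals.count(hi) > 1:
        raise ValidationError("tie at an accuracy extreme; trim is ambiguous")
    return [r for r, a in accuracies.items() if a != lo and a != hi]


def enumerate_teams(humans: Sequence[str], machine: str) -> list[Team]:
    """All ordered human pairs around the fixed machine second reader:
    n*(n-1) teams for n humans."""
    humans = list(humans)
    if len(humans) < 2:
        raise ValidationError("need at least two human readers")
    if machine in humans:
        raise ValidationError("machine cannot be one of the human readers")
    return [Team(a, machine, b) for a, b in permutations(humans, 2)]


def split_weak_strong(
    panel: Panel, humans: Sequence[str] | None = None
) -> tuple[list[str], list[str]]:
    """Split humans into the least-accurate and most-accurate halves by
    panel accuracy against gold."""
    ids = list(humans) if humans is not None else panel.human_ids()
    ranked = sorted(ids, key=lambda r: (panel.reader_accuracy(r), r))
    k = len(ranked) // 2
    return ranked[:k], ranked[-k:]


def resolve_params(
    panel: Panel, config: ExperimentConfig, humans: Sequence[str]
) -> ProtocolParams:
    """Protocol parameters for a run: thresholds from the panel (or fixed
    by config) and accuracy weights estimated on the full panel."""
    threshold_readers = list(humans)
    if config.include_machine_in_thresholds:
        threshold_readers = threshold_readers + [config.machine_member]
    tau = config.tau if config.tau is not None else compute_tau(panel, threshold_readers)
    delta = (
        config.delta
        if config.delta is not None
        else compute_delta(panel, threshold_readers)
    )
    return ProtocolParams(
        tau=tau,
        delta=delta,
        accuracies=panel.reader_accuracies(),
        tie_rule=config.tie_rule,
    )


def evaluate_team(
    panel: Panel, team: Team, protocol: str, params: ProtocolParams
) -> MetricSet:
    """Six-metric summary of one team under one protocol on a panel."""
    decisions, judgments = apply_protocol(panel, team, protocol, params)
    return metric_set(decisions, judgments, panel.gold)


def evaluate_teams(
    panel: Panel,
    teams: Sequence[Team],
    protocols: Sequence[str],
    params: ProtocolParams,
) -> pd.DataFrame:
    """Per-(team, protocol) metric table, full precision, in percent."""
    rows = []
    for team in teams:
        for protocol in protocols:
            ms = evaluate_team(panel, team, protocol, params)
            rows.append(
                {
                    "first": team.first,
                    "second": team.second,
                    "third": team.third,
                    "protocol": protocol,
                    **ms.as_dict(),
                }
            )
    return pd.DataFrame(rows)


def benchmark_metrics(panel: Panel, reader_id: str) -> MetricSet:
    """A single reader evaluated as a one-judgment-per-case 'team'."""
    arr = panel.reader_arrays(reader_id)
    n = len(panel.cases)
    return metric_set(arr["decision"], np.ones(n, dtype=np.int64), panel.gold)


def mean_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Sample mean with a t-distribution confidence interval."""
    x = np.asarray(values, dtype=float)
    m = float(x.mean())
    if x.size < 2 or x.std(ddof=1) == 0.0:
        return m, m, m
    half = float(
        t_dist.ppf(0.5 + level / 2.0, x.size - 1) * x.std(ddof=1) / np.sqrt(x.size)
    )
    return m, m - half, m + half


def aggregate_metrics(by_team: pd.DataFrame) -> pd.DataFrame:
    """Per-(protocol, metric) mean and 95% CI over teams."""
    rows = []
    for protocol, grp in by_team.groupby("protocol", sort=False):
        for metric in METRIC_NAMES:
            m, lo, hi = mean_ci(grp[metric].to_numpy())
            rows.append(
                {
                    "protocol": protocol,
                    "metric": metric,
                    "mean": m,
                    "ci_low": lo,
                    "ci_high": hi,
                    "n_teams": len(grp),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class Experiment1Result:
    metrics_by_team: pd.DataFrame
    aggregates: pd.DataFrame
    tests: pd.DataFrame
    benchmark: MetricSet
    params: ProtocolParams
    teams: list[Team] = field(default_factory=list)


def run_experiment_1(
    panel: Panel,
    config: ExperimentConfig | None = None,
    humans: Sequence[str] | None = None,
) -> Experiment1Result:
    """Teams-vs-strong-machine experiment over all ordered human pairs."""
    config = config or ExperimentConfig()
    human_ids = list(humans) if humans is not None else panel.human_ids()
    for machine in (config.machine_member, config.benchmark_machine):
        if machine not in panel.profiles:
            raise ValidationError(f"panel lacks readings for {machine!r}")
    teams = enumerate_teams(human_ids, config.machine_member)
    params = resolve_params(panel, config, human_ids)
    by_team = evaluate_teams(panel, teams, config.protocols, params)
    bench = benchmark_metrics(panel, config.benchmark_machine)

    family = (
        config.family_experiment1
        if config.family_experiment1 is not None
        else len(config.protocols)
    )
    metrics = list(EXPERIMENT1_TEST_METRICS)
    if config.test_efficiency:
        metrics += ["efficiency", "f2_acc_eff"]
    test_rows = []
    for metric in metrics:
        mu0 = getattr(bench, metric)
        for protocol in config.protocols:
            vals = by_team.loc[by_team["protocol"] == protocol, metric].to_numpy()
            res = stats.one_sample_t(vals, mu0).corrected(family)
            test_rows.append(
                {
                    "metric": metric,
                    "protocol": protocol,
                    "team_mean": float(np.mean(vals)),
                    "benchmark": mu0,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_raw": res.p_raw,
                    "p_corrected": res.p_corrected,
                    "family_size": res.family_size,
                }
            )
    return Experiment1Result(
        metrics_by_team=by_team,
        aggregates=aggregate_metrics(by_team),
        tests=pd.DataFrame(test_rows),
        benchmark=bench,
        params=params,
        teams=teams,
    )


@dataclass
class Experiment2Result:
    weak_ids: list[str]
    strong_ids: list[str]
    metrics_by_team: pd.DataFrame          # includes a "group" column
    aggregates: pd.DataFrame               # per (group, protocol, metric)
    ks_pvalues: dict[str, pd.DataFrame]    # metric -> 8x8 corrected p
    ks_statistics: dict[str, pd.DataFrame]
    params: ProtocolParams


def ks_comparison_matrices(
    strong_by_team: pd.DataFrame,
    weak_by_team: pd.DataFrame,
    protocols: Sequence[str] = PROTOCOL_NAMES,
    metrics: Sequence[str] = METRIC_NAMES,
    family: int | None = None,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Per metric, the strong-rows x weak-columns KS comparison grids of
    corrected p-values and D statistics."""
    family = family if family is not None else len(protocols) ** 2
    pvals, dstats = {}, {}
    for metric in metrics:
        p = pd.DataFrame(index=list(protocols), columns=list(protocols), dtype=float)
        d = p.copy()
        for ps in protocols:
            a = strong_by_team.loc[
                strong_by_team["protocol"] == ps, metric
            ].to_numpy()
            for pw in protocols:
                b = weak_by_team.loc[
                    weak_by_team["protocol"] == pw, metric
                ].to_numpy()
                res = stats.ks_two_sample(a, b).corrected(family)
                p.loc[ps, pw] = res.p_corrected
                d.loc[ps, pw] = res.statistic
        pvals[metric] = p
        dstats[metric] = d
    return pvals, dstats


def run_experiment_2(
    panel: Panel,
    config: ExperimentConfig | None = None,
    humans: Sequence[str] | None = None,
) -> Experiment2Result:
    """Weak-vs-strong team experiment with the shared machine second
    reader."""
    config = config or ExperimentConfig()
    human_ids = list(humans) if humans is not None else panel.human_ids()
    weak, strong = split_weak_strong(panel, human_ids)
    if set(weak) & set(strong):
        raise ValidationError("weak and strong splits overlap")
    params = resolve_params(panel, config, human_ids)

    frames = []
    for group, ids in (("strong", strong), ("weak", weak)):
        teams = enumerate_teams(ids, config.machine_member)
        df = evaluate_teams(panel, teams, config.protocols, params)
        df.insert(0, "group", group)
        frames.append(df)
    by_team = pd.concat(frames, ignore_index=True)

    agg_frames = []
    for group, grp in by_team.groupby("group", sort=False):
        agg = aggregate_metrics(grp)
        agg.insert(0, "group", group)
        agg_frames.append(agg)

    pvals, dstats = ks_comparison_matrices(
        by_team[by_team["group"] == "strong"],
        by_team[by_team["group"] == "weak"],
        protocols=config.protocols,
        family=config.family_experiment2,
    )
    return Experiment2Result(
        weak_ids=weak,
        strong_ids=strong,
        metrics_by_team=by_team,
        aggregates=pd.concat(agg_frames, ignore_index=True),
        ks_pvalues=pvals,
        ks_statistics=dstats,
        params=params,
    )


def sweep_panel_size(
    panel: Panel,
    sizes: Sequence[int] = (1, 3, 5, 7, 9),
    reader_ids: Sequence[str] | None = None,
    max_groups: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """All-readers majority accuracy for groups of varying odd size.

    For each size k, evaluates the always-consulted majority over all
    k-subsets of the readers (or a random sample of ``max_groups`` of
    them) and reports the mean, minimum and maximum group accuracy (%).
    """
    ids = list(reader_ids) if reader_ids is not None else panel.human_ids()
    gold = panel.gold
    decision_rows = {r: panel.reader_arrays(r)["decision"] for r in ids}
    rng = np.random.default_rng(seed)
    rows = []
    for k in sizes:
        if k % 2 == 0 or k < 1:
            raise ValidationError(f"group sizes must be odd and >= 1, got {k}")
        if k > len(ids):
            raise ValidationError(
                f"group size {k} exceeds available readers ({len(ids)})"
            )
        groups = list(combinations(ids, k))
        if max_groups is not None and len(groups) > max_groups:
            pick = rng.choice(len(groups), size=max_groups, replace=False)
            groups = [groups[i] for i in sorted(pick)]
        accs = np.array(
            [
                100.0
                * (
                    majority_panel_decisions(
                        np.vstack([decision_rows[r] for r in grp])
                    )
                    == gold
                ).mean()
                for grp in groups
            ]
        )
        rows.append(
            {
                "size": k,
                "n_groups": len(groups),
                "mean_accuracy": float(accs.mean()),
                "min_accuracy": float(accs.min()),
                "max_accuracy": float(accs.max()),
            }
        )
    return pd.DataFrame(rows)
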