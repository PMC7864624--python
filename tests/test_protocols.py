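"""Protocol semantics against independently coded brute-force oracles:
exhaustive truth tables over decision combinations, confidence orderings
and threshold regimes, plus the reduction and symmetry properties."""

from collections import Counter
from itertools import product

import numpy as np
import pytest

from doubleread import (
    ABNORMAL,
    NORMAL,
    ProtocolParams,
    Team,
    ValidationError,
    apply_protocol,
    cautious,
    compute_delta,
    compute_tau,
    generate_panel,
    majority_panel,
    or_rule,
    presumptuous,
    sensitivity_oriented,
    simple_majority,
    specificity_oriented,
    weighted_majority,
)
from doubleread.panel import Reading, ReaderProfile

from conftest import build_manual_panel

TRIPLES = list(product([NORMAL, ABNORMAL], repeat=3))


def R(rid, dec, conf=3, compl=2):
    return Reading(rid, "c0", dec, conf, compl)


def majority3_oracle(decs):
    return Counter(decs).most_common(1)[0][0] if len(set(decs)) == 1 else (
        ABNORMAL if sum(decs) >= 2 else NORMAL
    )


class TestSimpleMajority:
    @pytest.mark.parametrize("d1,d2,d3", TRIPLES)
    def test_truth_table(self, d1, d2, d3):
        out = simple_majority(R("a", d1), R("b", d2), R("c", d3))
        if d1 == d2:
            assert (out.decision, out.judgments) == (d1, 2)
            assert out.involved == ("a", "b")
        else:
            assert out.decision == majority3_oracle([d1, d2, d3])
            assert out.judgments == 3

    def test_mismatched_case_rejected(self):
        with pytest.raises(ValidationError):
            simple_majority(
                R("a", 0), Reading("b", "c1", 0, 3, 2), R("c", 0)
            )

    def test_duplicate_reader_rejected(self):
        with pytest.raises(ValidationError):
            simple_majority(R("a", 0), R("a", 1), R("c", 0))


class TestWeightedMajority:
    @pytest.mark.parametrize("d1,d2,d3", TRIPLES)
    def test_equal_weights_reduce_to_simple_majority(self, d1, d2, d3):
        w = {"a": 0.5, "b": 0.5, "c": 0.5}
        out = weighted_majority(R("a", d1), R("b", d2), R("c", d3), w)
        ref = simple_majority(R("a", d1), R("b", d2), R("c", d3))
        assert (out.decision, out.judgments) == (ref.decision, ref.judgments)

    def test_dominant_weight_overrules_pair(self):
        w = {"a": 0.9, "b": 0.1, "c": 0.1}
        out = weighted_majority(R("a", ABNORMAL), R("b", NORMAL), R("c", NORMAL), w)
        assert (out.decision, out.judgments) == (ABNORMAL, 3)

    def test_random_grid_matches_argmax_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            decs = rng.integers(0, 2, 3)
            w = dict(zip("abc", rng.random(3)))
            out = weighted_majority(
                R("a", decs[0]), R("b", decs[1]), R("c", decs[2]), w
            )
            if decs[0] == decs[1]:
                assert (out.decision, out.judgments) == (decs[0], 2)
            else:
                w_pos = sum(w[r] for r, d in zip("abc", decs) if d == ABNORMAL)
                w_neg = sum(w[r] for r, d in zip("abc", decs) if d == NORMAL)
                expected = ABNORMAL if w_pos > w_neg else NORMAL if w_neg > w_pos \
                    else ABNORMAL  # default tie rule errs abnormal
                assert (out.decision, out.judgments) == (expected, 3)

    def test_exact_tie_follows_tie_rule(self):
        w = {"a": 0.3, "b": 0.15, "c": 0.15}
        args = (R("a", ABNORMAL), R("b", NORMAL), R("c", NORMAL))
        assert weighted_majority(*args, w, tie_rule="abnormal_wins").decision == ABNORMAL
        assert weighted_majority(*args, w, tie_rule="normal_wins").decision == NORMAL

    def test_all_zero_weights_fall_back_to_majority_with_note(self):
        w = {"a": 0.0, "b": 0.0, "c": 0.0}
        out = weighted_majority(R("a", ABNORMAL), R("b", NORMAL), R("c", NORMAL), w)
        assert out.decision == NORMAL  # simple majority of the three
        assert out.note == "zero_weights_fallback"

    def test_negative_weight_rejected(self):
        with pytest.raises(ValidationError):
            weighted_majority(
                R("a", 0), R("b", 1), R("c", 0), {"a": -1.0, "b": 0.5, "c": 0.5}
            )


class TestAsymmetricProtocols:
    @pytest.mark.parametrize("d1,d2,d3", TRIPLES)
    def test_specificity_oriented_truth_table(self, d1, d2, d3):
        out = specificity_oriented(R("a", d1), R("b", d2), R("c", d3))
        if d1 == NORMAL:
            expected = (NORMAL, 1)
        elif d2 == ABNORMAL:
            expected = (ABNORMAL, 2)
        else:
            expected = (majority3_oracle([d1, d2, d3]), 3)
        assert (out.decision, out.judgments) == expected

    @pytest.mark.parametrize("d1,d2,d3", TRIPLES)
    def test_sensitivity_oriented_truth_table(self, d1, d2, d3):
        out = sensitivity_oriented(R("a", d1), R("b", d2), R("c", d3))
        if d1 == ABNORMAL:
            expected = (ABNORMAL, 1)
        elif d2 == NORMAL:
            expected = (NORMAL, 2)
        else:
            expected = (majority3_oracle([d1, d2, d3]), 3)
        assert (out.decision, out.judgments) == expected

    @pytest.mark.parametrize("d1,d2,d3", TRIPLES)
    def test_label_swap_symmetry(self, d1, d2, d3):
        spec = specificity_oriented(R("a", d1), R("b", d2), R("c", d3))
        mirr = sensitivity_oriented(R("a", 1 - d1), R("b", 1 - d2), R("c", 1 - d3))
        assert spec.decision == 1 - mirr.decision
        assert spec.judgments == mirr.judgments

    @pytest.mark.parametrize("d1,d2", list(product([0, 1], repeat=2)))
    def test_or_rule_is_logical_or(self, d1, d2):
        out = or_rule(R("a", d1), R("b", d2))
        assert out.decision == (d1 | d2)
        assert out.judgments == (1 if d1 == ABNORMAL else 2)
        assert out.judgments == len(out.involved)


class TestConfidenceProtocols:
    @pytest.mark.parametrize("tau", [0.0, 0.17, 0.3, 1.0])
    @pytest.mark.parametrize("delta", [0.0, 0.5, 0.7, 1.0])
    def test_cautious_predicate_grid(self, tau, delta):
        # exhaustive over decisions x confidence levels x complexity levels
        for d1, d2, d3 in TRIPLES:
            for c1, c2 in product(range(1, 6), repeat=2):
                for k1, k2 in product([1, 4], repeat=2):
                    r1, r2, r3 = (
                        R("a", d1, c1, k1), R("b", d2, c2, k2), R("c", d3)
                    )
                    out = cautious(r1, r2, r3, tau, delta)
                    gap = abs(r1.confidence - r2.confidence)
                    mean_compl = (r1.complexity + r2.complexity) / 2
                    shortcut = gap >= tau and mean_compl <= delta and c1 != c2
                    if shortcut:
                        expected = (d1 if c1 > c2 else d2, 2)
                    else:
                        expected = (majority3_oracle([d1, d2, d3]), 3)
                    assert (out.decision, out.judgments) == expected

    def test_cautious_impossible_gap_reduces_to_three_reader_majority(self):
        for d1, d2, d3 in TRIPLES:
            for c1, c2 in product(range(1, 6), repeat=2):
                out = cautious(R("a", d1, c1), R("b", d2, c2), R("c", d3), 1.5, 1.0)
                ref = majority3_oracle([d1, d2, d3])
                assert (out.decision, out.judgments) == (ref, 3)

    def test_presumptuous_grid(self):
        for d1, d2, d3 in TRIPLES:
            for c1, c2 in product(range(1, 6), repeat=2):
                out = presumptuous(R("a", d1, c1), R("b", d2, c2), R("c", d3))
                if c1 == c2:
                    assert (out.decision, out.judgments) == (
                        majority3_oracle([d1, d2, d3]), 3
                    )
                else:
                    assert (out.decision, out.judgments) == (
                        d1 if c1 > c2 else d2, 2
                    )

    def test_cautious_tau0_delta1_matches_presumptuous_off_ties(self):
        for d1, d2, d3 in TRIPLES:
            for c1, c2 in product(range(1, 6), repeat=2):
                if c1 == c2:
                    continue
                a = cautious(R("a", d1, c1), R("b", d2, c2), R("c", d3), 0.0, 1.0)
                b = presumptuous(R("a", d1, c1), R("b", d2, c2), R("c", d3))
                assert (a.decision, a.judgments) == (b.decision, b.judgments)


class TestMajorityPanel:
    def test_single_reading_passthrough(self):
        assert majority_panel([R("a", ABNORMAL)]) == ABNORMAL

    def test_all_quintuples_match_counting_oracle(self):
        for decs in product([0, 1], repeat=5):
            readings = [R(f"r{i}", d) for i, d in enumerate(decs)]
            assert majority_panel(readings) == (1 if sum(decs) >= 3 else 0)

    def test_even_count_rejected(self):
        with pytest.raises(ValidationError):
            majority_panel([R("a", 0), R("b", 1)])


class TestThresholdFormulas:
    def test_constant_confidence_gives_zero_tau(self):
        rng = np.random.default_rng(2)
        dec = {f"r{i}": rng.integers(0, 2, 10) for i in range(3)}
        panel = build_manual_panel(dec, rng.integers(0, 2, 10))
        assert compute_tau(panel, panel.reader_ids) == 0.0

    def test_single_pair_single_case(self):
        dec = {"r0": [0], "r1": [1]}
        conf = {"r0": np.array([2]), "r1": np.array([4])}  # 0.25 vs 0.75
        panel = build_manual_panel(dec, [1], conf_levels=conf)
        assert compute_tau(panel, ["r0", "r1"]) == pytest.approx(0.5)

    def test_extreme_complexities(self):
        dec = {"r0": [0, 1], "r1": [1, 0]}
        hi = {"r0": np.array([4, 4]), "r1": np.array([4, 4])}
        lo = {"r0": np.array([1, 1]), "r1": np.array([1, 1])}
        assert compute_delta(
            build_manual_panel(dec, [0, 1], compl_levels=hi), ["r0", "r1"]
        ) == pytest.approx(1.0)
        assert compute_delta(
            build_manual_panel(dec, [0, 1], compl_levels=lo), ["r0", "r1"]
        ) == pytest.approx(0.0)

    def test_brute_force_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        n, readers = 6, 4
        ids = [f"r{i}" for i in range(readers)]
        dec = {r: rng.integers(0, 2, n) for r in ids}
        conf = {r: rng.integers(1, 6, n) for r in ids}
        compl = {r: rng.integers(1, 5, n) for r in ids}
        panel = build_manual_panel(dec, rng.integers(0, 2, n),
                                   conf_levels=conf, compl_levels=compl)
        # independent hand enumeration
        tau_terms, delta_terms = [], []
        for c in range(n):
            gaps = []
            for i in range(readers):
                for j in range(i + 1, readers):
                    gaps.append(abs((conf[ids[i]][c] - conf[ids[j]][c]) / 4.0))
            tau_terms.append(np.mean(gaps))
            delta_terms.append(np.mean([(compl[r][c] - 1) / 3.0 for r in ids]))
        assert compute_tau(panel, ids) == pytest.approx(np.mean(tau_terms))
        assert compute_delta(panel, ids) == pytest.approx(np.mean(delta_terms))

    def test_too_few_readers_rejected(self):
        dec = {"r0": [0, 1]}
        panel = build_manual_panel(dec, [0, 1])
        with pytest.raises(ValidationError):
            compute_tau(panel, ["r0"])


class TestVectorScalarConsistency:
    """The panel-wide vector path and the per-reading scalar path must be
    two views of the same semantics."""

    def test_apply_protocol_matches_scalar_ops_on_random_panel(self):
        profs = [ReaderProfile(f"r{i}", "human", 0.75, 0.75, 0.3) for i in range(3)]
        panel = generate_panel(profs, 60, 0.5, seed=21)
        team = Team("r0", "r1", "r2")
        params = ProtocolParams(
            tau=0.17, delta=0.7, accuracies=panel.reader_accuracies()
        )
        scalar_ops = {
            "majority": lambda r1, r2, r3: simple_majority(r1, r2, r3),
            "acc_weighted": lambda r1, r2, r3: weighted_majority(
                r1, r2, r3, params.accuracies
            ),
            "conf_weighted": lambda r1, r2, r3: weighted_majority(
                r1, r2, r3,
                {r.reader_id: r.confidence for r in (r1, r2, r3)},
            ),
            "specific": specificity_oriented,
            "sensitive": sensitivity_oriented,
            "cautious": lambda r1, r2, r3: cautious(r1, r2, r3, 0.17, 0.7),
            "presumptuous": presumptuous,
            "or_rule": lambda r1, r2, r3: or_rule(r1, r2),
        }
        for name, op in scalar_ops.items():
            dec, j = apply_protocol(panel, team, name, params)
            for idx, cid in enumerate(panel.case_ids):
                rs = [panel.reading(r, cid) for r in team.members]
                out = op(*rs)
                assert out.decision == dec[idx], (name, cid)
                assert out.judgments == j[idx], (name, cid)

    def test_judgment_count_ranges(self, study_panel):
        team = Team("reader_01", "machine_mobilenet", "reader_02")
        params = ProtocolParams(tau=0.17, delta=0.7,
                                accuracies=study_panel.reader_accuracies())
        ranges = {
            "majority": {2, 3}, "acc_weighted": {2, 3}, "conf_weighted": {2, 3},
            "specific": {1, 2, 3}, "sensitive": {1, 2, 3},
            "cautious": {2, 3}, "presumptuous": {2, 3}, "or_rule": {1, 2},
        }
        for name, allowed in ranges.items():
            _, j = apply_protocol(study_panel, team, name, params)
            assert set(np.unique(j)) <= allowed

    def test_or_rule_sensitivity_dominates_members(self, study_panel):
        team = Team("reader_04", "machine_mobilenet", "reader_02")
        dec, _ = apply_protocol(study_panel, team, "or_rule")
        gold = study_panel.gold
        pos = gold == ABNORMAL
        team_sens = (dec[pos] == ABNORMAL).mean()
        for member in (team.first, team.second):
            d = study_panel.reader_arrays(member)["decision"]
            assert team_sens >= (d[pos] == ABNORMAL).mean()

    def test_unknown_protocol_rejected(self, study_panel):
        with pytest.raises(ValidationError):
            apply_protocol(
                study_panel, Team("reader_01", "machine_mobilenet", "reader_02"),
                "consensus",
            )
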