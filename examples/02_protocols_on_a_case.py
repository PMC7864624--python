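"""Run all eight double-reading protocols on a single disputed case.

The first reader calls the case abnormal with middling confidence, the
machine second reader disagrees confidently, and the human arbiter sides
with the machine.  Each protocol resolves the conflict differently and at
a different cost in judgments."""

from doubleread import (
    Reading,
    cautious,
    or_rule,
    presumptuous,
    sensitivity_oriented,
    simple_majority,
    specificity_oriented,
    weighted_majority,
)

r1 = Reading("radiologist_a", "case_0042", decision=1,
             confidence_level=3, complexity_level=2)
r2 = Reading("machine", "case_0042", decision=0,
             confidence_level=5, complexity_level=1)
r3 = Reading("radiologist_b", "case_0042", decision=0,
             confidence_level=4, complexity_level=2)

accuracies = {"radiologist_a": 0.81, "machine": 0.82, "radiologist_b": 0.84}
confidences = {r.reader_id: r.confidence for r in (r1, r2, r3)}

outcomes = {
    "majority": simple_majority(r1, r2, r3),
    "acc_weighted": weighted_majority(r1, r2, r3, accuracies),
    "conf_weighted": weighted_majority(r1, r2, r3, confidences),
    "specific": specificity_oriented(r1, r2, r3),
    "sensitive": sensitivity_oriented(r1, r2, r3),
    "cautious": cautious(r1, r2, r3, tau=0.17, delta=0.70),
    "presumptuous": presumptuous(r1, r2, r3),
    "or_rule": or_rule(r1, r2),
}

print(f"{'protocol':<15}{'decision':<12}{'judgments':<11}involved")
for name, out in outcomes.items():
    label = "abnormal" if out.decision else "normal"
    print(f"{name:<15}{label:<12}{out.judgments:<11}{', '.join(out.involved)}")
print("\nJudgments is the workload each protocol spends on the case; "
      "efficiency divides correct calls by this total.")
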