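"""Second experiment: can teams of weaker readers rival teams of stronger
readers sharing the same machine?  Splits the humans into accuracy-ranked
halves, evaluates 20 teams per half, and compares every strong-protocol
score distribution against every weak-protocol one with exact
Kolmogorov-Smirnov tests."""

import doubleread as dr

panel = dr.generate_panel(dr.default_study_profiles(), 427, 0.5, seed=1)
result = dr.run_experiment_2(panel)

print("weak readers:  ", ", ".join(result.weak_ids))
print("strong readers:", ", ".join(result.strong_ids), "\n")

agg = result.aggregates
table = agg[agg.metric == "accuracy"].pivot(index="protocol", columns="group",
                                            values="mean")
print("mean team accuracy (%)")
print(table.round(2).to_string(), "\n")

p = result.ks_pvalues["accuracy"]
print("corrected KS p, same protocol strong vs weak (diagonal):")
for name in p.index:
    tag = "significant" if p.loc[name, name] < 0.05 else "n.s."
    print(f"  {name:<15}{p.loc[name, name]:.3f}  ({tag})")
print("\nAn n.s. diagonal cell means the weak teams are statistically "
      "indistinguishable from the strong ones under that protocol.")
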