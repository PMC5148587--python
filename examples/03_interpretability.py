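"""Readability and comprehensibility indices of a trained rule base.

Trains on the separable fixture, then reports per-rule coverage,
accuracy, goodness and the cofiring comprehensibility index, and shows
rule simplification at work on a redundant rule base.
"""

import copy

import frfiwsa as fw

dataset, _ = fw.separable_toy()
ranking = fw.f_information_ranking(dataset)
filtered = fw.filter_top_genes(dataset, ranking, 2)
result = fw.optimize(filtered, fw.RunConfig(swarm_size=20, iterations=50,
                                            seed=0))
kb = result.kb

stats = fw.rule_stats(kb, filtered)
averages = fw.ruleset_averages(kb, filtered)
report = fw.cofiring_matrix(kb, filtered)
ci, cfci, _, cfci_rule = fw.comprehensibility(report, threshold=0.5,
                                              normalize=True)

print("rule  R_cov   R_acc   R_gud   CFCI")
for s in stats:
    if not kb.rules[s.rule_index].is_active:
        continue
    print(f"R{s.rule_index + 1:<3d}  {s.r_cov:.3f}  {s.r_acc:.3f}  "
          f"{s.r_gud:+.3f}  {cfci_rule[s.rule_index]:.3f}")
print(f"\nA_rl (premises/rule)      : {averages.a_rl:.2f}")
print(f"A_fr (firing events/rule) : {averages.a_fr:.2f}")
print(f"A_cfd (mean confidence)   : {averages.a_cfd:.3f}")
print(f"ruleset CI {ci:.3f} -> CFCI {cfci:.3f} "
      "(1 = no premise-weighted cofiring at all)")

# duplicate a rule, then let simplification fuse it away
bloated = copy.deepcopy(kb)
bloated.rules.append(copy.deepcopy(next(r for r in kb.rules if r.is_active)))
before = fw.evaluate_kb(bloated, filtered)
slim = fw.simplify_rules(bloated, filtered)
after = fw.evaluate_kb(slim, filtered)
print(f"\nsimplification: {before.rs} rules -> {after.rs} rules, "
      f"accuracy {before.accuracy:.2f} -> {after.accuracy:.2f} "
      "(accepted only because accuracy did not drop)")
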