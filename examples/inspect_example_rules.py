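"""Inspect the bundled species-level example rule set.

Loads the 25 published-style decision rules over bacterial 4-mer
frequencies, reports their size statistics, and applies one rule to show
the half-open interval semantics.
"""

import kmerlogic as kl

model = kl.load_example_species_rules()
stats = kl.model_complexity(model)
print(f"{stats['n_rules']} rules, "
      f"{stats['mean_literals_per_rule']:.2f} literals per rule on average, "
      f"{stats['n_distinct_kmers']} distinct 4-mers used\n")

(hp,) = [r for r in model.rules if r.conclusion == "H. pylori"]
single = kl.RuleModel(rules=[hp], default_class="other")
print("rule:", kl.render_model(single))
for f in (20e-5, 42.82e-5):
    print(f"f(GTAC) = {f:.6f}  ->  {single.predict({'GTAC': f})}")
print("\nthe upper bound is excluded: intervals are half-open [lo, hi),")
print("so a frequency exactly at the bound falls outside the rule.")
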