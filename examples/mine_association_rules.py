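"""Mine two- and three-herb association rules from a fixture corpus.

The fixture realizes published occurrence counts for the strongest herb
combination in internal alopecia prescriptions (N=312): Polygonum
multiflorum occurs 175 times, Angelica sinensis 171 times, and they
co-occur 120 times. Support is the fraction of prescriptions containing
both herbs, confidence the fraction of the antecedent's prescriptions that
also contain the consequent, and lift the ratio of observed to expected
co-occurrence under independence (>1 means the herbs travel together).
"""

from herbnet import mine_rules, top_rules
from herbnet.datasets import pair_fixture, triple_fixture

corpus = pair_fixture({"Polygonum", "Angelica"})
print(f"corpus: {corpus.n} prescriptions")
for r in top_rules(mine_rules(corpus, rule_len=2), 1):
    print(f"{'+'.join(r.antecedent)} -> {'+'.join(r.consequent)}: "
          f"support={r.support:.3f} confidence={r.confidence:.3f} "
          f"lift={r.lift:.3f} frequency={r.frequency}")

corpus3 = triple_fixture({"Ligusticum", "Polygonum", "Angelica"})
rule = next(r for r in mine_rules(corpus3, rule_len=3)
            if set(r.itemset) == {"Ligusticum", "Polygonum", "Angelica"})
print(f"{'+'.join(rule.antecedent)} -> {'+'.join(rule.consequent)}: "
      f"support={rule.support:.3f} confidence={rule.confidence:.3f} "
      f"lift={rule.lift:.3f} frequency={rule.frequency}")
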