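"""Rebalance a generated-negative set against positive compound frequencies.

Random pair generation over-uses some compounds relative to the positive
set.  The rebalancing removes each over-represented compound's excess
pairs (keeping a MaxMin-diverse subset) and substitutes experimentally
verified negatives, conserving the total count.
"""

from cocrystal_gcn import LabeledPair, PairDataset, SyntheticSpec, generate_dataset
from cocrystal_gcn.data import compound_frequency, rebalance_negatives

skewed = generate_dataset(SyntheticSpec(n_molecules=60, n_pos=60, n_neg=150,
                                        label_noise=0.0, seed=11, skew=1.5))
gen_neg = PairDataset([LabeledPair(p.api_smiles, p.cf_smiles, 0, "gen_neg")
                       for p in skewed if p.label == 0])
csd_pos = PairDataset([LabeledPair(p.api_smiles, p.cf_smiles, 1, "csd_pos")
                       for p in skewed if p.label == 1])
gen_keys = {p.key() for p in gen_neg}
extra = generate_dataset(SyntheticSpec(n_molecules=60, n_pos=10, n_neg=60,
                                       label_noise=0.0, seed=12))
exp_neg = PairDataset([LabeledPair(p.api_smiles, p.cf_smiles, 0, "exp_neg")
                       for p in extra if p.label == 0 and p.key() not in gen_keys][:30])

out = rebalance_negatives(gen_neg, csd_pos, exp_neg, remove_total=30)

top_before = max(compound_frequency(gen_neg).items(), key=lambda kv: kv[1])
after = compound_frequency(PairDataset([p for p in out if p.source == "gen_neg"]))
print(f"negatives: {len(gen_neg)} generated - 30 removed + {len(exp_neg)} experimental = {len(out)}")
print(f"most over-used compound {top_before[0]}: frequency {top_before[1]} -> {after.get(top_before[0], 0)}")
# The output size is conserved exactly and the worst offender's frequency
# drops towards its frequency among the positives.
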