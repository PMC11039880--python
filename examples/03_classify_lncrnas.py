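"""Positional subclassification of lncRNA loci.

Builds a small annotated genome with a known subclass mix, classifies every
lncRNA against the protein-coding genes, and compares the recovered
proportions to the planted mix (placement is constructed to be unambiguous,
so recovery is exact).
"""

from collections import Counter

from cerna_weaver import MoleculeClass, classify_lncrna, subclass_summary
from cerna_weaver.synth import SyntheticConfig, generate_experiment

exp = generate_experiment(SyntheticConfig(
    n_lnc=200, n_mrna=400, n_mir=30, de_fraction=0.05,
    n_planted_triplets_up=2, n_planted_triplets_down=2, n_decoy_triplets=1,
    seed=7,
))
genes = [f for f in exp.features if f.molecule_class is MoleculeClass.mRNA]
lncs = [f for f in exp.features if f.molecule_class is MoleculeClass.lncRNA]

assignments = [classify_lncrna(l, genes) for l in lncs]
props = subclass_summary(assignments)
print("recovered subclass proportions:")
for sc, p in sorted(props.items(), key=lambda kv: -kv[1]):
    print(f"  {sc.value:20s} {p:.3f}")

planted = Counter(exp.truth.subclasses.values())
agree = sum(a is exp.truth.subclasses[l.feature_id] for l, a in zip(lncs, assignments))
print(f"\nagreement with planted subclasses: {agree}/{len(lncs)}")
print("intergenic dominates, with natural antisense and intronic antisense "
      "next — the mix typical of array-profiled lncRNAs.")
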