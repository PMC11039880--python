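"""Recovery and calibration measurements against generator ground truth.

These helpers run the analysis modules on a synthetic experiment and score
them against its truth manifest: planted-DE recovery and false-positive rates,
exact sponge-triplet recovery, cis-pair recovery, and subclass recovery.

Differential expression is scored on the generated matrices directly: the
generator emits every column on a common intensity scale, so quantile
normalization (which corrects cross-sample technical bias the generator does
not simulate) is a no-op in expectation and is not applied here; its defining
distributional property is validated separately.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cerna import CernaParams, build_cerna
from .diffexpr import DEThresholds, differential_expression
from .genomic import cis_pairs, classify_lncrna
from .model import CANONICAL_COMPARISONS, DERecord, DEStatus, MoleculeClass
from .synth import SyntheticExperiment


def run_de(exp: SyntheticExperiment, thresholds: DEThresholds = DEThresholds()):
    """Per-class DE records for all canonical comparisons on the raw matrices."""
    de: dict[MoleculeClass, list[DERecord]] = {}
    for mc, matrix in exp.matrices.items():
        records: list[DERecord] = []
        for comparison in CANONICAL_COMPARISONS:
            records += differential_expression(matrix, comparison, thresholds)
        de[mc] = records
    return de


@dataclass
class RecoveryRates:
    n_planted: int
    n_recovered: int
    n_null: int
    n_false_positive: int

    @property
    def recovery(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else 1.0

    @property
    def false_positive_rate(self) -> float:
        return self.n_false_positive / self.n_null if self.n_null else 0.0


def de_recovery(exp: SyntheticExperiment, thresholds: DEThresholds = DEThresholds()) -> RecoveryRates:
    """Planted-status recovery and false-positive rates over all classes and
    comparisons (a recovered feature must carry the planted direction)."""
    de = run_de(exp, thresholds)
    planted = recovered = null = fp = 0
    for mc, records in de.items():
        for r in records:
            truth = exp.truth.de_status[mc.value][r.comparison].get(r.feature_id)
            if truth is None:
                null += 1
                if r.status is not DEStatus.ns:
                    fp += 1
            else:
                planted += 1
                if r.status.value == truth:
                    recovered += 1
    return RecoveryRates(planted, recovered, null, fp)


def null_p_fraction(exp: SyntheticExperiment, alpha: float = 0.05) -> tuple[int, int]:
    """(count of p <= alpha, total tests) over all classes and comparisons;
    meaningful when the experiment was generated without planted effects."""
    de = run_de(exp)
    hits = total = 0
    for records in de.values():
        for r in records:
            total += 1
            if r.p <= alpha:
                hits += 1
    return hits, total


def triplet_recovery(
    exp: SyntheticExperiment,
    params: CernaParams = CernaParams(),
    thresholds: DEThresholds = DEThresholds(),
):
    """(recovered, planted) sponge triplet identity sets over both directions."""
    de = run_de(exp, thresholds)
    recovered = set()
    for direction in ("up_module", "down_module"):
        triplets, _ = build_cerna(
            de[MoleculeClass.lncRNA], de[MoleculeClass.miRNA], de[MoleculeClass.mRNA],
            exp.interactions, params, direction, thresholds,
        )
        recovered |= {(t.comparison, t.lncRNA_id, t.miRNA_id, t.mRNA_id) for t in triplets}
    planted = {
        (t.comparison, t.lncRNA_id, t.miRNA_id, t.mRNA_id) for t in exp.truth.triplets
    }
    return recovered, planted


def cis_recovery(exp: SyntheticExperiment, thresholds: DEThresholds = DEThresholds(), window: int = 300_000):
    """(recovered, planted) cis-pair identity sets on noiseless DE calls."""
    de = run_de(exp, thresholds)
    pairs = cis_pairs(
        de[MoleculeClass.lncRNA], de[MoleculeClass.mRNA], exp.features, window=window
    )
    recovered = {(p.lncRNA_id, p.mRNA_id, p.comparison) for p in pairs}
    planted = {(p.lncRNA_id, p.mRNA_id, p.comparison) for p in exp.truth.cis_pairs}
    return recovered, planted


def subclass_recovery(exp: SyntheticExperiment) -> float:
    """Fraction of lncRNAs classified into their planted subclass."""
    genes = [f for f in exp.features if f.molecule_class is MoleculeClass.mRNA]
    lncs = [f for f in exp.features if f.molecule_class is MoleculeClass.lncRNA]
    hits = sum(
        classify_lncrna(l, genes) is exp.truth.subclasses[l.feature_id] for l in lncs
    )
    return hits / len(lncs)
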