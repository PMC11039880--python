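"""Genomic context of lncRNA loci.

Positional subclassification of lncRNAs relative to protein-coding genes
(intergenic, natural antisense, intronic antisense/sense, sense overlapping,
bidirectional), chromosome distributions, and enumeration of cis lncRNA-mRNA
pairs within a proximity window (default < 300 kb) among features that are
differentially expressed in the same comparison.
"""

from __future__ import annotations

import enum
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .model import DERecord, DEStatus, GenomicFeature, MoleculeClass, Strand


class LncSubclass(str, enum.Enum):
    intergenic = "intergenic"
    natural_antisense = "natural_antisense"
    intronic_antisense = "intronic_antisense"
    intronic_sense = "intronic_sense"
    sense_overlapping = "sense_overlapping"
    bidirectional = "bidirectional"


def _spans_overlap(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def _exonic_overlap(lnc: GenomicFeature, gene: GenomicFeature) -> bool:
    for la, lb in lnc.exon_intervals():
        for ga, gb in gene.exon_intervals():
            if _spans_overlap(la, lb, ga, gb):
                return True
    return False


def _divergent_promoter(lnc: GenomicFeature, gene: GenomicFeature, window: int) -> bool:
    """Head-to-head arrangement: opposite strands, non-overlapping spans, the
    lncRNA TSS within ``window`` bp of the gene TSS on its upstream side."""
    if lnc.strand == gene.strand:
        return False
    if _spans_overlap(lnc.start, lnc.end, gene.start, gene.end):
        return False
    if abs(lnc.tss - gene.tss) > window:
        return False
    if gene.strand is Strand.plus:
        return lnc.strand is Strand.minus and lnc.tss <= gene.tss
    return lnc.strand is Strand.plus and lnc.tss >= gene.tss


def classify_lncrna(
    lnc: GenomicFeature,
    genes: Sequence[GenomicFeature],
    promoter_window: int = 1000,
) -> LncSubclass:
    """Assign exactly one positional subclass by fixed precedence.

    Precedence (first match wins, evaluated against all protein-coding genes):
    sense_overlapping > intronic_sense > natural_antisense > intronic_antisense
    > bidirectional > intergenic. Sense categories outrank antisense, and
    exonic overlap outranks containment-without-exon-overlap.
    """
    coding = [g for g in genes if g.molecule_class is MoleculeClass.mRNA and g.chrom == lnc.chrom]

    def any_gene(pred) -> bool:
        return any(pred(g) for g in coding)

    same = lambda g: g.strand == lnc.strand
    overlap = lambda g: _spans_overlap(lnc.start, lnc.end, g.start, g.end)
    within = lambda g: g.start <= lnc.start and lnc.end <= g.end

    if any_gene(lambda g: same(g) and _exonic_overlap(lnc, g)):
        return LncSubclass.sense_overlapping
    if any_gene(lambda g: same(g) and within(g) and not _exonic_overlap(lnc, g)):
        return LncSubclass.intronic_sense
    if any_gene(lambda g: not same(g) and _exonic_overlap(lnc, g)):
        return LncSubclass.natural_antisense
    if any_gene(lambda g: not same(g) and within(g) and not _exonic_overlap(lnc, g)):
        return LncSubclass.intronic_antisense
    if not any_gene(overlap) and any_gene(lambda g: _divergent_promoter(lnc, g, promoter_window)):
        return LncSubclass.bidirectional
    return LncSubclass.intergenic


def subclass_summary(assignments: Iterable[LncSubclass]) -> dict[LncSubclass, float]:
    """Proportion of lncRNAs per subclass (sums to 1)."""
    counts = Counter(LncSubclass(a) for a in assignments)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no subclass assignments given")
    return {sc: counts[sc] / total for sc in LncSubclass if counts[sc]}


def chromosome_summary(features: Iterable[GenomicFeature]) -> dict[str, int]:
    counts = Counter(f.chrom for f in features)
    if not counts:
        raise ValueError("no features given")
    return dict(sorted(counts.items()))


# --------------------------------------------------------------------------
# cis pairing
# --------------------------------------------------------------------------


class CisOrientation(str, enum.Enum):
    overlapping = "overlapping"
    upstream = "upstream"
    downstream = "downstream"


@dataclass(frozen=True)
class CisPair:
    """A significantly DE lncRNA within the proximity window of a significantly
    DE protein-coding gene, in the same comparison. ``orientation`` places the
    lncRNA relative to the gene's strand; strand is ignored for distance."""

    lncRNA_id: str
    mRNA_id: str
    comparison: str
    distance_bp: int
    orientation: CisOrientation
    lnc_status: DEStatus
    mrna_status: DEStatus


def span_gap(a0: int, a1: int, b0: int, b1: int) -> int:
    """Bases strictly between two half-open spans; 0 when they overlap or abut."""
    if a1 <= b0:
        return b0 - a1
    if b1 <= a0:
        return a0 - b1
    return 0


def _orientation(lnc: GenomicFeature, gene: GenomicFeature) -> CisOrientation:
    if _spans_overlap(lnc.start, lnc.end, gene.start, gene.end):
        return CisOrientation.overlapping
    lnc_is_left = lnc.end <= gene.start
    if gene.strand is Strand.plus:
        return CisOrientation.upstream if lnc_is_left else CisOrientation.downstream
    return CisOrientation.downstream if lnc_is_left else CisOrientation.upstream


def cis_pairs(
    de_lnc: Sequence[DERecord],
    de_mrna: Sequence[DERecord],
    annotation: Sequence[GenomicFeature],
    window: int = 300_000,
    distance_mode: str = "span",
) -> list[CisPair]:
    """All (lncRNA, mRNA) pairs on the same chromosome closer than ``window``,
    restricted to features with up/down status in the same comparison.

    ``distance_mode='span'`` measures the gap strictly between the two spans
    (0 when overlapping); ``'tss'`` measures |TSS - TSS|. DE features lacking
    an annotation entry are skipped with a warning.
    """
    if distance_mode not in ("span", "tss"):
        raise ValueError("distance_mode must be 'span' or 'tss'")
    by_id = {f.feature_id: f for f in annotation}
    sig = lambda rs: [r for r in rs if r.status is not DEStatus.ns]

    missing = sorted(
        {r.feature_id for r in sig(de_lnc) + sig(de_mrna) if r.feature_id not in by_id}
    )
    if missing:
        warnings.warn(
            f"{len(missing)} DE feature(s) lack coordinates and were skipped: "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
        )

    # per-chromosome interval index of annotated DE genes, expanded by window
    pairs: list[CisPair] = []
    lnc_by_cmp: dict[str, list[DERecord]] = {}
    for r in sig(de_lnc):
        if r.feature_id in by_id:
            lnc_by_cmp.setdefault(r.comparison, []).append(r)
    mrna_by_cmp: dict[str, list[DERecord]] = {}
    for r in sig(de_mrna):
        if r.feature_id in by_id:
            mrna_by_cmp.setdefault(r.comparison, []).append(r)

    for cmp_name, lnc_records in sorted(lnc_by_cmp.items()):
        mrna_records = mrna_by_cmp.get(cmp_name, [])
        trees: dict[str, IntervalTree] = {}
        for r in mrna_records:
            g = by_id[r.feature_id]
            trees.setdefault(g.chrom, IntervalTree()).addi(
                max(0, g.start - window), g.end + window, r
            )
        for lr in lnc_records:
            lnc = by_id[lr.feature_id]
            tree = trees.get(lnc.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(lnc.start, lnc.end):
                mr = hit.data
                gene = by_id[mr.feature_id]
                if distance_mode == "span":
                    dist = span_gap(lnc.start, lnc.end, gene.start, gene.end)
                else:
                    dist = abs(lnc.tss - gene.tss)
                if dist < window:
                    pairs.append(
                        CisPair(
                            lncRNA_id=lnc.feature_id,
                            mRNA_id=gene.feature_id,
                            comparison=cmp_name,
                            distance_bp=dist,
                            orientation=_orientation(lnc, gene),
                            lnc_status=lr.status,
                            mrna_status=mr.status,
                        )
                    )
    pairs.sort(key=lambda p: (p.lncRNA_id, p.mRNA_id, p.comparison))
    return pairs
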