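"""Direction-concordant ceRNA (sponge) triplet assembly.

A lncRNA acting as a competing endogenous RNA carries multiple binding sites
for a miRNA and titrates it away from its mRNA targets. The sponge-consistent
expression pattern is therefore lncRNA up / shared miRNA down / target mRNA up
(the "up module"), or its mirror image (the "down module").

Triplets are assembled per comparison from differential-expression tables and
two interaction tables: validated lncRNA-miRNA binding edges (with binding-site
counts) and miRNA-mRNA target edges (validated or predicted). Candidate sponge
lncRNAs must be expressed (raw signal > 100 by default), catalogued in a
GENCODE/Ensembl-style reference, and carry more than one binding site.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .diffexpr import DEThresholds
from .model import (
    DERecord,
    DEStatus,
    DiseaseAnnotation,
    Evidence,
    InteractionKind,
    InteractionRecord,
)


@dataclass(frozen=True)
class CernaParams:
    """Filters applied when assembling sponge triplets.

    ``binding_site_scope`` controls where the "more than one binding site"
    requirement applies: ``"lncrna"`` (default) qualifies a sponge candidate
    when its strongest miRNA edge has >= min_binding_sites and then keeps all
    of its validated edges; ``"edge"`` drops every individual edge below the
    threshold. ``mirna_direction_mode="significance_only"`` (default) calls a
    miRNA's direction from the sign of its fold change at p <= p_max, without
    the 1.5x magnitude bar; ``"full_threshold"`` defers to the DE status.
    """

    min_binding_sites: int = 2
    min_raw_intensity: float = 100.0
    require_reference_annotation: bool = True
    mirna_direction_mode: str = "significance_only"
    mrna_evidence: str = "validated_or_predicted"
    binding_site_scope: str = "lncrna"
    dedup_associations: bool = False

    def __post_init__(self) -> None:
        if self.min_binding_sites < 1:
            raise ValueError("min_binding_sites must be >= 1")
        if self.mirna_direction_mode not in ("significance_only", "full_threshold"):
            raise ValueError("mirna_direction_mode must be significance_only or full_threshold")
        if self.mrna_evidence not in ("validated_only", "validated_or_predicted"):
            raise ValueError("mrna_evidence must be validated_only or validated_or_predicted")
        if self.binding_site_scope not in ("lncrna", "edge"):
            raise ValueError("binding_site_scope must be 'lncrna' or 'edge'")


@dataclass(frozen=True)
class CernaTriplet:
    lncRNA_id: str
    miRNA_id: str
    mRNA_id: str
    binding_sites: int
    lnc_fc: float
    mir_fc: float
    mrna_fc: float
    direction: str  # up_down_up | down_up_down
    comparison: str
    mrna_evidence: str
    association_row: int = -1  # index of the mir_mrna input row this came from
    disease_terms: tuple[str, ...] = ()


@dataclass(frozen=True)
class ModuleSummary:
    """Union counts across the comparisons of one module direction.

    ``n_mrna_associations`` counts miRNA->mRNA table rows that joined into at
    least one triplet, multiplicity preserved (a gene listed twice under one
    miRNA counts twice); ``n_mrna_distinct`` collapses to distinct gene ids.
    """

    direction: str
    comparisons: tuple[str, ...]
    n_lncRNA_distinct: int
    n_miRNA_distinct: int
    n_mrna_associations: int
    n_mrna_distinct: int
    triplet_count: int

    def __post_init__(self) -> None:
        if self.n_mrna_distinct > self.n_mrna_associations:
            raise ValueError("distinct mRNA count cannot exceed association count")


def mirna_direction(
    record: DERecord,
    mode: str = "significance_only",
    p_max: float = 0.05,
    use_adjusted_p: bool = False,
) -> DEStatus:
    """Direction call for a miRNA.

    Microarray miRNA fold changes are compressed, so a sponge partner may be
    reproducibly shifted without clearing the 1.5x bar; significance_only mode
    therefore calls direction from the sign of the fold change alone at
    p <= p_max. full_threshold mode defers to the magnitude-filtered DE status.
    """
    if mode == "full_threshold":
        return record.status
    if mode != "significance_only":
        raise ValueError(f"unknown mirna direction mode {mode!r}")
    crit = record.adj_p if use_adjusted_p else record.p
    if crit <= p_max:
        if record.fc > 1.0:
            return DEStatus.up
        if record.fc < 1.0:
            return DEStatus.down
    return DEStatus.ns


def select_cerna_lncrnas(
    de_lnc: Sequence[DERecord],
    direction: DEStatus,
    params: CernaParams = CernaParams(),
) -> list[str]:
    """Sponge-candidate lncRNAs: matching status, expressed above the raw
    intensity floor, and (optionally) catalogued in the reference annotation.
    Sorted by |log2FC| descending, id ascending on ties."""
    direction = DEStatus(direction)
    picked = [
        r
        for r in de_lnc
        if r.status is direction
        and r.raw_intensity > params.min_raw_intensity
        and (r.annotated_in_reference or not params.require_reference_annotation)
    ]
    picked.sort(key=lambda r: (-abs(r.log2fc), r.feature_id))
    return [r.feature_id for r in picked]


def _by_comparison(records: Sequence[DERecord]) -> dict[str, dict[str, DERecord]]:
    out: dict[str, dict[str, DERecord]] = defaultdict(dict)
    for r in records:
        out[r.comparison][r.feature_id] = r
    return out


_MODULE_PATTERN = {
    # module -> (lnc status, mir direction, mrna status, triplet direction tag)
    "up_module": (DEStatus.up, DEStatus.down, DEStatus.up, "up_down_up"),
    "down_module": (DEStatus.down, DEStatus.up, DEStatus.down, "down_up_down"),
}


def build_cerna(
    de_lnc: Sequence[DERecord],
    de_mir: Sequence[DERecord],
    de_mrna: Sequence[DERecord],
    interactions: Sequence[InteractionRecord],
    params: CernaParams = CernaParams(),
    direction: str = "up_module",
    thresholds: DEThresholds = DEThresholds(),
) -> tuple[list[CernaTriplet], ModuleSummary]:
    """Assemble direction-concordant sponge triplets.

    A triplet (L, m, G) is emitted per miRNA->mRNA table row, per comparison,
    when: L is a selected sponge candidate in the module direction; a validated
    lncRNA-miRNA edge (L, m) passes the binding-site filter; m is called in the
    opposing direction; and the row links m to G (admissible evidence) with G
    differentially expressed in the module direction, all in one comparison.
    Interaction rows naming features never measured are skipped with a warning.
    """
    if direction not in _MODULE_PATTERN:
        raise ValueError("direction must be 'up_module' or 'down_module'")
    lnc_status, mir_dir, mrna_status, tag = _MODULE_PATTERN[direction]

    lnc_by_cmp = _by_comparison(de_lnc)
    mir_by_cmp = _by_comparison(de_mir)
    mrna_by_cmp = _by_comparison(de_mrna)
    comparisons = sorted(lnc_by_cmp)

    measured_lnc = {r.feature_id for r in de_lnc}
    measured_mir = {r.feature_id for r in de_mir}
    measured_mrna = {r.feature_id for r in de_mrna}

    lnc_mir = [
        r for r in interactions
        if r.kind is InteractionKind.lnc_mir and r.evidence is Evidence.validated
    ]
    mir_mrna_rows = [
        (i, r) for i, r in enumerate(interactions) if r.kind is InteractionKind.mir_mrna
    ]
    if params.mrna_evidence == "validated_only":
        mir_mrna_rows = [(i, r) for i, r in mir_mrna_rows if r.evidence is Evidence.validated]

    skipped = 0
    edges: dict[str, list[tuple[str, int]]] = defaultdict(list)  # lnc -> [(mir, sites)]
    for e in lnc_mir:
        targets = [t for t in e.target_id.split("|") if t]
        if e.source_id not in measured_lnc or any(t not in measured_mir for t in targets):
            skipped += 1
            continue
        for t in targets:
            edges[e.source_id].append((t, int(e.binding_sites)))

    # binding-site filter
    if params.binding_site_scope == "edge":
        edges = {
            l: [(m, s) for (m, s) in ems if s >= params.min_binding_sites]
            for l, ems in edges.items()
        }
    else:  # lncrna scope: candidate keeps all edges if its best edge qualifies
        edges = {
            l: ems
            for l, ems in edges.items()
            if ems and max(s for _, s in ems) >= params.min_binding_sites
        }

    triplets: list[CernaTriplet] = []
    joined_rows: set = set()
    for cmp_name in comparisons:
        lnc_recs = lnc_by_cmp[cmp_name]
        mir_recs = mir_by_cmp.get(cmp_name, {})
        mrna_recs = mrna_by_cmp.get(cmp_name, {})
        selected = set(select_cerna_lncrnas(list(lnc_recs.values()), lnc_status, params))

        # admissible miRNAs in this comparison: right direction + sponge edge
        sponge_edges: dict[str, list[tuple[str, int]]] = defaultdict(list)  # mir -> [(lnc, sites)]
        for l in sorted(selected):
            for (m, sites) in edges.get(l, []):
                rec = mir_recs.get(m)
                if rec is None:
                    continue
                if mirna_direction(
                    rec, params.mirna_direction_mode, thresholds.p_max, thresholds.use_adjusted_p
                ) is mir_dir:
                    sponge_edges[m].append((l, sites))

        for row_idx, row in mir_mrna_rows:
            members = row.source_members
            gene = row.target_id
            if any(m not in measured_mir for m in members) or gene not in measured_mrna:
                skipped += 1
                continue
            grec = mrna_recs.get(gene)
            if grec is None or grec.status is not mrna_status:
                continue
            for m in members:
                for (l, sites) in sponge_edges.get(m, []):
                    joined_rows.add(
                        (row.source_id, row.target_id) if params.dedup_associations else row_idx
                    )
                    triplets.append(
                        CernaTriplet(
                            lncRNA_id=l,
                            miRNA_id=m,
                            mRNA_id=gene,
                            binding_sites=sites,
                            lnc_fc=lnc_recs[l].fc,
                            mir_fc=mir_recs[m].fc,
                            mrna_fc=grec.fc,
                            direction=tag,
                            comparison=cmp_name,
                            mrna_evidence=row.evidence.value,
                            association_row=row_idx,
                        )
                    )

    if skipped:
        warnings.warn(f"{skipped} interaction row(s) referenced unmeasured features; skipped")

    if params.dedup_associations:
        # collapse repeated (miRNA, mRNA) listings to one triplet each
        seen: set = set()
        unique = []
        for t in sorted(triplets, key=lambda t: t.association_row):
            key = (t.comparison, t.lncRNA_id, t.miRNA_id, t.mRNA_id)
            if key not in seen:
                seen.add(key)
                unique.append(t)
        triplets = unique

    triplets.sort(key=lambda t: (-t.binding_sites, t.lncRNA_id, t.miRNA_id, t.mRNA_id, t.comparison))
    summary = ModuleSummary(
        direction=direction,
        comparisons=tuple(comparisons),
        n_lncRNA_distinct=len({t.lncRNA_id for t in triplets}),
        n_miRNA_distinct=len({t.miRNA_id for t in triplets}),
        n_mrna_associations=len(joined_rows),
        n_mrna_distinct=len({t.mRNA_id for t in triplets}),
        triplet_count=len(triplets),
    )
    return triplets, summary


def annotate_diseases(
    triplets: Sequence[CernaTriplet],
    disease_table: Sequence[DiseaseAnnotation],
) -> list[CernaTriplet]:
    """Left-join disease terms onto triplets by sponge lncRNA id (idempotent;
    lncRNAs absent from the table get an empty term list)."""
    terms: dict[str, tuple[str, ...]] = {}
    for ann in disease_table:
        terms.setdefault(ann.lncRNA_id, ())
        terms[ann.lncRNA_id] = tuple(dict.fromkeys(terms[ann.lncRNA_id] + tuple(ann.disease_terms)))
    return [replace(t, disease_terms=terms.get(t.lncRNA_id, ())) for t in triplets]
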