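"""Readers and writers for every external format the pipeline touches.

Formats: TSV expression matrices plus a sample-design TSV; GTF2.2 / BED6 gene
annotation; interaction tables (lncRNA-miRNA binding sites, miRNA-mRNA targets)
as TSV; GMT gene sets; differential-expression TSV tables; SIF / GraphML / TSV
network exports; lncRNA-disease annotation TSV.

Coordinates are 0-based half-open internally; GTF (1-based closed) is converted
on read and write. Feature ids are matched case-sensitively and exactly.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import gffutils
import networkx as nx
import numpy as np
import pandas as pd

from .model import (
    Comparison,
    DERecord,
    DEStatus,
    DiseaseAnnotation,
    Evidence,
    ExpressionMatrix,
    GeneSet,
    GenomicFeature,
    InteractionKind,
    InteractionRecord,
    Knockdown,
    MoleculeClass,
    Sample,
    SampleDesign,
    Strand,
    Treatment,
)

# --------------------------------------------------------------------------
# expression matrices + design
# --------------------------------------------------------------------------


def read_design(path: str | os.PathLike) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "knockdown", "treatment", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design file {path} missing columns: {sorted(missing)}")
    samples = [
        Sample(
            sample_id=row.sample_id,
            knockdown=Knockdown(row.knockdown),
            treatment=Treatment(row.treatment),
            replicate=int(row.replicate),
        )
        for row in df.itertuples()
    ]
    return SampleDesign(samples)


def write_design(design: SampleDesign, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in design],
            "knockdown": [s.knockdown.value for s in design],
            "treatment": [s.treatment.value for s in design],
            "replicate": [s.replicate for s in design],
        }
    ).to_csv(path, sep="\t", index=False)


def read_expression(
    path: str | os.PathLike,
    design_path: str | os.PathLike,
    molecule_class: MoleculeClass | str,
) -> ExpressionMatrix:
    """Load a feature x sample TSV against its design.

    Rejects duplicate feature ids, missing/non-numeric/negative cells, and
    samples present in the matrix but absent from the design.
    """
    design = read_design(design_path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate feature ids in {path}: {dupes}")
    unknown = [c for c in df.columns if c not in set(design.sample_ids)]
    if unknown:
        raise ValueError(f"samples in matrix but not in design: {unknown}")
    missing = [s for s in design.sample_ids if s not in df.columns]
    if missing:
        raise ValueError(f"design samples missing from matrix: {missing}")
    df = df[design.sample_ids]
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric intensity in {path}: {exc}") from exc
    return ExpressionMatrix(df, design, MoleculeClass(molecule_class), normalized=False)


def write_expression(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    out = matrix.data.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


# --------------------------------------------------------------------------
# genome annotation (GTF / BED6)
# --------------------------------------------------------------------------

#: biotype -> molecule class mapping used for both GTF attributes and the
#: optional 7th BED column. Unlisted biotypes map to lncRNA (the array targets
#: non-coding transcripts; protein-coding genes and miRNA loci are explicit).
BIOTYPE_TO_CLASS = {
    "protein_coding": MoleculeClass.mRNA,
    "miRNA": MoleculeClass.miRNA,
}


def _class_from_biotype(biotype: str) -> MoleculeClass:
    return BIOTYPE_TO_CLASS.get(biotype, MoleculeClass.lncRNA)


def _biotype_from_class(mc: MoleculeClass) -> str:
    for k, v in BIOTYPE_TO_CLASS.items():
        if v is mc:
            return k
    return "lncRNA"


def read_annotation(path: str | os.PathLike, dialect: str = "gtf") -> list[GenomicFeature]:
    if dialect == "gtf":
        return _read_gtf(path)
    if dialect == "bed":
        return _read_bed(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}; use 'gtf' or 'bed'")


def _read_gtf(path: str | os.PathLike) -> list[GenomicFeature]:
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    features: list[GenomicFeature] = []
    for g in db.features_of_type("gene"):
        # GTF is 1-based closed; internal is 0-based half-open.
        start, end = g.start - 1, g.end
        if end <= start:
            raise ValueError(f"{path}: gene {g.id} has end <= start after conversion")
        exons = [(e.start - 1, e.end) for e in db.children(g, featuretype="exon")]
        attrs = dict(g.attributes)
        biotype = attrs.get("gene_biotype", ["lncRNA"])[0]
        in_ref = attrs.get("in_reference", ["1"])[0] not in ("0", "false", "False")
        features.append(
            GenomicFeature(
                feature_id=g.id,
                chrom=g.seqid,
                start=start,
                end=end,
                strand=Strand(g.strand),
                molecule_class=_class_from_biotype(biotype),
                gene_name=attrs.get("gene_name", [None])[0],
                exons=sorted(exons) or None,
                annotated_in_reference=in_ref,
            )
        )
    return features


def write_gtf(features: Sequence[GenomicFeature], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for f in features:
            attrs = f'gene_id "{f.feature_id}"; gene_biotype "{_biotype_from_class(f.molecule_class)}";'
            if f.gene_name:
                attrs += f' gene_name "{f.gene_name}";'
            if not f.annotated_in_reference:
                attrs += ' in_reference "0";'
            base = f"{f.chrom}\tcerna_weaver\t{{kind}}\t{{s}}\t{{e}}\t.\t{f.strand.value}\t.\t{attrs}\n"
            fh.write(base.format(kind="gene", s=f.start + 1, e=f.end))
            for (a, b) in f.exons or []:
                fh.write(base.format(kind="exon", s=a + 1, e=b))


def _read_bed(path: str | os.PathLike) -> list[GenomicFeature]:
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 needs >= 6 columns")
            chrom, start, end, name, _score, strand = parts[:6]
            start_i, end_i = int(start), int(end)
            if end_i <= start_i:
                raise ValueError(f"{path}:{lineno}: end <= start")
            biotype = parts[6] if len(parts) > 6 else "lncRNA"
            features.append(
                GenomicFeature(
                    feature_id=name,
                    chrom=chrom,
                    start=start_i,
                    end=end_i,
                    strand=Strand(strand),
                    molecule_class=_class_from_biotype(biotype),
                )
            )
    return features


def write_bed(features: Sequence[GenomicFeature], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_id}\t0\t{f.strand.value}"
                f"\t{_biotype_from_class(f.molecule_class)}\n"
            )


# --------------------------------------------------------------------------
# interaction tables
# --------------------------------------------------------------------------

_INTERACTION_COLS = ["kind", "source_id", "target_id", "binding_sites", "evidence"]


def read_interactions(path: str | os.PathLike) -> list[InteractionRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"source_id": str, "target_id": str})
    missing = set(_INTERACTION_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"interaction table {path} missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples():
        sites = None if pd.isna(row.binding_sites) else int(row.binding_sites)
        records.append(
            InteractionRecord(
                kind=InteractionKind(row.kind),
                source_id=row.source_id,
                target_id=row.target_id,
                binding_sites=sites,
                evidence=Evidence(row.evidence),
            )
        )
    return records


def write_interactions(records: Iterable[InteractionRecord], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "kind": [r.kind.value for r in records],
            "source_id": [r.source_id for r in records],
            "target_id": [r.target_id for r in records],
            "binding_sites": [r.binding_sites if r.binding_sites is not None else "" for r in records],
            "evidence": [r.evidence.value for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# gene sets (GMT) and disease annotation
# --------------------------------------------------------------------------


def read_gmt(path: str | os.PathLike) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT needs id, description, >=1 member")
            sets.append(GeneSet(parts[0], parts[1], frozenset(m for m in parts[2:] if m)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *sorted(s.members)]) + "\n")


def read_disease_table(path: str | os.PathLike) -> list[DiseaseAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"lncRNA_id", "disease_terms"} <= set(df.columns):
        raise ValueError(f"disease table {path} needs columns lncRNA_id, disease_terms")
    return [
        DiseaseAnnotation(
            row.lncRNA_id,
            tuple(t for t in str(row.disease_terms).split(";") if t and t != "nan"),
        )
        for row in df.itertuples()
    ]


# --------------------------------------------------------------------------
# differential-expression tables
# --------------------------------------------------------------------------

_DE_COLS = [
    "feature_id", "comparison", "mean_test", "mean_control", "fc", "log2fc",
    "p", "adj_p", "raw_intensity", "status", "annotated_in_reference",
]


def write_de_table(records: Iterable[DERecord], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "comparison": r.comparison,
                "mean_test": r.mean_test,
                "mean_control": r.mean_control,
                "fc": r.fc,
                "log2fc": r.log2fc,
                "p": r.p,
                "adj_p": r.adj_p,
                "raw_intensity": r.raw_intensity,
                "status": r.status.value,
                "annotated_in_reference": int(r.annotated_in_reference),
            }
            for r in records
        ],
        columns=_DE_COLS,
    ).to_csv(path, sep="\t", index=False)


def read_de_table(path: str | os.PathLike) -> list[DERecord]:
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "comparison": str})
    missing = set(_DE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"DE table {path} missing columns: {sorted(missing)}")
    return [
        DERecord(
            feature_id=row.feature_id,
            comparison=row.comparison,
            mean_test=float(row.mean_test),
            mean_control=float(row.mean_control),
            fc=float(row.fc),
            log2fc=float(row.log2fc),
            p=float(row.p),
            adj_p=float(row.adj_p),
            raw_intensity=float(row.raw_intensity),
            status=DEStatus(row.status),
            annotated_in_reference=bool(row.annotated_in_reference),
        )
        for row in df.itertuples()
    ]


# --------------------------------------------------------------------------
# network export
# --------------------------------------------------------------------------


def write_network(triplets: Sequence, path: str | os.PathLike, format: str = "sif") -> None:
    """Export ceRNA triplets as a sponge network.

    SIF uses relation labels ``sponges`` (lncRNA -> miRNA) and ``targets``
    (miRNA -> mRNA); GraphML nodes carry molecule_class and log2FC attributes;
    TSV is a flat edge list.
    """
    if format == "sif":
        seen = set()
        with open(path, "w") as fh:
            for t in triplets:
                for edge in (
                    (t.lncRNA_id, "sponges", t.miRNA_id),
                    (t.miRNA_id, "targets", t.mRNA_id),
                ):
                    if edge not in seen:
                        seen.add(edge)
                        fh.write("\t".join(edge) + "\n")
    elif format == "graphml":
        g = nx.DiGraph()
        for t in triplets:
            g.add_node(t.lncRNA_id, molecule_class="lncRNA", log2fc=float(np.log2(t.lnc_fc)))
            g.add_node(t.miRNA_id, molecule_class="miRNA", log2fc=float(np.log2(t.mir_fc)))
            g.add_node(t.mRNA_id, molecule_class="mRNA", log2fc=float(np.log2(t.mrna_fc)))
            g.add_edge(t.lncRNA_id, t.miRNA_id, relation="sponges", binding_sites=int(t.binding_sites))
            g.add_edge(t.miRNA_id, t.mRNA_id, relation="targets")
        nx.write_graphml(g, path)
    elif format == "tsv":
        pd.DataFrame(
            [
                {
                    "lncRNA_id": t.lncRNA_id,
                    "miRNA_id": t.miRNA_id,
                    "mRNA_id": t.mRNA_id,
                    "binding_sites": t.binding_sites,
                    "lnc_fc": t.lnc_fc,
                    "mir_fc": t.mir_fc,
                    "mrna_fc": t.mrna_fc,
                    "direction": t.direction,
                    "comparison": t.comparison,
                }
                for t in triplets
            ]
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r}; use sif, graphml or tsv")
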