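"""Config-driven end-to-end orchestration.

One YAML config (or an equivalent dict) is the source of truth for a run:
inputs (real file paths, a synthetic-generator config, or the packaged
published-table fixtures), comparisons, thresholds, and output directory.
``run_pipeline`` executes normalize -> differential expression -> lncRNA
classification -> cis pairing -> sponge-triplet assembly (both directions) ->
enrichment, writes tabular/network artifacts plus a machine-readable report,
and is fully deterministic for a given config and seed.
"""

from __future__ import annotations

import difflib
import json
import os
import shutil
import warnings
from dataclasses import asdict, dataclass, field
from typing import Any, Optional

import yaml

from . import __version__
from . import io as cio
from .cerna import CernaParams, annotate_diseases, build_cerna
from .diffexpr import DEThresholds, differential_expression, quantile_normalize
from .enrichment import enrich
from .fixtures import make_published_fixtures
from .genomic import (
    LncSubclass,
    chromosome_summary,
    cis_pairs,
    classify_lncrna,
    subclass_summary,
)
from .model import (
    CANONICAL_COMPARISONS,
    DERecord,
    DEStatus,
    MoleculeClass,
    comparison_by_name,
)
from .synth import SyntheticConfig, generate_experiment


class PipelineError(RuntimeError):
    """Raised with a stage-labelled message when any stage fails."""


_DEFAULTS: dict[str, Any] = {
    "inputs": None,
    "synthetic": None,
    "fixtures": False,
    "comparisons": [c.name for c in CANONICAL_COMPARISONS],
    "thresholds": {"fc_min": 1.5, "p_max": 0.05, "use_adjusted_p": False},
    "cerna": {
        "min_binding_sites": 2,
        "min_raw_intensity": 100.0,
        "require_reference_annotation": True,
        "mirna_direction_mode": "significance_only",
        "mrna_evidence": "validated_or_predicted",
        "binding_site_scope": "lncrna",
        "dedup_associations": False,
    },
    "cis_window": 300_000,
    "enrichment_top_k": 10,
    "output_dir": None,
    "seed": 0,
}

_INPUT_KEYS = {
    "lnc_matrix", "mrna_matrix", "mir_matrix", "design", "annotation",
    "annotation_dialect", "interactions", "gmt", "disease_table",
}


def _reject_unknown(given: dict, allowed: set[str], context: str) -> None:
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown {context} key {key!r}{suffix}")


def normalize_config(raw: dict) -> dict:
    """Inject defaults and reject unknown keys (idempotent)."""
    raw = dict(raw or {})
    _reject_unknown(raw, set(_DEFAULTS), "config")
    cfg = {**_DEFAULTS, **raw}
    cfg["thresholds"] = {**_DEFAULTS["thresholds"], **(raw.get("thresholds") or {})}
    _reject_unknown(cfg["thresholds"], set(_DEFAULTS["thresholds"]), "thresholds")
    cfg["cerna"] = {**_DEFAULTS["cerna"], **(raw.get("cerna") or {})}
    _reject_unknown(cfg["cerna"], set(_DEFAULTS["cerna"]), "cerna")
    if cfg["inputs"] is not None:
        _reject_unknown(cfg["inputs"], _INPUT_KEYS, "inputs")
    if cfg["inputs"] is None and cfg["synthetic"] is None and not cfg["fixtures"]:
        raise ValueError("config needs one of: inputs, synthetic, fixtures")
    if cfg["synthetic"] is not None:
        syn = dict(cfg["synthetic"])
        syn.setdefault("seed", cfg["seed"])
        if syn.get("subclass_mix") is not None:
            syn["subclass_mix"] = {
                LncSubclass(getattr(k, "value", k)): float(v)
                for k, v in syn["subclass_mix"].items()
            }
        validated = SyntheticConfig(**syn)
        echo = asdict(validated)
        echo["subclass_mix"] = {k.value: v for k, v in validated.subclass_mix.items()}
        cfg["synthetic"] = echo
    return cfg


def validate_config(path: str | os.PathLike) -> dict:
    """Load and normalize a YAML run config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    cfg = normalize_config(raw)
    if cfg["inputs"] is not None:
        required = {"lnc_matrix", "mrna_matrix", "mir_matrix", "design", "interactions"}
        for key in sorted(required):
            if key not in cfg["inputs"]:
                raise ValueError(f"config inputs missing required path {key!r}")
    return cfg


@dataclass
class RunReport:
    tool_version: str
    config: dict
    de_counts: dict[str, dict[str, dict[str, int]]]  # class -> comparison -> {up,down}
    subclass_summary: dict[str, float]
    chromosome_summary: dict[str, int]
    cis_pair_count: int
    modules: dict[str, dict]
    enrichment_top: list[dict]
    warnings: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def check_consistency(self) -> None:
        for direction, mod in self.modules.items():
            if mod["n_mrna_distinct"] > mod["n_mrna_associations"]:
                raise AssertionError(f"{direction}: distinct mRNAs exceed associations")
        for mc, per_cmp in self.de_counts.items():
            for cmp_name, counts in per_cmp.items():
                if min(counts.values()) < 0:
                    raise AssertionError("negative DE count")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapped
    return deco


@_stage("load")
def _load_inputs(cfg: dict):
    if cfg["fixtures"]:
        return None  # handled separately
    if cfg["synthetic"] is not None:
        syn = dict(cfg["synthetic"])
        if syn.get("subclass_mix") is not None:
            syn["subclass_mix"] = {LncSubclass(k): v for k, v in syn["subclass_mix"].items()}
        exp = generate_experiment(SyntheticConfig(**syn))
        return {
            "matrices": exp.matrices,
            "features": exp.features,
            "interactions": exp.interactions,
            "gene_sets": exp.gene_sets,
            "diseases": exp.diseases,
            "truth": exp.truth,
        }
    inp = cfg["inputs"]
    matrices = {
        MoleculeClass.lncRNA: cio.read_expression(inp["lnc_matrix"], inp["design"], MoleculeClass.lncRNA),
        MoleculeClass.mRNA: cio.read_expression(inp["mrna_matrix"], inp["design"], MoleculeClass.mRNA),
        MoleculeClass.miRNA: cio.read_expression(inp["mir_matrix"], inp["design"], MoleculeClass.miRNA),
    }
    features = (
        cio.read_annotation(inp["annotation"], inp.get("annotation_dialect", "gtf"))
        if "annotation" in inp else []
    )
    return {
        "matrices": matrices,
        "features": features,
        "interactions": cio.read_interactions(inp["interactions"]),
        "gene_sets": cio.read_gmt(inp["gmt"]) if "gmt" in inp else [],
        "diseases": cio.read_disease_table(inp["disease_table"]) if "disease_table" in inp else [],
        "truth": None,
    }


def run_pipeline(config: dict, output_dir: Optional[str] = None) -> RunReport:
    """Execute the full analysis for a normalized config; see module docstring."""
    cfg = normalize_config(config)
    outdir = output_dir or cfg["output_dir"]
    thresholds = DEThresholds(**cfg["thresholds"])
    params = CernaParams(**cfg["cerna"])
    comparisons = [comparison_by_name(n) for n in cfg["comparisons"]]
    caught: list[str] = []

    if cfg["fixtures"]:
        report = _run_fixture_mode(cfg, params, thresholds, caught)
    else:
        report = _run_matrix_mode(cfg, params, thresholds, comparisons, caught)

    report.check_consistency()
    if outdir:
        _write_artifacts(report, outdir)
    return report


@_stage("cerna")
def _modules_report(de, interactions, params, thresholds, diseases):
    modules = {}
    triplets_all = {}
    for direction in ("up_module", "down_module"):
        triplets, summary = build_cerna(
            de[MoleculeClass.lncRNA], de[MoleculeClass.miRNA], de[MoleculeClass.mRNA],
            interactions, params, direction, thresholds,
        )
        if diseases:
            triplets = annotate_diseases(triplets, diseases)
        triplets_all[direction] = triplets
        modules[direction] = {
            "comparisons": list(summary.comparisons),
            "n_lncRNA_distinct": summary.n_lncRNA_distinct,
            "n_miRNA_distinct": summary.n_miRNA_distinct,
            "n_mrna_associations": summary.n_mrna_associations,
            "n_mrna_distinct": summary.n_mrna_distinct,
            "triplet_count": summary.triplet_count,
        }
    return modules, triplets_all


def _de_counts(de_records: dict) -> dict:
    out: dict = {}
    for mc, records in de_records.items():
        per: dict = {}
        for r in records:
            slot = per.setdefault(r.comparison, {"up": 0, "down": 0, "ns": 0})
            slot[r.status.value] += 1
        out[mc.value] = per
    return out


def _run_fixture_mode(cfg, params, thresholds, caught) -> RunReport:
    fx = make_published_fixtures(thresholds)
    modules = {}
    triplets_all = {}
    de_records = {mc: [] for mc in MoleculeClass}
    for mod in (fx.up, fx.down):
        de_records[MoleculeClass.lncRNA] += mod.de_lnc
        de_records[MoleculeClass.miRNA] += mod.de_mir
        de_records[MoleculeClass.mRNA] += mod.de_mrna
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            triplets, summary = build_cerna(
                mod.de_lnc, mod.de_mir, mod.de_mrna, mod.interactions,
                params, mod.direction, thresholds,
            )
            caught.extend(str(x.message) for x in w)
        triplets_all[mod.direction] = triplets
        modules[mod.direction] = {
            "comparisons": list(summary.comparisons),
            "n_lncRNA_distinct": summary.n_lncRNA_distinct,
            "n_miRNA_distinct": summary.n_miRNA_distinct,
            "n_mrna_associations": summary.n_mrna_associations,
            "n_mrna_distinct": summary.n_mrna_distinct,
            "triplet_count": summary.triplet_count,
        }
    report = RunReport(
        tool_version=__version__,
        config=cfg,
        de_counts=_de_counts(de_records),
        subclass_summary={},
        chromosome_summary={},
        cis_pair_count=0,
        modules=modules,
        enrichment_top=[],
        warnings=caught,
    )
    report._triplets = triplets_all  # type: ignore[attr-defined]
    return report


def _run_matrix_mode(cfg, params, thresholds, comparisons, caught) -> RunReport:
    bundle = _load_inputs(cfg)
    matrices = bundle["matrices"]
    features = bundle["features"]

    in_reference = {f.feature_id: f.annotated_in_reference for f in features}

    @_stage("normalize")
    def _normalize():
        return {mc: quantile_normalize(m) for mc, m in matrices.items()}

    normalized = _normalize()

    @_stage("differential_expression")
    def _de():
        de: dict = {mc: [] for mc in MoleculeClass}
        for mc in MoleculeClass:
            for comparison in comparisons:
                de[mc] += differential_expression(
                    normalized[mc], comparison, thresholds,
                    raw_matrix=matrices[mc],
                    annotated_in_reference=in_reference,
                )
        return de

    de = _de()

    @_stage("classify")
    def _classify():
        lncs = [f for f in features if f.molecule_class is MoleculeClass.lncRNA]
        genes = [f for f in features if f.molecule_class is MoleculeClass.mRNA]
        if not lncs or not genes:
            return {}, {}
        assignments = {l.feature_id: classify_lncrna(l, genes) for l in lncs}
        return (
            {k.value: v for k, v in subclass_summary(assignments.values()).items()},
            chromosome_summary(lncs),
        )

    sub_summary, chrom_summary = _classify()

    @_stage("cis")
    def _cis():
        if not features:
            return []
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            pairs = cis_pairs(
                de[MoleculeClass.lncRNA], de[MoleculeClass.mRNA], features,
                window=cfg["cis_window"],
            )
            caught.extend(str(x.message) for x in w)
        return pairs

    pairs = _cis()
    modules, triplets_all = _modules_report(
        de, bundle["interactions"], params, thresholds, bundle["diseases"]
    )

    @_stage("enrich")
    def _enrich():
        if not bundle["gene_sets"]:
            return []
        background = matrices[MoleculeClass.mRNA].feature_ids
        de_genes = {
            r.feature_id for r in de[MoleculeClass.mRNA] if r.status is not DEStatus.ns
        }
        results = enrich(de_genes, background, bundle["gene_sets"])
        return [
            {
                "set_id": r.set_id, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                "p_right": r.p_right, "adj_p": r.adj_p,
                "fold_enrichment": r.fold_enrichment,
            }
            for r in results[: cfg["enrichment_top_k"]]
        ]

    report = RunReport(
        tool_version=__version__,
        config=cfg,
        de_counts=_de_counts(de),
        subclass_summary=sub_summary,
        chromosome_summary=chrom_summary,
        cis_pair_count=len(pairs),
        modules=modules,
        enrichment_top=_enrich(),
        warnings=caught,
    )
    report._triplets = triplets_all  # type: ignore[attr-defined]
    report._de = de  # type: ignore[attr-defined]
    report._cis = pairs  # type: ignore[attr-defined]
    return report


@_stage("write")
def _write_artifacts(report: RunReport, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []
    try:
        path = os.path.join(outdir, "report.json")
        with open(path, "w") as fh:
            fh.write(report.to_json() + "\n")
        written.append(path)
        for direction, triplets in getattr(report, "_triplets", {}).items():
            for fmt, ext in (("tsv", "tsv"), ("sif", "sif"), ("graphml", "graphml")):
                path = os.path.join(outdir, f"{direction}_network.{ext}")
                cio.write_network(triplets, path, fmt)
                written.append(path)
        for mc, records in getattr(report, "_de", {}).items():
            path = os.path.join(outdir, f"de_{mc.value}.tsv")
            cio.write_de_table(records, path)
            written.append(path)
        if hasattr(report, "_cis"):
            import pandas as pd

            path = os.path.join(outdir, "cis_pairs.tsv")
            pd.DataFrame(
                [
                    {
                        "lncRNA_id": p.lncRNA_id, "mRNA_id": p.mRNA_id,
                        "comparison": p.comparison, "distance_bp": p.distance_bp,
                        "orientation": p.orientation.value,
                        "lnc_status": p.lnc_status.value,
                        "mrna_status": p.mrna_status.value,
                    }
                    for p in report._cis
                ]
            ).to_csv(path, sep="\t", index=False)
            written.append(path)
    except Exception:
        for path in written:
            if os.path.exists(path):
                os.remove(path)
        raise
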