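"""Packaged machine-readable transcription of the published sponge modules.

Two fixture bundles ship with the package as plain TSV under
``cerna_weaver/data``: the up module (upregulated lncRNAs with downregulated
partner miRNAs and their upregulated mRNA targets) and the mirror down module.
Each bundle holds the printed lncRNA/miRNA fold changes and p-values per
comparison, the lncRNA-miRNA binding-site counts, and the miRNA->mRNA target
lists row for row (duplicated gene listings preserved; target lists attributed
to a co-listed miRNA family carry a ``|``-joined source id).

Transcription conventions (the publication prints neither of these): mRNA
targets get placeholder fold change 2.0 (up) / 0.5 (down) at p = 0.01 in every
comparison where their miRNA is differentially expressed, and all raw signal
intensities are set to 150 — above the > 100 expressed-lncRNA filter by
construction. Printed negative fold changes -x are stored as printed and
loaded as linear 1/x.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from . import io as cio
from .diffexpr import DEThresholds, assign_status
from .model import DERecord, InteractionKind, InteractionRecord, MoleculeClass

#: fixture raw-intensity placeholder (fluorescence units); a convention, not data
FIXTURE_RAW_INTENSITY = 150.0
FIXTURE_MRNA_FC = 2.0
FIXTURE_MRNA_P = 0.01


@dataclass
class ModuleFixture:
    """One sponge module: per-class DE records plus its interaction table."""

    direction: str  # up_module | down_module
    de_lnc: list[DERecord]
    de_mir: list[DERecord]
    de_mrna: list[DERecord]
    interactions: list[InteractionRecord]


@dataclass
class PublishedFixtures:
    up: ModuleFixture
    down: ModuleFixture

    def write(self, outdir: str | os.PathLike) -> None:
        """Emit the fixture bundle as the same TSV dialects the readers load."""
        os.makedirs(outdir, exist_ok=True)
        for mod, tag in ((self.up, "up"), (self.down, "down")):
            cio.write_de_table(mod.de_lnc, os.path.join(outdir, f"{tag}_de_lncRNA.tsv"))
            cio.write_de_table(mod.de_mir, os.path.join(outdir, f"{tag}_de_miRNA.tsv"))
            cio.write_de_table(mod.de_mrna, os.path.join(outdir, f"{tag}_de_mRNA.tsv"))
            cio.write_interactions(mod.interactions, os.path.join(outdir, f"{tag}_interactions.tsv"))


def _data_path(name: str):
    return resources.files("cerna_weaver").joinpath("data", name)


def _printed_fc_to_linear(v: float) -> float:
    """Printed fold changes use -x for x-fold downregulation."""
    return float(v) if v > 0 else 1.0 / abs(float(v))


def _de_record(fid: str, comparison: str, fc: float, p: float, thresholds: DEThresholds) -> DERecord:
    return DERecord(
        feature_id=fid,
        comparison=comparison,
        mean_test=FIXTURE_RAW_INTENSITY,
        mean_control=FIXTURE_RAW_INTENSITY / fc,
        fc=fc,
        log2fc=float(np.log2(fc)),
        p=p,
        adj_p=p,
        raw_intensity=FIXTURE_RAW_INTENSITY,
        status=assign_status(fc, p, thresholds),
        annotated_in_reference=True,
    )


def _load_module(de_name: str, int_name: str, direction: str, thresholds: DEThresholds) -> ModuleFixture:
    with resources.as_file(_data_path(de_name)) as p:
        de = pd.read_csv(p, sep="\t")
    with resources.as_file(_data_path(int_name)) as p:
        interactions = cio.read_interactions(p)

    de_lnc, de_mir = [], []
    mir_comparisons: dict[str, list[str]] = {}
    for row in de.itertuples():
        fc = _printed_fc_to_linear(row.fold_change)
        rec = _de_record(row.feature_id, row.comparison, fc, float(row.p), thresholds)
        if row.molecule_class == MoleculeClass.lncRNA.value:
            de_lnc.append(rec)
        else:
            de_mir.append(rec)
            mir_comparisons.setdefault(row.feature_id, []).append(row.comparison)

    # derived mRNA records: each listed target is differentially expressed in
    # the module direction wherever its miRNA is (placeholder FC/p; see module
    # docstring)
    mrna_fc = FIXTURE_MRNA_FC if direction == "up_module" else 1.0 / FIXTURE_MRNA_FC
    seen: set[tuple[str, str]] = set()
    de_mrna = []
    for r in interactions:
        if r.kind is not InteractionKind.mir_mrna:
            continue
        comparisons = sorted(
            {c for m in r.source_members for c in mir_comparisons.get(m, [])}
        )
        for c in comparisons:
            key = (r.target_id, c)
            if key not in seen:
                seen.add(key)
                de_mrna.append(_de_record(r.target_id, c, mrna_fc, FIXTURE_MRNA_P, thresholds))

    return ModuleFixture(
        direction=direction,
        de_lnc=de_lnc,
        de_mir=de_mir,
        de_mrna=de_mrna,
        interactions=interactions,
    )


def make_published_fixtures(thresholds: DEThresholds = DEThresholds()) -> PublishedFixtures:
    """Load the packaged transcription of the published sponge modules."""
    return PublishedFixtures(
        up=_load_module("module_up_de.tsv", "module_up_interactions.tsv", "up_module", thresholds),
        down=_load_module("module_down_de.tsv", "module_down_interactions.tsv", "down_module", thresholds),
    )
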