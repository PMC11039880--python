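"""Seeded synthetic experiment generator with known ground truth.

Emulates the study design end to end: three feature x sample intensity
matrices (lncRNA, mRNA, miRNA) over the 2x2 siNT/siOct4 x DMSO/POVPC design
with log-normal intensities and planted multiplicative effects; a genome
annotation in which lncRNA loci are placed to realize an exact subclass mix
against generated protein-coding genes; validated interaction tables carrying
planted direction-concordant sponge triplets (binding sites 2-8) plus 1-site
decoys that must be rejected by the binding-site filter; and gene sets with
one set seeded with DE genes.

Effects are planted so the three canonical comparisons stay orthogonal: the
knockdown effect is applied to both siOct4 cells, treatment effects to the
respective POVPC cell only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genomic import LncSubclass, span_gap
from .model import (
    CANONICAL_COMPARISONS,
    Comparison,
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

#: default positional mix: the dominant intergenic / natural-antisense /
#: intronic-antisense split observed on arrays of this kind, with the small
#: remainder spread over the remaining conventional classes.
DEFAULT_SUBCLASS_MIX: dict[LncSubclass, float] = {
    LncSubclass.intergenic: 0.72,
    LncSubclass.natural_antisense: 0.12,
    LncSubclass.intronic_antisense: 0.09,
    LncSubclass.intronic_sense: 0.03,
    LncSubclass.sense_overlapping: 0.02,
    LncSubclass.bidirectional: 0.02,
}

_CELLS: tuple[tuple[Knockdown, Treatment], ...] = (
    (Knockdown.siNT, Treatment.DMSO),
    (Knockdown.siNT, Treatment.POVPC),
    (Knockdown.siOct4, Treatment.DMSO),
    (Knockdown.siOct4, Treatment.POVPC),
)

#: design cells receiving the planted effect for each canonical comparison;
#: the knockdown effect goes into both siOct4 cells so it cancels out of the
#: siOct4-POVPC vs siOct4-DMSO contrast.
_EFFECT_CELLS: dict[str, tuple[int, ...]] = {
    CANONICAL_COMPARISONS[0].name: (1,),
    CANONICAL_COMPARISONS[1].name: (2, 3),
    CANONICAL_COMPARISONS[2].name: (3,),
}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic experiment.

    ``de_fraction`` is the fraction of features planted per direction per
    comparison (each comparison gets round(de_fraction*n) up and as many down
    features per molecule class, disjoint across comparisons). Intensities are
    2^(baseline + effect*indicator + Normal(0, noise_log2_sd)).
    """

    n_lnc: int = 300
    n_mrna: int = 800
    n_mir: int = 100
    n_replicates: int = 3
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    noise_log2_sd: float = 0.25
    de_fraction: float = 0.05
    effect_log2: float = 1.5
    n_planted_triplets_up: int = 5
    n_planted_triplets_down: int = 5
    n_decoy_triplets: int = 4
    n_background_lnc_mir: int = 30
    n_background_mir_mrna: int = 50
    subclass_mix: dict[LncSubclass, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBCLASS_MIX)
    )
    chrom_count: int = 5
    intergenic_far_fraction: float = 0.5
    cis_window: int = 300_000
    n_gene_sets: int = 20
    gene_set_size: int = 25
    planted_set_de_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.subclass_mix.values()):
            raise ValueError("subclass proportions must be nonnegative")
        if abs(sum(self.subclass_mix.values()) - 1.0) > 1e-9:
            raise ValueError("subclass proportions must sum to 1")
        if self.noise_log2_sd < 0:
            raise ValueError("noise_log2_sd must be >= 0")
        if self.effect_log2 <= 0:
            raise ValueError("effect_log2 must be > 0")
        if not (0 <= self.de_fraction <= 1):
            raise ValueError("de_fraction must be in [0, 1]")
        total_trip = self.n_planted_triplets_up + self.n_planted_triplets_down + self.n_decoy_triplets
        if total_trip > min(self.n_lnc, self.n_mrna, self.n_mir):
            raise ValueError("planted triplet counts exceed available features")


@dataclass(frozen=True)
class PlantedTriplet:
    lncRNA_id: str
    miRNA_id: str
    mRNA_id: str
    direction: str  # up_down_up | down_up_down
    comparison: str
    binding_sites: int


@dataclass(frozen=True)
class PlantedCisPair:
    lncRNA_id: str
    mRNA_id: str
    comparison: str
    distance_bp: int


@dataclass
class TruthManifest:
    """Ground truth of one synthetic experiment.

    ``de_status[molecule_class][comparison]`` maps feature id -> "up"/"down"
    for every planted effect; cis pairs are derived exactly from the
    constructed geometry and planted DE sets.
    """

    de_status: dict[str, dict[str, dict[str, str]]]
    triplets: list[PlantedTriplet]
    decoy_triplets: list[PlantedTriplet]
    subclasses: dict[str, LncSubclass]
    cis_pairs: list[PlantedCisPair]
    planted_set_id: str

    def de_features(self, molecule_class: str, comparison: str, status: str) -> set[str]:
        table = self.de_status.get(molecule_class, {}).get(comparison, {})
        return {fid for fid, s in table.items() if s == status}

    def n_planted(self, molecule_class: str, comparison: str, status: str) -> int:
        return len(self.de_features(molecule_class, comparison, status))


@dataclass
class SyntheticExperiment:
    lnc: ExpressionMatrix
    mrna: ExpressionMatrix
    mir: ExpressionMatrix
    features: list[GenomicFeature]
    interactions: list[InteractionRecord]
    gene_sets: list[GeneSet]
    diseases: list[DiseaseAnnotation]
    truth: TruthManifest

    @property
    def matrices(self) -> dict[MoleculeClass, ExpressionMatrix]:
        return {
            MoleculeClass.lncRNA: self.lnc,
            MoleculeClass.mRNA: self.mrna,
            MoleculeClass.miRNA: self.mir,
        }


def _make_design(n_replicates: int) -> SampleDesign:
    samples = []
    for kd, tr in _CELLS:
        for r in range(1, n_replicates + 1):
            samples.append(Sample(f"{kd.value}_{tr.value}_r{r}", kd, tr, r))
    return SampleDesign(samples)


def _apportion(n: int, proportions: dict[LncSubclass, float]) -> dict[LncSubclass, int]:
    """Exact largest-remainder apportionment so recovered proportions equal the
    planted mix at the given n."""
    raw = {sc: n * p for sc, p in proportions.items()}
    counts = {sc: math.floor(v) for sc, v in raw.items()}
    leftover = n - sum(counts.values())
    order = sorted(raw, key=lambda sc: (-(raw[sc] - counts[sc]), sc.value))
    for sc in order[:leftover]:
        counts[sc] += 1
    return counts


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

_TERRITORY = 200_000
_FAR_SPACING = 800_000


def _make_genes(n: int, chrom_count: int, rng: np.random.Generator) -> list[GenomicFeature]:
    genes = []
    cursors = {f"chr{c + 1}": 0 for c in range(chrom_count)}
    for i in range(n):
        chrom = f"chr{(i % chrom_count) + 1}"
        base = cursors[chrom]
        gs = base + int(rng.integers(40_000, 60_000))
        e1, e2, e3 = (int(rng.integers(1_000, 3_000)) for _ in range(3))
        i1, i2 = (int(rng.integers(6_000, 10_000)) for _ in range(2))
        exons = [
            (gs, gs + e1),
            (gs + e1 + i1, gs + e1 + i1 + e2),
            (gs + e1 + i1 + e2 + i2, gs + e1 + i1 + e2 + i2 + e3),
        ]
        strand = Strand.plus if rng.random() < 0.5 else Strand.minus
        genes.append(
            GenomicFeature(
                feature_id=f"GENE{i:05d}",
                chrom=chrom,
                start=gs,
                end=exons[-1][1],
                strand=strand,
                molecule_class=MoleculeClass.mRNA,
                gene_name=f"Gene{i}",
                exons=exons,
            )
        )
        cursors[chrom] = base + _TERRITORY
    return genes


def _place_lncrnas(
    cfg: SyntheticConfig,
    lnc_ids: list[str],
    genes: list[GenomicFeature],
    rng: np.random.Generator,
) -> tuple[list[GenomicFeature], dict[str, LncSubclass]]:
    counts = _apportion(cfg.n_lnc, cfg.subclass_mix)
    n_far = int(round(counts[LncSubclass.intergenic] * cfg.intergenic_far_fraction))
    n_attached = cfg.n_lnc - n_far
    if n_attached > len(genes):
        raise ValueError(
            f"impossible placement: {n_attached} gene-attached lncRNAs but only "
            f"{len(genes)} genes; increase n_mrna or chromosome capacity"
        )
    host_idx = list(rng.choice(len(genes), size=n_attached, replace=False))

    # far-intergenic region starts well past every gene territory
    tail_start = max(g.end for g in genes) + _FAR_SPACING
    far_cursor = {g.chrom for g in genes}
    far_cursors = {chrom: tail_start for chrom in sorted(far_cursor)}
    chroms = sorted(far_cursors)

    features: list[GenomicFeature] = []
    subclasses: dict[str, LncSubclass] = {}
    queue = []
    for sc in LncSubclass:
        queue.extend([sc] * counts.get(sc, 0))
    far_left = n_far
    hosts = iter(host_idx)
    for lid, sc in zip(lnc_ids, queue):
        if sc is LncSubclass.intergenic and far_left > 0:
            far_left -= 1
            chrom = chroms[far_left % len(chroms)]
            start = far_cursors[chrom]
            far_cursors[chrom] += _FAR_SPACING
            feat = GenomicFeature(
                lid, chrom, start, start + 2_000,
                Strand.plus if rng.random() < 0.5 else Strand.minus,
                MoleculeClass.lncRNA,
            )
        else:
            g = genes[int(next(hosts))]
            feat = _attach_lncrna(lid, sc, g, rng)
        features.append(feat)
        subclasses[lid] = sc
    return features, subclasses


def _attach_lncrna(
    lid: str, sc: LncSubclass, g: GenomicFeature, rng: np.random.Generator
) -> GenomicFeature:
    opp = Strand.minus if g.strand is Strand.plus else Strand.plus
    exons = g.exons or [(g.start, g.end)]
    (e2a, e2b) = exons[1] if len(exons) > 1 else exons[0]
    if sc is LncSubclass.sense_overlapping:
        return GenomicFeature(lid, g.chrom, e2a - 500, e2b + 500, g.strand, MoleculeClass.lncRNA)
    if sc is LncSubclass.natural_antisense:
        return GenomicFeature(lid, g.chrom, e2a - 500, e2b + 500, opp, MoleculeClass.lncRNA)
    if sc in (LncSubclass.intronic_sense, LncSubclass.intronic_antisense):
        i_start, i_end = exons[0][1], exons[1][0]  # first intron
        a = i_start + 1_000
        b = min(i_end - 1_000, a + 2_500)
        strand = g.strand if sc is LncSubclass.intronic_sense else opp
        return GenomicFeature(lid, g.chrom, a, b, strand, MoleculeClass.lncRNA)
    if sc is LncSubclass.bidirectional:
        if g.strand is Strand.plus:
            return GenomicFeature(lid, g.chrom, g.start - 2_500, g.start - 500, Strand.minus, MoleculeClass.lncRNA)
        return GenomicFeature(lid, g.chrom, g.end + 500, g.end + 2_500, Strand.plus, MoleculeClass.lncRNA)
    # near intergenic: inside the territory margin, clear of the promoter window
    start = max(0, g.start - 35_000)
    return GenomicFeature(
        lid, g.chrom, start, start + 2_000,
        Strand.plus if rng.random() < 0.5 else Strand.minus,
        MoleculeClass.lncRNA,
    )


# ---------------------------------------------------------------------------
# experiment generation
# ---------------------------------------------------------------------------


def generate_experiment(config: SyntheticConfig) -> SyntheticExperiment:
    """Generate a complete seeded experiment with its ground-truth manifest."""
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    rng_de, rng_expr, rng_geo, rng_int, rng_sets = (
        np.random.default_rng(s) for s in root.spawn(5)
    )

    ids = {
        MoleculeClass.lncRNA: [f"LNC{i:05d}" for i in range(cfg.n_lnc)],
        MoleculeClass.mRNA: [f"GENE{i:05d}" for i in range(cfg.n_mrna)],
        MoleculeClass.miRNA: [f"syn-miR-{i:04d}" for i in range(cfg.n_mir)],
    }
    sizes = {
        MoleculeClass.lncRNA: cfg.n_lnc,
        MoleculeClass.mRNA: cfg.n_mrna,
        MoleculeClass.miRNA: cfg.n_mir,
    }

    # ---- planted DE assignment: per comparison, per class, disjoint features
    de_status: dict[str, dict[str, dict[str, str]]] = {
        mc.value: {c.name: {} for c in CANONICAL_COMPARISONS} for mc in ids
    }
    pools = {mc: list(rng_de.permutation(sizes[mc])) for mc in ids}

    def take(mc: MoleculeClass, k: int) -> list[str]:
        chosen, pool = pools[mc][:k], pools[mc][k:]
        if len(chosen) < k:
            raise ValueError(f"not enough {mc.value} features to plant requested DE")
        pools[mc] = pool
        return [ids[mc][i] for i in chosen]

    planted_up: dict[tuple[MoleculeClass, str], list[str]] = {}
    planted_down: dict[tuple[MoleculeClass, str], list[str]] = {}
    for c in CANONICAL_COMPARISONS:
        for mc in ids:
            n_dir = int(round(cfg.de_fraction * sizes[mc]))
            planted_up[(mc, c.name)] = take(mc, n_dir)
            planted_down[(mc, c.name)] = take(mc, n_dir)
            for fid in planted_up[(mc, c.name)]:
                de_status[mc.value][c.name][fid] = "up"
            for fid in planted_down[(mc, c.name)]:
                de_status[mc.value][c.name][fid] = "down"

    # ---- planted sponge triplets drawn from the planted DE sets
    def draw_triplets(n: int, direction: str, offset: int, decoy: bool) -> list[PlantedTriplet]:
        out = []
        for t in range(n):
            c = CANONICAL_COMPARISONS[(t + offset) % len(CANONICAL_COMPARISONS)]
            lnc_pool = planted_up if direction == "up_down_up" else planted_down
            mir_pool = planted_down if direction == "up_down_up" else planted_up
            mrna_pool = planted_up if direction == "up_down_up" else planted_down
            try:
                l = lnc_pool[(MoleculeClass.lncRNA, c.name)].pop(0)
                m = mir_pool[(MoleculeClass.miRNA, c.name)].pop(0)
                g = mrna_pool[(MoleculeClass.mRNA, c.name)].pop(0)
            except IndexError as exc:
                raise ValueError(
                    "de_fraction too small for requested planted triplets"
                ) from exc
            sites = 1 if decoy else int(rng_int.integers(2, 9))
            out.append(PlantedTriplet(l, m, g, direction, c.name, sites))
        return out

    triplets = draw_triplets(cfg.n_planted_triplets_up, "up_down_up", 0, decoy=False)
    triplets += draw_triplets(cfg.n_planted_triplets_down, "down_up_down", 1, decoy=False)
    n_dec_up = cfg.n_decoy_triplets // 2
    decoys = draw_triplets(n_dec_up, "up_down_up", 2, decoy=True)
    decoys += draw_triplets(cfg.n_decoy_triplets - n_dec_up, "down_up_down", 0, decoy=True)

    # ---- expression matrices
    design = _make_design(cfg.n_replicates)
    cell_index = {cell: i for i, cell in enumerate(_CELLS)}
    sample_cells = np.array([cell_index[s.condition] for s in design])
    matrices: dict[MoleculeClass, ExpressionMatrix] = {}
    sponge_lnc_floor = math.log2(4 * 100.0) + cfg.effect_log2
    sponge_lncs = {t.lncRNA_id for t in triplets} | {t.lncRNA_id for t in decoys}
    for mc in ids:
        n = sizes[mc]
        baseline = rng_expr.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)
        if mc is MoleculeClass.lncRNA:
            for i, fid in enumerate(ids[mc]):
                if fid in sponge_lncs:
                    baseline[i] = max(baseline[i], sponge_lnc_floor)
        cell_shift = np.zeros((n, len(_CELLS)))
        index = {fid: i for i, fid in enumerate(ids[mc])}
        for c in CANONICAL_COMPARISONS:
            for fid, status in de_status[mc.value][c.name].items():
                sign = 1.0 if status == "up" else -1.0
                for cell in _EFFECT_CELLS[c.name]:
                    cell_shift[index[fid], cell] += sign * cfg.effect_log2
        log2_means = baseline[:, None] + cell_shift[:, sample_cells]
        noise = rng_expr.normal(0.0, cfg.noise_log2_sd, size=log2_means.shape) if cfg.noise_log2_sd > 0 else 0.0
        values = np.exp2(log2_means + noise)
        df = pd.DataFrame(values, index=ids[mc], columns=design.sample_ids)
        matrices[mc] = ExpressionMatrix(df, design, mc, normalized=False)

    # ---- genome annotation
    genes = _make_genes(cfg.n_mrna, cfg.chrom_count, rng_geo)
    lnc_feats, subclasses = _place_lncrnas(cfg, ids[MoleculeClass.lncRNA], genes, rng_geo)
    mir_feats = []
    mir_tail = max(f.end for f in genes + lnc_feats) + _FAR_SPACING
    for i, mid in enumerate(ids[MoleculeClass.miRNA]):
        chrom = f"chr{(i % cfg.chrom_count) + 1}"
        start = mir_tail + i * 10_000
        mir_feats.append(
            GenomicFeature(mid, chrom, start, start + 80, Strand.plus, MoleculeClass.miRNA)
        )
    features = genes + lnc_feats + mir_feats

    # ---- interactions: planted triplets, 1-site decoys, inert background
    interactions: list[InteractionRecord] = []
    for t in triplets + decoys:
        interactions.append(
            InteractionRecord(
                InteractionKind.lnc_mir, t.lncRNA_id, t.miRNA_id, t.binding_sites, Evidence.validated
            )
        )
        interactions.append(
            InteractionRecord(InteractionKind.mir_mrna, t.miRNA_id, t.mRNA_id, None, Evidence.validated)
        )
    de_mirs = {fid for c in CANONICAL_COMPARISONS for fid in de_status["miRNA"][c.name]}
    quiet_mirs = [m for m in ids[MoleculeClass.miRNA] if m not in de_mirs]
    # keep decoy sponges out of background edges: a multi-site background edge
    # would re-qualify a decoy under the lncRNA-level binding-site filter
    decoy_lncs = {t.lncRNA_id for t in decoys}
    bg_lncs = [l for l in ids[MoleculeClass.lncRNA] if l not in decoy_lncs]
    if quiet_mirs:
        for _ in range(cfg.n_background_lnc_mir):
            interactions.append(
                InteractionRecord(
                    InteractionKind.lnc_mir,
                    bg_lncs[int(rng_int.integers(len(bg_lncs)))],
                    quiet_mirs[int(rng_int.integers(len(quiet_mirs)))],
                    int(rng_int.integers(1, 9)),
                    Evidence.validated,
                )
            )
        for _ in range(cfg.n_background_mir_mrna):
            interactions.append(
                InteractionRecord(
                    InteractionKind.mir_mrna,
                    quiet_mirs[int(rng_int.integers(len(quiet_mirs)))],
                    ids[MoleculeClass.mRNA][int(rng_int.integers(cfg.n_mrna))],
                    None,
                    Evidence.predicted if rng_int.random() < 0.5 else Evidence.validated,
                )
            )

    # ---- gene sets: one planted with DE genes, the rest uniform draws
    all_de_genes = sorted(
        {fid for c in CANONICAL_COMPARISONS for fid in de_status["mRNA"][c.name]}
    )
    non_de_genes = [g for g in ids[MoleculeClass.mRNA] if g not in set(all_de_genes)]
    gene_sets = []
    planted_set_id = "SET_PLANTED"
    if cfg.n_gene_sets > 0:
        k_de = min(int(round(cfg.gene_set_size * cfg.planted_set_de_fraction)), len(all_de_genes))
        members = list(rng_sets.choice(all_de_genes, size=k_de, replace=False)) + list(
            rng_sets.choice(non_de_genes, size=cfg.gene_set_size - k_de, replace=False)
        )
        gene_sets.append(GeneSet(planted_set_id, "planted DE-enriched set", frozenset(members)))
        for s in range(1, cfg.n_gene_sets):
            members = rng_sets.choice(ids[MoleculeClass.mRNA], size=cfg.gene_set_size, replace=False)
            gene_sets.append(GeneSet(f"SET{s:03d}", f"random set {s}", frozenset(members)))

    # ---- ground-truth cis pairs: exact brute force on the planted DE sets
    lnc_by_id = {f.feature_id: f for f in lnc_feats}
    gene_by_id = {f.feature_id: f for f in genes}
    cis = []
    for c in CANONICAL_COMPARISONS:
        de_l = sorted(de_status["lncRNA"][c.name])
        de_g = sorted(de_status["mRNA"][c.name])
        for lid in de_l:
            lf = lnc_by_id[lid]
            for gid in de_g:
                gf = gene_by_id[gid]
                if lf.chrom != gf.chrom:
                    continue
                gap = span_gap(lf.start, lf.end, gf.start, gf.end)
                if gap < cfg.cis_window:
                    cis.append(PlantedCisPair(lid, gid, c.name, gap))

    diseases = [
        DiseaseAnnotation(t.lncRNA_id, ("atherosclerosis", "vascular remodeling"))
        for t in triplets[: min(3, len(triplets))]
    ]

    truth = TruthManifest(
        de_status=de_status,
        triplets=triplets,
        decoy_triplets=decoys,
        subclasses=subclasses,
        cis_pairs=cis,
        planted_set_id=planted_set_id,
    )
    return SyntheticExperiment(
        lnc=matrices[MoleculeClass.lncRNA],
        mrna=matrices[MoleculeClass.mRNA],
        mir=matrices[MoleculeClass.miRNA],
        features=features,
        interactions=interactions,
        gene_sets=gene_sets,
        diseases=diseases,
        truth=truth,
    )
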