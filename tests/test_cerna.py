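"""Sponge-triplet assembly: filters, direction concordance, oracle equality."""

import numpy as np
import pytest

from cerna_weaver.cerna import (
    CernaParams,
    CernaTriplet,
    ModuleSummary,
    annotate_diseases,
    build_cerna,
    mirna_direction,
    select_cerna_lncrnas,
)
from cerna_weaver.diffexpr import DEThresholds, assign_status
from cerna_weaver.model import (
    DERecord,
    DEStatus,
    DiseaseAnnotation,
    Evidence,
    InteractionKind,
    InteractionRecord,
)


def de(fid, comparison="c1", fc=2.0, p=0.01, raw=150.0, annotated=True,
       thresholds=DEThresholds()):
    return DERecord(fid, comparison, raw, raw / fc, fc, float(np.log2(fc)), p, p,
                    raw, assign_status(fc, p, thresholds), annotated)


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------


def _oracle_mir_dir(rec, mode, p_max):
    if mode == "full_threshold":
        return rec.status.value
    if rec.p <= p_max and rec.fc != 1.0:
        return "up" if rec.fc > 1.0 else "down"
    return "ns"


def cerna_bruteforce(de_lnc, de_mir, de_mrna, interactions, params, direction,
                     p_max=0.05):
    """Exhaustive triple loop over lncRNA x edge x target-row combinations."""
    want_lnc, want_mir, want_mrna = (
        ("up", "down", "up") if direction == "up_module" else ("down", "up", "down")
    )
    lnc_ids = {r.feature_id for r in de_lnc}
    mir_ids = {r.feature_id for r in de_mir}
    mrna_ids = {r.feature_id for r in de_mrna}

    # admissible lnc->mir edges among measured features
    raw_edges = []
    for e in interactions:
        if e.kind is not InteractionKind.lnc_mir or e.evidence is not Evidence.validated:
            continue
        members = [t for t in e.target_id.split("|") if t]
        if e.source_id in lnc_ids and all(t in mir_ids for t in members):
            for t in members:
                raw_edges.append((e.source_id, t, e.binding_sites))
    if params.binding_site_scope == "edge":
        edges = [e for e in raw_edges if e[2] >= params.min_binding_sites]
    else:
        best = {}
        for l, _, s in raw_edges:
            best[l] = max(best.get(l, 0), s)
        edges = [e for e in raw_edges if best[e[0]] >= params.min_binding_sites]

    triplets = set()
    comparisons = {r.comparison for r in de_lnc}
    for c in comparisons:
        for rl in de_lnc:
            if rl.comparison != c or rl.status.value != want_lnc:
                continue
            if rl.raw_intensity <= params.min_raw_intensity:
                continue
            if params.require_reference_annotation and not rl.annotated_in_reference:
                continue
            for (l, m, sites) in edges:
                if l != rl.feature_id:
                    continue
                rm = next((r for r in de_mir if r.comparison == c and r.feature_id == m), None)
                if rm is None or _oracle_mir_dir(rm, params.mirna_direction_mode, p_max) != want_mir:
                    continue
                for idx, row in enumerate(interactions):
                    if row.kind is not InteractionKind.mir_mrna:
                        continue
                    if params.mrna_evidence == "validated_only" and row.evidence is not Evidence.validated:
                        continue
                    members = [t for t in row.source_id.split("|") if t]
                    if any(t not in mir_ids for t in members) or row.target_id not in mrna_ids:
                        continue
                    if m not in members:
                        continue
                    rg = next(
                        (r for r in de_mrna if r.comparison == c and r.feature_id == row.target_id),
                        None,
                    )
                    if rg is None or rg.status.value != want_mrna:
                        continue
                    triplets.add((c, l, m, row.target_id, sites, idx))
    return triplets


def random_instance(rng, allow_ghosts=True):
    thresholds = DEThresholds()
    comparisons = ["c1", "c2"]
    n_l, n_m, n_g = (int(rng.integers(2, 21)) for _ in range(3))
    de_lnc, de_mir, de_mrna = [], [], []
    for i in range(n_l):
        for c in comparisons:
            de_lnc.append(de(f"L{i}", c, fc=float(np.exp2(rng.normal(0, 1.5))),
                             p=float(rng.uniform(0, 0.1)),
                             raw=float(rng.uniform(50, 200)),
                             annotated=bool(rng.random() < 0.8)))
    for i in range(n_m):
        for c in comparisons:
            de_mir.append(de(f"m{i}", c, fc=float(np.exp2(rng.normal(0, 1.0))),
                             p=float(rng.uniform(0, 0.1))))
    for i in range(n_g):
        for c in comparisons:
            de_mrna.append(de(f"G{i}", c, fc=float(np.exp2(rng.normal(0, 1.5))),
                              p=float(rng.uniform(0, 0.1))))
    interactions = []
    for _ in range(int(rng.integers(0, 30))):
        src = f"L{rng.integers(n_l + (2 if allow_ghosts else 0))}"
        tgt = f"m{rng.integers(n_m + (2 if allow_ghosts else 0))}"
        interactions.append(InteractionRecord(
            InteractionKind.lnc_mir, src, tgt, int(rng.integers(1, 9)),
            Evidence.validated if rng.random() < 0.8 else Evidence.predicted))
    for _ in range(int(rng.integers(0, 40))):
        k = int(rng.integers(1, 3))
        members = sorted({f"m{rng.integers(n_m + (2 if allow_ghosts else 0))}" for _ in range(k)})
        interactions.append(InteractionRecord(
            InteractionKind.mir_mrna, "|".join(members),
            f"G{rng.integers(n_g + (2 if allow_ghosts else 0))}", None,
            Evidence.validated if rng.random() < 0.6 else Evidence.predicted))
    return de_lnc, de_mir, de_mrna, interactions


class TestSelectLncrnas:
    def test_filters(self):
        records = [
            de("keep", fc=3.68, p=0.03),
            de("dim", fc=3.0, p=0.01, raw=80.0),          # below intensity floor
            de("down", fc=0.4, p=0.01),                    # wrong direction
            de("uncat", fc=3.0, p=0.01, annotated=False),  # not in reference
            de("flat", fc=1.1, p=0.01),                    # ns
        ]
        assert select_cerna_lncrnas(records, DEStatus.up) == ["keep"]

    def test_unannotated_kept_when_not_required(self):
        records = [de("uncat", fc=3.0, p=0.01, annotated=False)]
        params = CernaParams(require_reference_annotation=False)
        assert select_cerna_lncrnas(records, DEStatus.up, params) == ["uncat"]

    def test_sorted_by_effect_then_id(self):
        records = [de("b", fc=2.0), de("a", fc=2.0), de("c", fc=8.0)]
        assert select_cerna_lncrnas(records, DEStatus.up) == ["c", "a", "b"]


class TestMirnaDirection:
    def test_sub_threshold_fold_change_called_by_significance(self):
        rec = de("m1", fc=0.89, p=0.014)
        assert mirna_direction(rec, "significance_only") is DEStatus.down
        assert mirna_direction(rec, "full_threshold") is DEStatus.ns

    def test_strong_fold_change_down_in_both_modes(self):
        rec = de("m2", fc=0.01, p=0.001)
        assert mirna_direction(rec, "significance_only") is DEStatus.down
        assert mirna_direction(rec, "full_threshold") is DEStatus.down

    def test_not_significant_is_ns(self):
        rec = de("m3", fc=0.5, p=0.2)
        assert mirna_direction(rec, "significance_only") is DEStatus.ns


class TestBuildCerna:
    def test_empty_interactions(self):
        triplets, summary = build_cerna([de("L1")], [de("m1", fc=0.5)], [de("G1")], [])
        assert triplets == []
        assert (summary.n_lncRNA_distinct, summary.n_miRNA_distinct,
                summary.n_mrna_associations, summary.triplet_count) == (0, 0, 0, 0)

    def test_direction_invariant_holds(self):
        rng = np.random.default_rng(37)
        for _ in range(30):
            de_lnc, de_mir, de_mrna, ints = random_instance(rng)
            for direction in ("up_module", "down_module"):
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    triplets, _ = build_cerna(de_lnc, de_mir, de_mrna, ints,
                                              CernaParams(), direction)
                for t in triplets:
                    if t.direction == "up_down_up":
                        assert t.lnc_fc > 1 and t.mir_fc < 1 and t.mrna_fc > 1
                    else:
                        assert t.lnc_fc < 1 and t.mir_fc > 1 and t.mrna_fc < 1

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            de_lnc, de_mir, de_mrna, ints = random_instance(rng)
            params = CernaParams(
                binding_site_scope="edge" if rng.random() < 0.5 else "lncrna",
                mrna_evidence="validated_only" if rng.random() < 0.5 else "validated_or_predicted",
                mirna_direction_mode="full_threshold" if rng.random() < 0.3 else "significance_only",
            )
            direction = "up_module" if rng.random() < 0.5 else "down_module"
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # ghost rows warn; counted elsewhere
                triplets, _ = build_cerna(de_lnc, de_mir, de_mrna, ints, params, direction)
            got = {(t.comparison, t.lncRNA_id, t.miRNA_id, t.mRNA_id,
                    t.binding_sites, t.association_row) for t in triplets}
            assert len(got) == len(triplets)
            assert got == cerna_bruteforce(de_lnc, de_mir, de_mrna, ints, params, direction)

    def test_input_permutation_invariance(self):
        rng = np.random.default_rng(43)
        de_lnc, de_mir, de_mrna, ints = random_instance(rng, allow_ghosts=False)
        t1, s1 = build_cerna(de_lnc, de_mir, de_mrna, ints)
        perm = [de_lnc, de_mir, de_mrna]
        for lst in perm:
            rng.shuffle(lst)
        key = lambda ts: {(t.comparison, t.lncRNA_id, t.miRNA_id, t.mRNA_id, t.binding_sites)
                          for t in ts}
        t2, s2 = build_cerna(*perm, ints)
        assert key(t1) == key(t2)
        assert s1 == s2

    def test_filter_monotonicity(self):
        rng = np.random.default_rng(47)
        for _ in range(20):
            de_lnc, de_mir, de_mrna, ints = random_instance(rng, allow_ghosts=False)
            key = lambda ts: {(t.comparison, t.lncRNA_id, t.miRNA_id, t.mRNA_id,
                               t.association_row) for t in ts}
            base = key(build_cerna(de_lnc, de_mir, de_mrna, ints, CernaParams())[0])
            stricter_sites = key(build_cerna(de_lnc, de_mir, de_mrna, ints,
                                             CernaParams(min_binding_sites=5))[0])
            stricter_raw = key(build_cerna(de_lnc, de_mir, de_mrna, ints,
                                           CernaParams(min_raw_intensity=180.0))[0])
            assert stricter_sites <= base
            assert stricter_raw <= base

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(53)
        for _ in range(20):
            de_lnc, de_mir, de_mrna, ints = random_instance(rng, allow_ghosts=False)
            inv = lambda rs: [de(r.feature_id, r.comparison, fc=1.0 / r.fc, p=r.p,
                                 raw=r.raw_intensity, annotated=r.annotated_in_reference)
                              for r in rs]
            key = lambda ts: {(t.comparison, t.lncRNA_id, t.miRNA_id, t.mRNA_id,
                               t.association_row) for t in ts}
            down = key(build_cerna(de_lnc, de_mir, de_mrna, ints,
                                   direction="down_module")[0])
            up_inv = key(build_cerna(inv(de_lnc), inv(de_mir), inv(de_mrna), ints,
                                     direction="up_module")[0])
            assert down == up_inv

    def test_edge_scope_drops_single_site_edge_lncrna_scope_keeps_it(self):
        de_lnc = [de("L1", fc=0.3)]
        de_mir = [de("mA", fc=1.7), de("mB", fc=1.6)]
        de_mrna = [de("G1", fc=0.4), de("G2", fc=0.4)]
        ints = [
            InteractionRecord(InteractionKind.lnc_mir, "L1", "mA", 3),
            InteractionRecord(InteractionKind.lnc_mir, "L1", "mB", 1),
            InteractionRecord(InteractionKind.mir_mrna, "mA", "G1"),
            InteractionRecord(InteractionKind.mir_mrna, "mB", "G2"),
        ]
        lax, _ = build_cerna(de_lnc, de_mir, de_mrna, ints,
                             CernaParams(binding_site_scope="lncrna"), "down_module")
        strict, _ = build_cerna(de_lnc, de_mir, de_mrna, ints,
                                CernaParams(binding_site_scope="edge"), "down_module")
        assert {t.miRNA_id for t in lax} == {"mA", "mB"}
        assert {t.miRNA_id for t in strict} == {"mA"}

    def test_predicted_lnc_mir_edges_never_used(self):
        ints = [
            InteractionRecord(InteractionKind.lnc_mir, "L1", "mA", 5, Evidence.predicted),
            InteractionRecord(InteractionKind.mir_mrna, "mA", "G1"),
        ]
        triplets, _ = build_cerna([de("L1")], [de("mA", fc=0.5)], [de("G1")], ints)
        assert triplets == []

    def test_summary_counts_association_rows_with_multiplicity(self):
        # the same (miRNA, mRNA) listed twice joins twice
        ints = [
            InteractionRecord(InteractionKind.lnc_mir, "L1", "mA", 4),
            InteractionRecord(InteractionKind.mir_mrna, "mA", "G1"),
            InteractionRecord(InteractionKind.mir_mrna, "mA", "G1"),
        ]
        args = ([de("L1")], [de("mA", fc=0.5)], [de("G1")], ints)
        _, summary = build_cerna(*args)
        assert summary.n_mrna_associations == 2
        assert summary.n_mrna_distinct == 1
        _, dedup = build_cerna(*args, CernaParams(dedup_associations=True))
        assert dedup.n_mrna_associations == 1


class TestAnnotateDiseases:
    def _triplet(self):
        return CernaTriplet("L1", "m1", "G1", 4, 2.0, 0.5, 2.0,
                            "up_down_up", "c1", "validated")

    def test_empty_table_empty_terms(self):
        out = annotate_diseases([self._triplet()], [])
        assert out[0].disease_terms == ()

    def test_join_and_idempotence(self):
        table = [DiseaseAnnotation("L1", ("atherosclerosis",))]
        once = annotate_diseases([self._triplet()], table)
        assert once[0].disease_terms == ("atherosclerosis",)
        twice = annotate_diseases(once, table)
        assert twice == once


def test_module_summary_rejects_inconsistent_counts():
    with pytest.raises(ValueError):
        ModuleSummary("up_module", ("c1",), 1, 1, 2, 3, 5)
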