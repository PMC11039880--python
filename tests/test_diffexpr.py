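"""Quantile normalization, Welch test, BH, status calls and clustering."""

import numpy as np
import pandas as pd
import pytest

from cerna_weaver.diffexpr import (
    DEThresholds,
    Dendrogram,
    assign_status,
    bh_adjust,
    correlation_distance,
    differential_expression,
    hierarchical_cluster,
    quantile_normalize,
    welch_t,
)
from cerna_weaver.model import (
    CANONICAL_COMPARISONS,
    DEStatus,
    ExpressionMatrix,
    Knockdown,
    MoleculeClass,
    Sample,
    SampleDesign,
    Treatment,
)

from conftest import make_design, make_matrix


def two_group_design(n=3):
    samples = [
        Sample(f"t{r}", Knockdown.siNT, Treatment.POVPC, r) for r in range(1, n + 1)
    ] + [Sample(f"c{r}", Knockdown.siNT, Treatment.DMSO, r) for r in range(1, n + 1)]
    return SampleDesign(samples)


POVPC_CMP = CANONICAL_COMPARISONS[0]


class TestQuantileNormalize:
    def test_single_column_unchanged(self):
        design = SampleDesign([Sample("s1", Knockdown.siNT, Treatment.DMSO, 1)])
        m = make_matrix(np.array([[3.0], [1.0], [2.0]]), design)
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)
        assert out.normalized

    def test_two_column_hand_oracle(self):
        design = SampleDesign([
            Sample("s1", Knockdown.siNT, Treatment.DMSO, 1),
            Sample("s2", Knockdown.siNT, Treatment.DMSO, 2),
        ])
        m = make_matrix(np.array([[1.0, 4.0], [3.0, 2.0]]), design)
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, [[1.5, 3.5], [3.5, 1.5]])

    def test_columns_share_sorted_values(self, design):
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = make_matrix(rng.uniform(0, 1000, size=(30, len(design))), design)
            out = quantile_normalize(m).values
            ref = np.sort(out[:, 0])
            for j in range(out.shape[1]):
                np.testing.assert_allclose(np.sort(out[:, j]), ref, rtol=0, atol=1e-12)

    def test_ties_get_mean_of_spanned_reference(self):
        design = SampleDesign([
            Sample("s1", Knockdown.siNT, Treatment.DMSO, 1),
            Sample("s2", Knockdown.siNT, Treatment.DMSO, 2),
        ])
        # column 1 is constant: every entry gets the mean of the reference
        m = make_matrix(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]), design)
        out = quantile_normalize(m).values
        assert np.allclose(out[:, 0], out[:, 0].mean())

    def test_empty_matrix_errors(self):
        design = SampleDesign([Sample("s1", Knockdown.siNT, Treatment.DMSO, 1)])
        m = make_matrix(np.empty((0, 1)), design, feature_ids=[])
        with pytest.raises(ValueError):
            quantile_normalize(m)


class TestWelch:
    def test_identical_groups(self):
        design = two_group_design()
        m = make_matrix(np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]]), design)
        t, df, p = welch_t(m, "F000", POVPC_CMP)
        assert t == 0.0 and p == 1.0

    def test_matches_reference_implementation(self):
        # frozen from R t.test on the log2-scale values below
        a = np.array([12.1, 10.3, 11.7, 9.9])
        b = np.array([8.2, 9.5, 8.8, 10.1])
        design = two_group_design(4)
        values = np.concatenate([np.exp2(a) - 1.0, np.exp2(b) - 1.0])[None, :]
        m = make_matrix(values, design)
        t, df, p = welch_t(m, "F000", POVPC_CMP, pseudocount=1.0)
        assert t == pytest.approx(2.745137485904, abs=1e-9)
        assert df == pytest.approx(5.653132434576, abs=1e-9)
        assert p == pytest.approx(3.562979266863e-02, abs=1e-9)

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(3)
        design = two_group_design()
        vals = rng.uniform(1, 100, size=6)
        m = make_matrix(vals[None, :], design)
        swapped = make_matrix(np.concatenate([vals[3:], vals[:3]])[None, :], design)
        _, _, p1 = welch_t(m, "F000", POVPC_CMP)
        _, _, p2 = welch_t(swapped, "F000", POVPC_CMP)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_zero_variance_conventions(self):
        design = two_group_design()
        same = make_matrix(np.array([[4.0] * 6]), design)
        assert welch_t(same, "F000", POVPC_CMP)[2] == 1.0
        diff = make_matrix(np.array([[8.0] * 3 + [4.0] * 3]), design)
        t, _, p = welch_t(diff, "F000", POVPC_CMP)
        assert p == 0.0 and t == np.inf

    def test_requires_two_replicates(self):
        design = SampleDesign([
            Sample("t1", Knockdown.siNT, Treatment.POVPC, 1),
            Sample("c1", Knockdown.siNT, Treatment.DMSO, 1),
            Sample("c2", Knockdown.siNT, Treatment.DMSO, 2),
        ])
        m = make_matrix(np.array([[1.0, 2.0, 3.0]]), design)
        with pytest.raises(ValueError, match="replicate"):
            welch_t(m, "F000", POVPC_CMP)


def bh_bruteforce(p):
    """Step-up definition: adj_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):
        running = min(running, p[order[rank]] * m / (rank + 1))
        adj_sorted[rank] = min(1.0, running)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBH:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestStatus:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [
            (3.68, 0.03, DEStatus.up),      # printed upregulated sponge lncRNA
            (0.46, 0.001, DEStatus.down),   # printed downregulated partner miRNA
            (1.0, 0.001, DEStatus.ns),
            (2.0, 0.2, DEStatus.ns),
            (1.5, 0.05, DEStatus.up),       # thresholds are inclusive
            (1 / 1.5, 0.05, DEStatus.down),
        ],
    )
    def test_threshold_calls(self, fc, p, expected):
        assert assign_status(fc, p, DEThresholds()) is expected


class TestDifferentialExpression:
    def test_row_permutation_invariance(self, design):
        rng = np.random.default_rng(11)
        m = make_matrix(rng.uniform(1, 500, size=(20, len(design))), design)
        perm = rng.permutation(20)
        m2 = ExpressionMatrix(m.data.iloc[perm], design, MoleculeClass.mRNA)
        r1 = differential_expression(m, POVPC_CMP)
        r2 = differential_expression(m2, POVPC_CMP)
        assert [vars(a) for a in r1] == [vars(b) for b in r2]

    def test_status_antisymmetry(self, design):
        rng = np.random.default_rng(13)
        m = make_matrix(rng.uniform(1, 500, size=(30, len(design))), design)
        fwd = differential_expression(m, POVPC_CMP)
        from cerna_weaver.model import Comparison
        rev = differential_expression(
            m,
            Comparison("rev", POVPC_CMP.control_group, POVPC_CMP.test_group),
        )
        flip = {DEStatus.up: DEStatus.down, DEStatus.down: DEStatus.up, DEStatus.ns: DEStatus.ns}
        for a, b in zip(fwd, rev):
            assert b.fc == pytest.approx(1.0 / a.fc, rel=1e-9)
            assert b.status is flip[a.status]

    def test_missing_group_errors(self):
        design = two_group_design()
        m = make_matrix(np.ones((2, 6)), design)
        with pytest.raises(ValueError):
            differential_expression(m, CANONICAL_COMPARISONS[1])


def average_linkage_bruteforce(dist):
    """O(n^3) UPGMA: track clusters as leaf sets, merge min average distance."""
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i_pos, ki in enumerate(keys):
            for kj in keys[i_pos + 1:]:
                d = np.mean([dist[a, b] for a in clusters[ki] for b in clusters[kj]])
                if best is None or d < best[0]:
                    best = (d, ki, kj)
        d, ki, kj = best
        merges.append((clusters[ki], clusters[kj], d))
        clusters[min(ki, kj)] = clusters.pop(ki) | clusters.pop(kj)
    return merges


class TestHierarchicalCluster:
    def test_identical_rows_merge_first_at_zero(self, design):
        rng = np.random.default_rng(17)
        base = rng.uniform(size=len(design))
        rows = np.vstack([base, base, rng.uniform(size=len(design))])
        m = make_matrix(rows, design, feature_ids=["A", "B", "C"])
        dg = hierarchical_cluster(m, "features")
        assert dg.merges[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert sorted(dg.merges[0, :2]) == [0, 1]  # A and B

    def test_block_structure_pairs_merge_before_cross(self, design):
        rng = np.random.default_rng(19)
        u, v = rng.uniform(size=len(design)), rng.uniform(size=len(design))
        rows = np.vstack([u, 2 * u + 1, v, 3 * v + 2])  # two perfectly correlated pairs
        m = make_matrix(rows, design, feature_ids=["a1", "a2", "b1", "b2"])
        dg = hierarchical_cluster(m, "features")
        first_two = {tuple(sorted(dg.merges[i, :2])) for i in range(2)}
        assert first_two == {(0, 1), (2, 3)}
        assert dg.merges[0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_matches_bruteforce_oracle(self, design):
        rng = np.random.default_rng(23)
        m = make_matrix(rng.uniform(size=(8, 6)), _six_sample_design(),
                        feature_ids=[f"r{i}" for i in range(8)])
        dg = hierarchical_cluster(m, "features")
        dist = correlation_distance(m.data.sort_index().to_numpy())
        expected = average_linkage_bruteforce(dist)
        # replay scipy merge matrix into leaf-set merges
        n = 8
        members = {i: frozenset([i]) for i in range(n)}
        for step, (li, ri, h, _size) in enumerate(dg.merges):
            a, b = members[int(li)], members[int(ri)]
            ea, eb, eh = expected[step]
            assert {a, b} == {ea, eb}
            assert h == pytest.approx(eh, abs=1e-10)
            members[n + step] = a | b

    def test_zero_variance_row_distance_one(self):
        rows = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        dist = correlation_distance(rows)
        assert dist[0, 1] == 1.0

    def test_needs_two_items(self, design):
        m = make_matrix(np.ones((1, len(design))), design)
        with pytest.raises(ValueError):
            hierarchical_cluster(m, "features")


def _six_sample_design():
    from cerna_weaver.model import Sample, SampleDesign, Knockdown, Treatment
    return SampleDesign([
        Sample(f"s{r}", Knockdown.siNT, Treatment.DMSO, r) for r in range(1, 7)
    ])
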