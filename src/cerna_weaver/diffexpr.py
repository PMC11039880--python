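"""Microarray-style differential expression.

Quantile normalization, linear fold change on group means, Welch's t-test on
log2 intensities, up/down/ns status at a fold-change + p-value threshold
(defaults 1.5x and 0.05), optional Benjamini-Hochberg adjustment, and
average-linkage hierarchical clustering on correlation distance for heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import squareform
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .model import Comparison, DERecord, DEStatus, ExpressionMatrix


@dataclass(frozen=True)
class DEThresholds:
    """Significance thresholds: |FC| >= fc_min (down means FC <= 1/fc_min) and
    p <= p_max, on raw p by default."""

    fc_min: float = 1.5
    p_max: float = 0.05
    use_adjusted_p: bool = False

    def __post_init__(self) -> None:
        if self.fc_min <= 1:
            raise ValueError("fc_min must be > 1")
        if not (0 < self.p_max <= 1):
            raise ValueError("p_max must be in (0, 1]")


# --------------------------------------------------------------------------
# quantile normalization
# --------------------------------------------------------------------------


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Make every column's value distribution identical to the reference
    (row means of column-sorted values); ties within a column receive the mean
    of the reference values they span."""
    data = matrix.data
    if data.shape[0] == 0 or data.shape[1] == 0:
        raise ValueError("cannot quantile-normalize an empty matrix")
    values = data.to_numpy(dtype=float)
    reference = np.mean(np.sort(values, axis=0), axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty_like(reference)
        ranked[order] = reference
        # average reference values across tied entries
        out[:, j] = pd.Series(ranked).groupby(col).transform("mean").to_numpy()
    normalized = pd.DataFrame(out, index=data.index, columns=data.columns)
    return matrix.with_data(normalized, normalized=True)


# --------------------------------------------------------------------------
# Welch's t-test
# --------------------------------------------------------------------------


def _welch_arrays(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch t, Welch-Satterthwaite df and two-sided p along axis 1.

    Conventions for degenerate rows (zero variance in both groups): equal
    means -> (t=0, p=1); unequal means -> (t=+/-inf, p=0).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * _stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    equal = degenerate & (ma == mb)
    unequal = degenerate & (ma != mb)
    t = np.where(equal, 0.0, t)
    p = np.where(equal, 1.0, p)
    t = np.where(unequal, np.where(ma > mb, np.inf, -np.inf), t)
    p = np.where(unequal, 0.0, p)
    df = np.where(degenerate, na + nb - 2.0, df)
    return t, df, p


def welch_t(
    matrix: ExpressionMatrix,
    feature_id: str,
    comparison: Comparison,
    pseudocount: float = 1.0,
) -> tuple[float, float, float]:
    """Two-sided Welch t-test on log2(intensity + pseudocount) for one feature."""
    for cond in (comparison.test_group, comparison.control_group):
        matrix.design.require_replicates(cond, 2)
    if feature_id not in matrix.data.index:
        raise KeyError(f"feature {feature_id!r} not in matrix")
    row = matrix.data.loc[feature_id]
    a = np.log2(row[matrix.design.columns_for(comparison.test_group)].to_numpy() + pseudocount)
    b = np.log2(row[matrix.design.columns_for(comparison.control_group)].to_numpy() + pseudocount)
    t, df, p = _welch_arrays(a[None, :], b[None, :])
    return float(t[0]), float(df[0]), float(p[0])


# --------------------------------------------------------------------------
# Benjamini-Hochberg
# --------------------------------------------------------------------------


def bh_adjust(p_values) -> np.ndarray:
    """Step-up FDR adjustment, returned in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# differential expression
# --------------------------------------------------------------------------


def assign_status(fc: float, p_criterion: float, thresholds: DEThresholds) -> DEStatus:
    """Status from a linear fold change and the applicable p-value."""
    if p_criterion <= thresholds.p_max:
        if fc >= thresholds.fc_min:
            return DEStatus.up
        if fc <= 1.0 / thresholds.fc_min:
            return DEStatus.down
    return DEStatus.ns


def differential_expression(
    matrix: ExpressionMatrix,
    comparison: Comparison,
    thresholds: DEThresholds = DEThresholds(),
    raw_matrix: Optional[ExpressionMatrix] = None,
    pseudocount: float = 1.0,
    annotated_in_reference: Optional[dict[str, bool]] = None,
) -> list[DERecord]:
    """One DERecord per feature for a two-group contrast.

    Fold change is computed on (normalized) linear-scale group means; the
    t-test on log2(intensity + pseudocount). ``raw_matrix`` supplies the
    un-normalized test-group mean recorded as ``raw_intensity`` (falls back to
    ``matrix`` itself). Output is sorted by feature id.
    """
    design = matrix.design
    test_cols = design.require_replicates(comparison.test_group, 2)
    ctrl_cols = design.require_replicates(comparison.control_group, 2)
    data = matrix.data
    a = data[test_cols].to_numpy(dtype=float)
    b = data[ctrl_cols].to_numpy(dtype=float)
    mean_test = a.mean(axis=1)
    mean_ctrl = b.mean(axis=1)
    eps = 1e-12
    fc = np.maximum(mean_test, eps) / np.maximum(mean_ctrl, eps)
    _, _, p = _welch_arrays(np.log2(a + pseudocount), np.log2(b + pseudocount))
    adj = bh_adjust(p)

    if raw_matrix is not None:
        if list(raw_matrix.data.index) != list(data.index):
            raise ValueError("raw matrix features do not match normalized matrix")
        raw_means = raw_matrix.data[test_cols].to_numpy(dtype=float).mean(axis=1)
    else:
        raw_means = mean_test

    annotated_in_reference = annotated_in_reference or {}
    records = []
    for i, fid in enumerate(data.index):
        crit = adj[i] if thresholds.use_adjusted_p else p[i]
        records.append(
            DERecord(
                feature_id=str(fid),
                comparison=comparison.name,
                mean_test=float(mean_test[i]),
                mean_control=float(mean_ctrl[i]),
                fc=float(fc[i]),
                log2fc=float(np.log2(fc[i])),
                p=float(p[i]),
                adj_p=float(adj[i]),
                raw_intensity=float(raw_means[i]),
                status=assign_status(float(fc[i]), float(crit), thresholds),
                annotated_in_reference=annotated_in_reference.get(str(fid), True),
            )
        )
    records.sort(key=lambda r: r.feature_id)
    return records


# --------------------------------------------------------------------------
# hierarchical clustering
# --------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Average-linkage dendrogram: ids (leaf labels, lexicographic input
    order), scipy-style merge matrix, and the ordered leaves."""

    ids: list[str]
    merges: np.ndarray  # (n-1, 4): left, right, height, size
    leaf_order: list[str]


def correlation_distance(rows: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson distance; pairs involving a zero-variance row get
    distance 1 (correlation undefined)."""
    rows = np.asarray(rows, dtype=float)
    sd = rows.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(rows)
    dist = 1.0 - corr
    bad = sd == 0
    dist[bad, :] = 1.0
    dist[:, bad] = 1.0
    np.fill_diagonal(dist, 0.0)
    # clip tiny negative round-off from correlations slightly above 1
    return np.clip(dist, 0.0, None)


def hierarchical_cluster(matrix: ExpressionMatrix, axis: str = "features") -> Dendrogram:
    """Cluster features (rows) or samples (columns) with average linkage on
    correlation distance. Items are pre-sorted by id so equal-distance merges
    resolve toward the lexicographically smallest member."""
    if axis == "features":
        df = matrix.data
    elif axis == "samples":
        df = matrix.data.T
    else:
        raise ValueError("axis must be 'features' or 'samples'")
    if df.shape[0] < 2:
        raise ValueError("need at least two items to cluster")
    df = df.sort_index(kind="mergesort")
    ids = [str(i) for i in df.index]
    dist = correlation_distance(df.to_numpy())
    z = _hier.linkage(squareform(dist, checks=False), method="average")
    leaf_order = [ids[i] for i in _hier.leaves_list(z)]
    return Dendrogram(ids=ids, merges=z, leaf_order=leaf_order)
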