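"""Gene-set over-representation by the right-tailed Fisher exact test.

For a DE list of size n drawn from a measured background of size N, a set with
K measured members and k DE members is scored with the hypergeometric upper
tail P(X >= k). The background defaults to all measured features of the
molecule class under test. Adjusted p-values are Benjamini-Hochberg across all
tested sets in one run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _stats

from .diffexpr import bh_adjust
from .model import GeneSet

#: below this background size the tail is summed with exact integer
#: combinatorics in log space (bit-exact small cases); above it, scipy's
#: hypergeometric survival function is used.
_EXACT_N = 1000


def fisher_right(k: int, K: int, n: int, N: int) -> float:
    """Right tail P(X >= k) for X ~ Hypergeom(N, K, n).

    k = DE hits in the set, K = measured set size, n = DE list size,
    N = measured background size.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(f"invalid table: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    if N <= _EXACT_N:
        denom = math.comb(N, n)
        total = sum(
            math.comb(K, i) * math.comb(N - K, n - i)
            for i in range(k, min(K, n) + 1)
        )
        return min(1.0, total / denom)
    return float(min(1.0, math.exp(_stats.hypergeom.logsf(k - 1, N, K, n))))


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    description: str
    k: int
    K: int
    n: int
    N: int
    p_right: float
    adj_p: float
    fold_enrichment: float


def enrich(
    de_ids: Iterable[str],
    background_ids: Iterable[str],
    sets: Sequence[GeneSet],
) -> list[EnrichmentResult]:
    """Test every gene set (intersected with the background) with K >= 1.

    Results are BH-adjusted and sorted by (p ascending, set_id ascending).
    Raises if the DE list is not a subset of the background.
    """
    de = set(de_ids)
    background = set(background_ids)
    offenders = sorted(de - background)
    if offenders:
        raise ValueError(f"DE ids not in background: {offenders[:10]}")
    n, N = len(de), len(background)

    rows = []
    for s in sorted(sets, key=lambda s: s.set_id):
        measured = s.members & background
        K = len(measured)
        if K == 0:
            continue
        k = len(measured & de)
        p = fisher_right(k, K, n, N)
        fold = (k / n) / (K / N) if n > 0 and k > 0 else 0.0
        rows.append((s, k, K, p, fold))
    if not rows:
        return []
    adj = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(
            set_id=s.set_id,
            description=s.description,
            k=k,
            K=K,
            n=n,
            N=N,
            p_right=p,
            adj_p=float(a),
            fold_enrichment=fold,
        )
        for (s, k, K, p, fold), a in zip(rows, adj)
    ]
    results.sort(key=lambda r: (r.p_right, r.set_id))
    return results
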