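"""Hypergeometric over-representation of functional clusters.

Cluster membership of a target protein list (e.g. the enriched set) is
tested against the full MS-identified background: for a cluster with K
members among N background proteins, observing k members in a target of
size n has upper-tail probability P(X ≥ k) under X ~ Hypergeom(N, K, n).
Raw p-values are reported; the display threshold used downstream is a
reporting cutoff, not a multiplicity adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ClusterResult:
    cluster: str
    k: int
    K: int
    n: int
    N: int
    p: float


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X ≥ k) for X ~ Hypergeom(N, K, n), exact at small sizes.

    Arguments follow the over-representation convention: N background
    proteins of which K belong to the cluster; n drawn into the target list
    of which k belong to the cluster.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"hypergeometric bounds violated: k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def test_clusters(
    target: set, background: set, annotation: dict[str, set[str]]
) -> list[ClusterResult]:
    """Over-representation of every annotated cluster in the target list.

    Proteins carrying several cluster labels count in each of their
    clusters; proteins without annotation contribute to the totals N and n
    but to no cluster.  Results are sorted by increasing p.
    """
    target = set(target)
    background = set(background)
    offenders = target - background
    if offenders:
        raise ValueError(
            f"target is not a subset of the background: {sorted(offenders)[:10]}"
        )
    clusters: dict[str, set] = {}
    for pid, labels in annotation.items():
        if pid not in background:
            continue
        for lab in labels:
            clusters.setdefault(lab, set()).add(pid)
    if not clusters:
        warnings.warn("no annotated background proteins; empty result",
                      stacklevel=2)
        return []
    N, n = len(background), len(target)
    results = [
        ClusterResult(
            cluster=lab,
            k=len(members & target),
            K=len(members),
            n=n,
            N=N,
            p=hypergeom_upper_tail(len(members & target), len(members), n, N),
        )
        for lab, members in clusters.items()
    ]
    return sorted(results, key=lambda r: (r.p, r.cluster))


def cluster_table(results: list[ClusterResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [r.__dict__ for r in results],
        columns=["cluster", "k", "K", "n", "N", "p"],
    )
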