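"""Brute-force reference implementations used as independent oracles.

The naive UPGMA below evaluates the average-distance formula
d(u,v) = sum_ij d(u_i, v_j) / (|u|*|v|) directly over the full pairwise
distance matrix at every step (O(n^3)), records the merge history, and
derives the cophenetic matrix and tree-cut partitions from it. It shares
only the tie-break convention (merge the pair whose leftmost member has the
smallest coordinate) with the production code, not the algorithm.
"""

from __future__ import annotations

import itertools

import numpy as np


def naive_upgma(positions):
    """Return (merge history, cophenetic matrix) for 1-D coordinates.

    merges: list of (members_a, members_b, height) with members as leaf-index
    tuples; cophenetic: symmetric n x n array.
    """
    pos = np.sort(np.asarray(positions, dtype=float))
    n = len(pos)
    dist = np.abs(pos[:, None] - pos[None, :])
    clusters: list[tuple[int, ...]] = [(i,) for i in range(n)]
    merges = []
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            A, B = clusters[a], clusters[b]
            d = sum(dist[i, j] for i in A for j in B) / (len(A) * len(B))
            key = (d, min(pos[i] for i in A + B), min(A + B))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _, _), a, b = best
        A, B = clusters[a], clusters[b]
        for i in A:
            for j in B:
                coph[i, j] = coph[j, i] = d
        merges.append((A, B, d))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [A + B]
    return merges, coph


def naive_flat_clusters(positions, t):
    """Tree cut at height t via union-find over the naive merge history
    (UPGMA merge heights are monotone, so merges with h <= t form the cut)."""
    pos = np.sort(np.asarray(positions, dtype=float))
    n = len(pos)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merges, _ = naive_upgma(pos)
    for A, B, h in merges:
        if h <= t:
            ra, rb = find(A[0]), find(B[0])
            parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted((tuple(sorted(g)) for g in groups.values()), key=lambda g: g[0])
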