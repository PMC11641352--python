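"""Independent reference implementations used to check the package.

Everything here is deliberately naive — set arithmetic, exhaustive
enumeration, from-scratch recomputation — and shares no code with the
implementations under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def tanimoto_sets(a: set[int], b: set[int]) -> float:
    """Tanimoto coefficient by direct set arithmetic on bit-index sets."""
    return len(a & b) / len(a | b)


def naive_agglomerate(points: np.ndarray, linkage: str):
    """O(n³) agglomeration recomputing every cluster-pair distance from the
    raw points at every step (no Lance–Williams recurrences).

    Returns a list of (left_index, right_index, height, size) in the same
    cluster-indexing convention as the package: leaves 0..n−1, the t-th
    merge creates cluster n+t.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)

    def cluster_distance(ci: list[int], cj: list[int]) -> float:
        pair = [
            math.dist(points[a], points[b]) for a in ci for b in cj
        ]
        if linkage == "single":
            return min(pair)
        if linkage == "complete":
            return max(pair)
        if linkage == "average":
            return sum(pair) / len(pair)
        if linkage == "ward":
            ni, nj = len(ci), len(cj)
            centroid_i = points[ci].mean(axis=0)
            centroid_j = points[cj].mean(axis=0)
            return math.sqrt(2.0 * ni * nj / (ni + nj)) * math.dist(centroid_i, centroid_j)
        raise ValueError(linkage)

    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    next_idx = n
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            d = cluster_distance(clusters[i], clusters[j])
            if best is None or d < best[0] or (d == best[0] and (i, j) < best[1:]):
                best = (d, i, j)
        d, i, j = best
        merged = clusters.pop(i) + clusters.pop(j)
        merges.append((i, j, d, len(merged)))
        clusters[next_idx] = merged
        next_idx += 1
    return merges


def adjusted_rand_index(labels_a: list, labels_b: list) -> float:
    """ARI from the contingency table, straight from its definition."""
    assert len(labels_a) == len(labels_b)
    n = len(labels_a)
    table: dict[tuple, int] = {}
    row: dict = {}
    col: dict = {}
    for a, b in zip(labels_a, labels_b):
        table[(a, b)] = table.get((a, b), 0) + 1
        row[a] = row.get(a, 0) + 1
        col[b] = col.get(b, 0) + 1

    def comb2(x):
        return x * (x - 1) // 2

    sum_cells = sum(comb2(v) for v in table.values())
    sum_rows = sum(comb2(v) for v in row.values())
    sum_cols = sum(comb2(v) for v in col.values())
    expected = sum_rows * sum_cols / comb2(n)
    max_index = (sum_rows + sum_cols) / 2
    if max_index == expected:
        return 1.0
    return (sum_cells - expected) / (max_index - expected)


def hypergeom_upper_tail_enumeration(big_n: int, big_k: int, n: int, k: int) -> float:
    """P(X ≥ k) by enumerating every n-subset of an N-element universe with
    K marked elements.  Only feasible for small N."""
    universe = range(big_n)
    marked = set(range(big_k))
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(marked & set(draw)) >= k:
            hits += 1
    return hits / total


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, written out by hand."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        value = pvals[i] * m / (rank_from_top + 1)
        running_min = min(running_min, value)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def degree_tally(edges: list[tuple[str, str]]) -> dict[str, int]:
    """Node degrees by counting edge endpoints directly."""
    tally: dict[str, int] = {}
    seen = set()
    for a, b in edges:
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        tally[a] = tally.get(a, 0) + 1
        tally[b] = tally.get(b, 0) + 1
    return tally


def exhaustive_medoid(sim: np.ndarray, ids: list[str]) -> tuple[str, float]:
    """Cluster medoid by exhaustively averaging each member's similarities
    to all the others (self excluded); lexicographic tie-break."""
    m = len(ids)
    if m == 1:
        return ids[0], 1.0
    best = None
    for i in range(m):
        mean = sum(sim[i][j] for j in range(m) if j != i) / (m - 1)
        if best is None or mean > best[1] + 1e-15 or (
            abs(mean - best[1]) <= 1e-15 and ids[i] < best[0]
        ):
            best = (ids[i], mean)
    return best
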