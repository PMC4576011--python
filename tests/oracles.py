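"""Independent oracles used by the test suite.

Each oracle is written from the mathematical definition, in a different
style from the implementation it checks (top-down recursion instead of the
iterative rolling-array kernel; dense textbook Markov clustering without
pruning or support-component extraction; spreadsheet-style recomputation of
structure statistics), so agreement is evidence and not tautology.
"""

from __future__ import annotations

import sys
from functools import lru_cache

import numpy as np

sys.setrecursionlimit(100000)


def sw_bruteforce(a: str, b: str, sub, gap_open: int, gap_extend: int) -> int:
    """Best local-alignment score by exhaustive recursion over alignment
    end states (memoized).

    An alignment may end at any (i, j) with a residue pair, or inside a gap
    in either sequence; a gap of length L costs gap_open + L * gap_extend.
    The empty alignment scores 0.
    """

    @lru_cache(maxsize=None)
    def match(i: int, j: int) -> int:
        # best alignment ending with a[i] aligned to b[j]
        prev = 0
        if i > 0 and j > 0:
            prev = max(prev, match(i - 1, j - 1), gap_a(i - 1, j - 1), gap_b(i - 1, j - 1))
        return prev + int(sub[a[i], b[j]])

    @lru_cache(maxsize=None)
    def gap_a(i: int, j: int) -> int:
        # best alignment ending with b[j] against a gap (a consumed up to i)
        opening = match(i, j - 1) + gap_open + gap_extend if j > 0 else -(10**9)
        extending = gap_a(i, j - 1) + gap_extend if j > 0 else -(10**9)
        return max(opening, extending)

    @lru_cache(maxsize=None)
    def gap_b(i: int, j: int) -> int:
        opening = match(i - 1, j) + gap_open + gap_extend if i > 0 else -(10**9)
        extending = gap_b(i - 1, j) + gap_extend if i > 0 else -(10**9)
        return max(opening, extending)

    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            best = max(best, match(i, j))
    return best


def mcl_reference(adjacency: np.ndarray, inflation: float,
                  iterations: int = 200, tol: float = 1e-10) -> list[set[int]]:
    """Dense textbook Markov clustering: self-loops of weight 1, column
    normalization, squaring + entry-wise inflation to convergence, clusters
    read off the attractor rows. No pruning, no epsilon tricks."""
    A = adjacency.astype(float).copy()
    np.fill_diagonal(A, 1.0)
    M = A / A.sum(axis=0)
    for _ in range(iterations):
        new = np.linalg.matrix_power(M, 2) ** inflation
        new = new / new.sum(axis=0)
        if np.abs(new - M).max() < tol:
            M = new
            break
        M = new
    attractors = [i for i in range(len(M)) if M[i, i] > 1e-8]
    clusters: list[set[int]] = []
    for i in attractors:
        members = {j for j in range(len(M)) if M[i, j] > 1e-8} | {i}
        merged = False
        for c in clusters:
            if c & members:
                c |= members
                merged = True
                break
        if not merged:
            clusters.append(members)
    # merge any remaining overlaps
    changed = True
    while changed:
        changed = False
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                if clusters[x] & clusters[y]:
                    clusters[x] |= clusters[y]
                    del clusters[y]
                    changed = True
                    break
            if changed:
                break
    return clusters


def complete_linkage_bruteforce(points: np.ndarray) -> list[float]:
    """Merge heights of complete-linkage agglomeration, by direct search:
    repeatedly merge the two clusters with the smallest maximum pairwise
    euclidean distance."""
    clusters = [[i] for i in range(len(points))]

    def cluster_dist(c1, c2):
        return max(
            float(np.linalg.norm(points[i] - points[j]))
            for i in c1 for j in c2
        )

    heights = []
    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = cluster_dist(clusters[x], clusters[y])
                if best is None or d < best[0]:
                    best = (d, x, y)
        d, x, y = best
        heights.append(d)
        clusters[x] = clusters[x] + clusters[y]
        del clusters[y]
    return heights
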