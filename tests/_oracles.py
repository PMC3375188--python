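"""Independent brute-force oracles used to check the fast implementations.

These deliberately use different formulations than the library code:
recursive enumeration for alignments, subsequence enumeration for LCS,
explicit cluster-set scans for single linkage, and simple-path enumeration
for maximin path weights.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

NEG = float("-inf")


def oracle_global_score(a: str, b: str, matrix, go: float, ge: float) -> float:
    """Max score over all global alignments; a gap run of length L costs
    go + L*ge.  Recursive enumeration over column types with memoisation."""

    @lru_cache(maxsize=None)
    def f(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = NEG
        if i < len(a) and j < len(b):
            best = max(best, matrix[(a[i], b[j])] + f(i + 1, j + 1, "m"))
        if i < len(a):  # a[i] over a gap in b
            cost = ge + (go if state != "ga" else 0.0)
            best = max(best, cost + f(i + 1, j, "ga"))
        if j < len(b):
            cost = ge + (go if state != "gb" else 0.0)
            best = max(best, cost + f(i, j + 1, "gb"))
        return best

    return f(0, 0, "m")


def oracle_local_best_score(a: str, b: str, matrix, go: float, ge: float) -> float:
    """Best local alignment score: max over all substring pairs of the
    global score of the substrings (0 if nothing positive exists)."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = oracle_global_score(a[i1:i2], b[j1:j2], matrix, go, ge)
                    if s > best:
                        best = s
    return best


def oracle_lcs_length(a: str, b: str) -> int:
    """Longest common subsequence by enumeration of subsequences of a."""
    best = 0
    for r in range(min(len(a), len(b)), 0, -1):
        for idx in combinations(range(len(a)), r):
            sub = "".join(a[i] for i in idx)
            it = iter(b)
            if all(c in it for c in sub):
                return r
    return best


def oracle_single_linkage_heights(labels, d) -> list[float]:
    """Naive O(n^3) single linkage; returns the sorted merge distances."""
    clusters = [{i} for i in range(len(labels))]
    heights = []
    while len(clusters) > 1:
        best = None
        for x, y in combinations(range(len(clusters)), 2):
            dm = min(d[i][j] for i in clusters[x] for j in clusters[y])
            if best is None or dm < best[0]:
                best = (dm, x, y)
        dm, x, y = best
        heights.append(dm)
        merged = clusters[x] | clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.append(merged)
    return sorted(heights)


def oracle_maximin_path(adj: dict, u, v) -> float:
    """Max over all simple u-v paths of the minimum edge weight on the path."""

    def walk(node, seen, wmin):
        if node == v:
            return wmin
        best = NEG
        for nxt, w in adj[node].items():
            if nxt not in seen:
                best = max(best, walk(nxt, seen | {nxt}, min(wmin, w)))
        return best

    return walk(u, {u}, float("inf"))
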