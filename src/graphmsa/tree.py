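"""Distance matrices and guide-tree construction.

Distances come either from global-alignment identity (d = 1 - identity)
or, when no global alignments are computed, from k-mer counting.  Guide
trees are rooted binary trees built by one of five clustering algorithms:
neighbor joining (rooted between the last two nodes joined) or the four
agglomerative schemes single linkage, complete linkage, UPGMA and weighted
UPGMA.  Ties between equally close cluster pairs are broken toward the
lexicographically smallest label pair, so trees are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator, Sequence

import numpy as np

from .io import ProteinSequence
from .pairwise import ScoringParams, global_align

TREE_METHODS = ("nj", "single", "complete", "upgma", "wupgma")


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal must be zero")

    def get(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.d[ia, ib])


@dataclass
class TreeNode:
    """Node of a rooted binary guide tree.

    Leaves carry ``label``; internal nodes have exactly two children.
    ``height`` is the merge height for agglomerative methods (leaves at 0),
    ``length`` the branch length to the parent where defined.
    """

    label: str | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None
    height: float | None = None
    length: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        return [x for c in self.children for x in c.leaves()]

    def postorder(self) -> Iterator["TreeNode"]:
        if self.children is not None:
            for c in self.children:
                yield from c.postorder()
        yield self


@dataclass
class GuideTree:
    root: TreeNode

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def edges_breadth_first(self) -> list[TreeNode]:
        """Tree edges identified by their child node, in breadth-first
        order from the root, left child before right."""
        out: list[TreeNode] = []
        frontier = [self.root]
        while frontier:
            nxt: list[TreeNode] = []
            for node in frontier:
                if node.children is not None:
                    out.extend(node.children)
                    nxt.extend(node.children)
            frontier = nxt
        return out

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                core = node.label or ""
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.length is not None:
                core += f":{max(0.0, node.length):g}"  # clamp for output only
            return core

        return fmt(self.root) + ";"


# ---------------------------------------------------------------------------
# Distances


def distances_from_global(
    sequences: Sequence[ProteinSequence],
    params: ScoringParams | None = None,
    identities: dict[frozenset[str], float] | None = None,
) -> DistanceMatrix:
    """d[i][j] = 1 - global-alignment identity.

    ``identities`` may carry precomputed identity fractions keyed by
    sequence-id pairs (the pipeline reuses its source alignments here).
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    params = params or ScoringParams()
    labels = [s.id for s in sequences]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            key = frozenset((labels[i], labels[j]))
            if identities is not None and key in identities:
                ident = identities[key]
            else:
                ident = global_align(sequences[i], sequences[j], params).identity
            d[i, j] = d[j, i] = 1.0 - ident
    return DistanceMatrix(labels, d)


def _kmer_counts(s: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(s) - k + 1):
        kmer = s[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def distances_kmer(
    sequences: Sequence[ProteinSequence], k: int = 3
) -> DistanceMatrix:
    """k-mer counting distance: 1 - shared/min(#kmers), where shared sums
    the minimum multiplicity of every k-mer; sequences shorter than k are at
    distance 1 from everything."""
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = [s.id for s in sequences]
    counts = [_kmer_counts(s.residues, k) for s in sequences]
    totals = [max(0, len(s) - k + 1) for s in sequences]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if totals[i] == 0 or totals[j] == 0:
                d[i, j] = d[j, i] = 1.0
                continue
            shared = sum(
                min(c, counts[j].get(kmer, 0)) for kmer, c in counts[i].items()
            )
            d[i, j] = d[j, i] = 1.0 - shared / min(totals[i], totals[j])
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Clustering


def _linkage_update(method: str) -> Callable[[float, float, int, int], float]:
    if method == "single":
        return lambda dik, djk, ni, nj: min(dik, djk)
    if method == "complete":
        return lambda dik, djk, ni, nj: max(dik, djk)
    if method == "upgma":
        return lambda dik, djk, ni, nj: (ni * dik + nj * djk) / (ni + nj)
    if method == "wupgma":
        return lambda dik, djk, ni, nj: (dik + djk) / 2.0
    raise ValueError(f"unknown linkage method {method!r}")


def _agglomerative(D: DistanceMatrix, method: str) -> GuideTree:
    update = _linkage_update(method)
    # cluster state: representative label (smallest leaf), node, size
    nodes: dict[str, TreeNode] = {
        lab: TreeNode(label=lab, height=0.0) for lab in D.labels
    }
    sizes: dict[str, int] = {lab: 1 for lab in D.labels}
    dist: dict[frozenset[str], float] = {}
    for i, a in enumerate(D.labels):
        for j in range(i + 1, len(D.labels)):
            dist[frozenset((a, D.labels[j]))] = float(D.d[i, j])
    while len(nodes) > 1:
        best: tuple[float, str, str] | None = None
        for key, dv in dist.items():
            a, b = sorted(key)
            cand = (dv, a, b)
            if best is None or cand < best:
                best = cand
        dv, a, b = best  # type: ignore[misc]
        na, nb = nodes.pop(a), nodes.pop(b)
        height = dv / 2.0
        for child in (na, nb):
            child.length = height - (child.height or 0.0)
        merged = TreeNode(children=(na, nb), height=height)
        rep = a  # a < b, so a is the smaller representative
        for other in list(nodes):
            dak = dist.pop(frozenset((a, other)))
            dbk = dist.pop(frozenset((b, other)))
            dist[frozenset((rep, other))] = update(
                dak, dbk, sizes[a], sizes[b]
            )
        del dist[frozenset((a, b))]
        sizes[rep] = sizes.pop(a) + sizes.pop(b)
        nodes[rep] = merged
    return GuideTree(next(iter(nodes.values())))


def _neighbor_joining(D: DistanceMatrix) -> GuideTree:
    nodes: dict[str, TreeNode] = {lab: TreeNode(label=lab) for lab in D.labels}
    dist: dict[frozenset[str], float] = {}
    labels = list(D.labels)
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            dist[frozenset((a, labels[j]))] = float(D.d[i, j])
    active = sorted(nodes)
    while len(active) > 2:
        r = len(active)
        rowsum = {
            a: sum(dist[frozenset((a, b))] for b in active if b != a)
            for a in active
        }
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (r - 2) * dist[frozenset((a, b))] - rowsum[a] - rowsum[b]
                cand = (q, a, b)
                if best is None or cand < best:
                    best = cand
        _, a, b = best  # type: ignore[misc]
        dab = dist[frozenset((a, b))]
        la = dab / 2.0 + (rowsum[a] - rowsum[b]) / (2.0 * (r - 2))
        lb = dab - la
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = la, lb
        rep = min(a, b)
        merged = TreeNode(children=(na, nb) if a < b else (nb, na))
        for other in active:
            if other in (a, b):
                continue
            dak = dist.pop(frozenset((a, other)))
            dbk = dist.pop(frozenset((b, other)))
            dist[frozenset((rep, other))] = (dak + dbk - dab) / 2.0
        del dist[frozenset((a, b))]
        nodes[rep] = merged
        active = sorted(nodes)
    a, b = active
    dab = dist[frozenset((a, b))] if len(D.labels) > 2 else D.get(a, b)
    na, nb = nodes[a], nodes[b]
    na.length = nb.length = dab / 2.0  # root between the last two joined
    return GuideTree(TreeNode(children=(na, nb)))


def build_tree(D: DistanceMatrix, method: str = "single") -> GuideTree:
    """Build a rooted binary guide tree from a distance matrix.

    ``method`` is one of ``nj``, ``single``, ``complete``, ``upgma``,
    ``wupgma``.
    """
    if len(D.labels) < 2:
        raise ValueError("need at least 2 labels to build a tree")
    if method == "nj":
        return _neighbor_joining(D)
    return _agglomerative(D, method)
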