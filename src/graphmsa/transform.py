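"""Score transformations of the alignment graph.

Four transformations are provided, all deterministic and all operating on
a frozen snapshot of the input weights:

* ``triplet_tcoffee`` — the T-Coffee triplet library extension: every
  existing edge (u,v) gains, for each common neighbour w, the minimum of
  the (u,w) and (v,w) weights.  The edge set is unchanged.
* ``triplet_seqan`` — the same update, but additionally *creating* an edge
  (u,v) wherever two vertices on different sequences share a common
  neighbour without being connected.  Iterating the step extends
  consistency to neighbourhoods of four, five, ... vertices.
* ``maxflow`` — each existing edge is reweighted to the consistency ratio
  of its endpoints: common neighbours over total neighbours (Jaccard of the
  neighbour sets with the endpoints themselves excluded), scaled by 100 and
  rounded; the topology is untouched.
* ``clique`` — connected components are clustered by Kruskal's algorithm
  run over edges in decreasing weight order; within each resulting spanning
  tree every different-sequence vertex pair is connected with a weight
  equal to the weakest link on the tree path between them (the maximin path
  weight over the whole component, by the classic maximum-spanning-tree
  property).

Edges are never introduced between vertices of the same sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import AlignmentGraph, Vertex

KINDS = ("none", "triplet_tcoffee", "triplet_seqan", "maxflow", "clique")


@dataclass(frozen=True)
class TransformConfig:
    """An ordered composition of score transformations.

    ``combine`` lists transformation kinds applied left to right, e.g.
    ``("triplet_tcoffee", "clique")``; ``iterations`` repeats the
    triplet_seqan step (other kinds ignore it).
    """

    combine: tuple[str, ...] = ("none",)
    iterations: int = 1

    def __post_init__(self) -> None:
        if not self.combine:
            raise ValueError("combine must be non-empty")
        for kind in self.combine:
            if kind not in KINDS:
                raise ValueError(f"unknown transform kind {kind!r}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def apply_transform(g: AlignmentGraph, cfg: TransformConfig) -> AlignmentGraph:
    for kind in cfg.combine:
        if kind == "none":
            continue
        elif kind == "triplet_tcoffee":
            g = triplet_tcoffee(g)
        elif kind == "triplet_seqan":
            g = triplet_seqan(g, cfg.iterations)
        elif kind == "maxflow":
            g = maxflow_consistency(g)
        elif kind == "clique":
            g = clique_transform(g)
    return g


def _snapshot(g: AlignmentGraph) -> dict[Vertex, dict[Vertex, float]]:
    return {v: dict(g.neighbors(v)) for v in g.vertices}


def _triplet_deltas(
    old: dict[Vertex, dict[Vertex, float]], create: bool
) -> dict[tuple[Vertex, Vertex], float]:
    """Sum of min(w(u,x), w(v,x)) over every common neighbour x, for each
    (existing, and optionally creatable) different-sequence pair (u,v)."""
    deltas: dict[tuple[Vertex, Vertex], float] = {}
    for x, nb in old.items():
        ns = sorted(nb)
        for i, u in enumerate(ns):
            wu = nb[u]
            for v in ns[i + 1 :]:
                if u.seq == v.seq:
                    continue
                if not create and v not in old[u]:
                    continue
                key = (u, v)
                deltas[key] = deltas.get(key, 0.0) + min(wu, nb[v])
    return deltas


def triplet_tcoffee(g: AlignmentGraph) -> AlignmentGraph:
    """Triplet library extension restricted to existing edges.

    All minima are taken on a snapshot of the input weights, so the result
    does not depend on edge iteration order.
    """
    old = _snapshot(g)
    out = g.copy_topology()
    deltas = _triplet_deltas(old, create=False)
    for u in old:
        for v, w in old[u].items():
            if u < v:
                out.add_edge(u, v, w + deltas.get((u, v), 0.0))
    return out


def triplet_seqan(g: AlignmentGraph, iterations: int = 1) -> AlignmentGraph:
    """Triplet extension that also creates implied edges.

    One iteration applies the T-Coffee update to existing edges and creates
    edge (u,v) with weight sum-of-mins whenever u and v lie on different
    sequences, share at least one common neighbour, and were unconnected.
    Further iterations repeat the whole step on the previous output.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    for _ in range(iterations):
        old = _snapshot(g)
        out = g.copy_topology()
        deltas = _triplet_deltas(old, create=True)
        for u in old:
            for v, w in old[u].items():
                if u < v:
                    out.add_edge(u, v, w + deltas.pop((u, v), 0.0))
        for (u, v), w in deltas.items():
            if u.length == v.length:
                out.add_edge(u, v, w)
            else:
                # cannot arise on a refined graph (edges join equal lengths,
                # so common neighbourhood forces equal lengths); guard anyway
                continue
        g = out
    return g


def maxflow_consistency(g: AlignmentGraph) -> AlignmentGraph:
    """Reweight every edge by its endpoint neighbourhood overlap.

    ratio(u,v) = |N(u) ∩ N(v)| / |N(u) ∪ N(v)| with v removed from N(u)
    and u from N(v); the weight becomes round(100 * ratio).  An isolated
    edge gets weight 0; no edges are created or deleted.
    """
    old = _snapshot(g)
    out = g.copy_topology()
    for u in old:
        for v in old[u]:
            if not u < v:
                continue
            nu = set(old[u]) - {v}
            nv = set(old[v]) - {u}
            union = nu | nv
            ratio = len(nu & nv) / len(union) if union else 0.0
            out.add_edge(u, v, round(100 * ratio))
    return out


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[Vertex, Vertex] = {}

    def find(self, v: Vertex) -> Vertex:
        root = v
        while self.parent.setdefault(root, root) != root:
            root = self.parent[root]
        while self.parent[v] != root:
            self.parent[v], v = root, self.parent[v]
        return root

    def union(self, u: Vertex, v: Vertex) -> bool:
        ru, rv = self.find(u), self.find(v)
        if ru == rv:
            return False
        self.parent[rv] = ru
        return True


def clique_transform(g: AlignmentGraph) -> AlignmentGraph:
    """Convert each connected component into a (near-)clique.

    Kruskal's algorithm over edges in decreasing weight (ties in
    lexicographic vertex order) yields a maximum-weight spanning forest;
    each vertex pair within a tree is connected — existing edges reweighted,
    same-sequence pairs skipped — with the minimum edge weight on the tree
    path between the pair.
    """
    edges = sorted(g.edges(), key=lambda e: (-e[2], e[0], e[1]))
    uf = _UnionFind()
    tree: dict[Vertex, dict[Vertex, float]] = {v: {} for v in g.vertices}
    for u, v, w in edges:
        if uf.union(u, v):
            tree[u][v] = tree[v][u] = w
    out = g.copy_topology()
    for root in g.vertices:
        # DFS from each vertex tracking the weakest link on the tree path
        stack = [(root, float("inf"))]
        seen = {root}
        while stack:
            node, wmin = stack.pop()
            for nxt, w in sorted(tree[node].items()):
                if nxt in seen:
                    continue
                seen.add(nxt)
                link = min(wmin, w)
                if root < nxt and root.seq != nxt.seq:
                    out.add_edge(root, nxt, link)
                stack.append((nxt, link))
    return out


__all__ = [
    "TransformConfig",
    "apply_transform",
    "triplet_tcoffee",
    "triplet_seqan",
    "maxflow_consistency",
    "clique_transform",
]
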