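"""The alignment graph: refined sequence segments joined by weighted edges.

Vertices are ungapped sequence segments, edges are possible alignments
between equal-length segments of two different sequences.  Before the graph
is built, the raw segment matches are *refined*: cut at projected
breakpoints, iterated to a fixed point, so that no two matches partly
overlap — afterwards any two segments on one sequence either coincide or
are disjoint.  Refinement conserves the multiset of aligned residue pairs.

Edge weights are per-residue-pair substitution scores shifted to be
strictly positive (BLOSUM62 + offset by default); evidence from several
sources landing on the same vertex pair is merged by summing weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

from .io import ProteinSequence, SegmentMatch
from .pairwise import ScoringParams


@dataclass(frozen=True, order=True)
class Vertex:
    """An ungapped segment ``seq[begin : begin + length]`` of one sequence."""

    seq: str
    begin: int
    length: int

    @property
    def end(self) -> int:
        return self.begin + self.length

    def __str__(self) -> str:
        return f"{self.seq}:{self.begin}:{self.length}"


class AlignmentGraph:
    """Weighted undirected graph over segment vertices.

    Invariants: no edge joins two vertices of the same sequence, every edge
    joins vertices of equal length, all weights are non-negative.
    """

    def __init__(self, sequences: Sequence[ProteinSequence]):
        self.sequences: dict[str, ProteinSequence] = {s.id: s for s in sequences}
        if len(self.sequences) != len(sequences):
            raise ValueError("duplicate sequence ids")
        self._adj: dict[Vertex, dict[Vertex, float]] = {}

    # -- construction -------------------------------------------------------

    def add_vertex(self, v: Vertex) -> None:
        if v.seq not in self.sequences:
            raise ValueError(f"vertex on unknown sequence {v.seq!r}")
        if v.end > len(self.sequences[v.seq]):
            raise ValueError(f"vertex {v} out of range")
        self._adj.setdefault(v, {})

    def add_edge(self, u: Vertex, v: Vertex, weight: float) -> None:
        if u.seq == v.seq:
            raise ValueError(f"edge within one sequence: {u} -- {v}")
        if u.length != v.length:
            raise ValueError(f"edge joins unequal-length vertices: {u} -- {v}")
        if weight < 0:
            raise ValueError("edge weights must be non-negative")
        self.add_vertex(u)
        self.add_vertex(v)
        self._adj[u][v] = self._adj[v][u] = weight

    def increment_edge(self, u: Vertex, v: Vertex, delta: float) -> None:
        self.add_edge(u, v, self._adj.get(u, {}).get(v, 0.0) + delta)

    # -- queries ------------------------------------------------------------

    @property
    def vertices(self) -> list[Vertex]:
        return sorted(self._adj)

    def neighbors(self, v: Vertex) -> dict[Vertex, float]:
        return self._adj.get(v, {})

    def weight(self, u: Vertex, v: Vertex) -> float | None:
        return self._adj.get(u, {}).get(v)

    def edges(self) -> Iterator[tuple[Vertex, Vertex, float]]:
        """Each undirected edge once, with u < v."""
        for u in sorted(self._adj):
            for v, w in sorted(self._adj[u].items()):
                if u < v:
                    yield u, v, w

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self._adj.values()) // 2

    def total_weight(self) -> float:
        return sum(w for _, _, w in self.edges())

    def copy_topology(self) -> "AlignmentGraph":
        g = AlignmentGraph(list(self.sequences.values()))
        for v in self._adj:
            g.add_vertex(v)
        return g

    def check_invariants(self) -> None:
        segs: dict[str, list[Vertex]] = {}
        for v in self._adj:
            segs.setdefault(v.seq, []).append(v)
        for seq, vs in segs.items():
            vs.sort()
            for a, b in zip(vs, vs[1:]):
                if a.begin == b.begin and a.length == b.length:
                    continue
                if b.begin < a.end:
                    raise AssertionError(
                        f"overlapping vertices on {seq!r}: {a} / {b}"
                    )
        for u, v, w in self.edges():
            assert u.seq != v.seq and u.length == v.length and w >= 0

    # -- plain-text dump/load (debugging, tests) ----------------------------

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for u, v, w in self.edges():
                fh.write(f"{u}\t{v}\t{w:g}\n")

    @classmethod
    def load(
        cls, path: str | Path, sequences: Sequence[ProteinSequence]
    ) -> "AlignmentGraph":
        g = cls(sequences)
        with open(path) as fh:
            for line in fh:
                us, vs, ws = line.split()
                u = Vertex(*_parse_vertex(us))
                v = Vertex(*_parse_vertex(vs))
                g.add_edge(u, v, float(ws))
        return g


def _parse_vertex(token: str) -> tuple[str, int, int]:
    seq, begin, length = token.rsplit(":", 2)
    return seq, int(begin), int(length)


# ---------------------------------------------------------------------------
# Segment refinement


def _refined_submatches(
    sequences: Sequence[ProteinSequence], matches: Sequence[SegmentMatch]
) -> list[SegmentMatch]:
    """Cut every match at projected breakpoints, iterated to a fixed point.

    Returns one sub-match per refined piece of every input match (the
    multiset view: duplicates are kept so weight accumulation conserves the
    input's residue-pair coverage).
    """
    lengths = {s.id: len(s) for s in sequences}
    for m in matches:
        m.validate_against(lengths)
    cuts: dict[str, set[int]] = {s.id: set() for s in sequences}
    for m in matches:
        cuts[m.seq_a].update((m.begin_a, m.begin_a + m.length))
        cuts[m.seq_b].update((m.begin_b, m.begin_b + m.length))
    # propagate cut points through matches until nothing changes
    changed = True
    while changed:
        changed = False
        for m in matches:
            for (sa, ba), (sb, bb) in (
                ((m.seq_a, m.begin_a), (m.seq_b, m.begin_b)),
                ((m.seq_b, m.begin_b), (m.seq_a, m.begin_a)),
            ):
                for p in list(cuts[sa]):
                    off = p - ba
                    if 0 < off < m.length:
                        q = bb + off
                        if q not in cuts[sb]:
                            cuts[sb].add(q)
                            changed = True
    refined: list[SegmentMatch] = []
    for m in matches:
        interior = sorted(
            off
            for off in (
                {p - m.begin_a for p in cuts[m.seq_a]}
                | {p - m.begin_b for p in cuts[m.seq_b]}
            )
            if 0 < off < m.length
        )
        bounds = [0, *interior, m.length]
        for lo, hi in zip(bounds, bounds[1:]):
            refined.append(
                SegmentMatch(
                    m.seq_a, m.begin_a + lo, m.seq_b, m.begin_b + lo,
                    hi - lo, m.source, m.raw_score,
                )
            )
    return refined


def _canonical_pair(m: SegmentMatch) -> tuple[Vertex, Vertex]:
    u = Vertex(m.seq_a, m.begin_a, m.length)
    v = Vertex(m.seq_b, m.begin_b, m.length)
    return (u, v) if u < v else (v, u)


def refine_matches(
    sequences: Sequence[ProteinSequence], matches: Sequence[SegmentMatch]
) -> tuple[list[Vertex], list[tuple[Vertex, Vertex]]]:
    """Refine matches and return the vertex set plus the edge skeleton.

    Duplicate refined sub-matches collapse to a single edge; vertices on one
    sequence are pairwise disjoint (or identical) after refinement.
    """
    pairs = {_canonical_pair(m) for m in _refined_submatches(sequences, matches)}
    vertices = sorted({v for pair in pairs for v in pair})
    return vertices, sorted(pairs)


def build_graph(
    sequences: Sequence[ProteinSequence],
    matches: Sequence[SegmentMatch],
    params: ScoringParams | None = None,
) -> AlignmentGraph:
    """Build the weighted alignment graph over refined segments.

    The weight of an edge is the sum over its aligned residue pairs of
    (substitution score + offset); sub-matches from different sources over
    the same vertex pair merge by summing.
    """
    params = params or ScoringParams()
    g = AlignmentGraph(sequences)
    res = {s.id: s.residues for s in sequences}
    for m in _refined_submatches(sequences, matches):
        w = sum(
            params.weight(res[m.seq_a][i], res[m.seq_b][j]) for i, j in m.pairs()
        )
        u, v = _canonical_pair(m)
        g.increment_edge(u, v, w)
    return g
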