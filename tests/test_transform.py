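import random

from _oracles import oracle_maximin_path
from graphmsa import (
    ProteinSequence,
    TransformConfig,
    apply_transform,
    clique_transform,
    maxflow_consistency,
    triplet_seqan,
    triplet_tcoffee,
)
from graphmsa.graph import AlignmentGraph, Vertex


def make_graph(n_seqs: int, edges: list[tuple[int, int, float]], length=2):
    """Graph with one length-2 vertex per sequence; edges by sequence index."""
    ss = [ProteinSequence(f"s{i + 1}", "AC") for i in range(n_seqs)]
    g = AlignmentGraph(ss)
    vs = [Vertex(s.id, 0, length) for s in ss]
    for i, j, w in edges:
        g.add_edge(vs[i], vs[j], w)
    return g, vs


class TestTripletTcoffee:
    def test_triangle_update(self):
        g, vs = make_graph(3, [(0, 1, 10), (1, 2, 8), (0, 2, 6)])
        out = triplet_tcoffee(g)
        assert out.weight(vs[0], vs[1]) == 16
        assert out.weight(vs[1], vs[2]) == 14
        assert out.weight(vs[0], vs[2]) == 14

    def test_triangle_free_graph_unchanged(self):
        g, vs = make_graph(4, [(0, 1, 5), (2, 3, 7)])
        out = triplet_tcoffee(g)
        assert list(out.edges()) == list(g.edges())

    def test_no_edge_creation_on_paths(self):
        g, vs = make_graph(3, [(0, 2, 6), (2, 1, 8)])
        out = triplet_tcoffee(g)
        assert out.n_edges == 2
        assert out.weight(vs[0], vs[1]) is None

    def test_never_decreases_weights(self, rng):
        for _ in range(30):
            g = random_toy_graph(rng)
            out = triplet_tcoffee(g)
            for u, v, w in g.edges():
                assert out.weight(u, v) >= w


class TestTripletSeqan:
    def test_creates_common_neighbor_edge_with_min_weight(self):
        g, vs = make_graph(3, [(0, 2, 6), (2, 1, 8)])
        out = triplet_seqan(g, 1)
        assert out.weight(vs[0], vs[1]) == 6

    def test_never_creates_same_sequence_edges(self):
        ss = [ProteinSequence("s1", "ACDE"), ProteinSequence("s2", "AC")]
        g = AlignmentGraph(ss)
        u1, u2 = Vertex("s1", 0, 2), Vertex("s1", 2, 2)
        w = Vertex("s2", 0, 2)
        g.add_edge(u1, w, 5)
        g.add_edge(u2, w, 7)
        out = triplet_seqan(g, 1)
        assert out.weight(u1, u2) is None
        assert out.n_edges == 2

    def test_second_iteration_reaches_distance_three(self):
        g, vs = make_graph(4, [(0, 1, 3), (1, 2, 4), (2, 3, 5)])
        one = triplet_seqan(g, 1)
        assert one.weight(vs[0], vs[3]) is None
        two = triplet_seqan(g, 2)
        assert two.weight(vs[0], vs[3]) is not None

    def test_only_adds_edges_and_never_decreases(self, rng):
        for _ in range(20):
            g = random_toy_graph(rng)
            out = triplet_seqan(g, 1)
            assert out.n_edges >= g.n_edges
            for u, v, w in g.edges():
                assert out.weight(u, v) >= w


class TestMaxflow:
    def test_identical_neighborhoods_score_100(self):
        # u and v both connect to w1 and w2 (and to each other)
        g, vs = make_graph(
            4, [(0, 1, 9), (0, 2, 1), (0, 3, 1), (1, 2, 1), (1, 3, 1)]
        )
        out = maxflow_consistency(g)
        assert out.weight(vs[0], vs[1]) == 100

    def test_disjoint_neighborhoods_score_0(self):
        g, vs = make_graph(4, [(0, 1, 9), (0, 2, 1), (1, 3, 1)])
        out = maxflow_consistency(g)
        assert out.weight(vs[0], vs[1]) == 0

    def test_isolated_edge_scores_0(self):
        g, vs = make_graph(2, [(0, 1, 42)])
        assert maxflow_consistency(g).weight(vs[0], vs[1]) == 0

    def test_five_vertex_ratios_match_set_arithmetic(self):
        g, vs = make_graph(
            5, [(0, 1, 2), (0, 2, 2), (1, 2, 2), (1, 3, 2), (2, 3, 2), (3, 4, 2)]
        )
        out = maxflow_consistency(g)
        # edge (1,2): shared {0,3}, union {0,3} -> 100
        assert out.weight(vs[1], vs[2]) == 100
        # edge (0,1): shared {2}, union {2,3} -> 50
        assert out.weight(vs[0], vs[1]) == 50
        # edge (3,4): shared {}, union {1,2} -> 0
        assert out.weight(vs[3], vs[4]) == 0
        assert out.n_edges == g.n_edges


class TestClique:
    def test_weakest_link_on_path(self):
        g, vs = make_graph(3, [(0, 1, 5), (1, 2, 3)])
        out = clique_transform(g)
        assert out.weight(vs[0], vs[2]) == 3
        assert out.weight(vs[0], vs[1]) == 5

    def test_same_sequence_pairs_skipped(self):
        ss = [ProteinSequence("s1", "ACDE"), ProteinSequence("s2", "AC")]
        g = AlignmentGraph(ss)
        u1, u2 = Vertex("s1", 0, 2), Vertex("s1", 2, 2)
        w = Vertex("s2", 0, 2)
        g.add_edge(u1, w, 5)
        g.add_edge(u2, w, 7)
        out = clique_transform(g)
        assert out.weight(u1, u2) is None

    def test_weights_equal_maximin_oracle_on_random_graphs(self, rng):
        for _ in range(40):
            g = random_toy_graph(rng, max_seqs=6, p=0.5)
            out = clique_transform(g)
            adj = {v: dict(g.neighbors(v)) for v in g.vertices}
            for u, v, w in out.edges():
                assert w == oracle_maximin_path(adj, u, v)


def random_toy_graph(rng: random.Random, max_seqs=6, p=0.4) -> AlignmentGraph:
    n = rng.randrange(3, max_seqs + 1)
    g, vs = make_graph(n, [])
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(vs[i], vs[j], rng.randrange(1, 20))
    return g


def test_apply_transform_composes_in_order(rng):
    g = random_toy_graph(rng)
    cfg = TransformConfig(("triplet_tcoffee", "clique"))
    combined = apply_transform(g, cfg)
    stepwise = clique_transform(triplet_tcoffee(g))
    assert list(combined.edges()) == list(stepwise.edges())


def test_transforms_are_deterministic(rng):
    g = random_toy_graph(rng)
    for fn in (triplet_tcoffee, lambda x: triplet_seqan(x, 2),
               maxflow_consistency, clique_transform):
        assert list(fn(g).edges()) == list(fn(g).edges())
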