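"""Synthetic protein families with known true alignments.

A random rooted binary tree is drawn over the requested number of leaves;
an ancestral sequence evolves along every branch by substitutions and
geometric-length insertions/deletions, and the true column-level alignment
is maintained through every event.  Degapping any row of the true
alignment reproduces the corresponding emitted sequence exactly, and a
fixed seed gives bit-identical output.

Substitutions replace a residue ``x`` by ``y != x`` with probability
proportional to ``exp(BLOSUM62[x, y])`` — a simple matrix-consistent
substitution model.  Two presets emulate the identity regimes of common
structural benchmarks: ``twilight`` (mean pairwise identity around
20-25%) and ``superfamily`` (around 35-50%).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import AMINO_ACIDS, ProteinSequence
from .msa import MSA
from .pairwise import blosum62
from .tree import GuideTree, TreeNode


@dataclass(frozen=True)
class SimConfig:
    """Family-evolution parameters.

    Rates are per site per branch: ``sub_rate`` is the probability a site
    substitutes on one branch, ``indel_rate`` the expected number of indel
    events per site per branch; ``indel_length_mean`` is the mean of the
    geometric indel-length distribution.
    """

    n_seqs: int = 8
    ancestor_length: int = 100
    sub_rate: float = 0.1
    indel_rate: float = 0.01
    indel_length_mean: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seqs < 2:
            raise ValueError("need at least 2 sequences")
        if self.ancestor_length < 1:
            raise ValueError("ancestor_length must be >= 1")
        if not (0 <= self.sub_rate <= 1 and 0 <= self.indel_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.indel_length_mean < 1:
            raise ValueError("indel_length_mean must be >= 1")


#: Identity regimes named after the benchmark sets they emulate.
PRESETS: dict[str, SimConfig] = {
    "superfamily": SimConfig(sub_rate=0.20, indel_rate=0.015),
    "twilight": SimConfig(sub_rate=0.42, indel_rate=0.03),
}


def preset(name: str, **overrides) -> SimConfig:
    return replace(PRESETS[name], **overrides)


def _substitution_sampler():
    """Per-residue replacement distributions, P(y | x) ∝ exp(B62[x, y])."""
    table = blosum62()
    probs: dict[str, tuple[list[str], np.ndarray]] = {}
    for x in AMINO_ACIDS:
        others = [y for y in AMINO_ACIDS if y != x]
        w = np.exp([table[(x, y)] for y in others])
        probs[x] = (others, w / w.sum())
    return probs


def _random_topology(n: int, rng: np.random.Generator) -> TreeNode:
    nodes: list[TreeNode] = [TreeNode(label=f"s{i + 1}") for i in range(n)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(TreeNode(children=(a, b)))
    return nodes[0]


def evolve_family(cfg: SimConfig) -> tuple[list[ProteinSequence], MSA, GuideTree]:
    """Simulate one family; returns (sequences, true MSA, true tree).

    Sequences are labelled s1..sN in leaf order of the returned tree.
    """
    rng = np.random.default_rng(cfg.seed)
    sub = _substitution_sampler()
    root_node = _random_topology(cfg.n_seqs, rng)

    # Site bookkeeping: every residue ever created gets a unique site id;
    # ``order`` holds all site ids in true-alignment column order.
    next_site = [0]
    order: list[int] = []

    def new_sites(k: int, insert_after: int | None) -> list[int]:
        """Mint k site ids and splice them into the global column order
        immediately after site ``insert_after`` (None = at the front)."""
        ids = list(range(next_site[0], next_site[0] + k))
        next_site[0] += k
        at = 0 if insert_after is None else order.index(insert_after) + 1
        order[at:at] = ids
        return ids

    def draw_residue() -> str:
        return AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]

    root_ids = list(range(cfg.ancestor_length))
    next_site[0] = cfg.ancestor_length
    order.extend(root_ids)
    root_seq = [(sid, draw_residue()) for sid in root_ids]

    leaf_seqs: dict[str, list[tuple[int, str]]] = {}

    def mutate(seq: list[tuple[int, str]]) -> list[tuple[int, str]]:
        out = list(seq)
        # substitutions
        hits = np.nonzero(rng.random(len(out)) < cfg.sub_rate)[0]
        for i in hits:
            sid, aa = out[i]
            others, p = sub[aa]
            out[i] = (sid, others[int(rng.choice(len(others), p=p))])
        # indel events: expected indel_rate per site
        n_events = int(rng.binomial(max(len(out), 1), cfg.indel_rate))
        for _ in range(n_events):
            length = int(rng.geometric(1.0 / cfg.indel_length_mean))
            if rng.random() < 0.5 and len(out) > length:  # deletion
                p = int(rng.integers(0, len(out) - length + 1))
                del out[p : p + length]
            else:  # insertion
                p = int(rng.integers(0, len(out) + 1))
                after = out[p - 1][0] if p > 0 else None
                ids = new_sites(length, after)
                out[p:p] = [(sid, draw_residue()) for sid in ids]
        return out

    def walk(node: TreeNode, seq: list[tuple[int, str]]) -> None:
        if node.is_leaf:
            leaf_seqs[node.label] = seq
            return
        for child in node.children:
            walk(child, mutate(seq))

    walk(root_node, root_seq)

    tree = GuideTree(root_node)
    leaf_order = tree.leaves()
    occupied = {sid for s in leaf_seqs.values() for sid, _ in s}
    columns = [sid for sid in order if sid in occupied]
    col_index = {sid: i for i, sid in enumerate(columns)}
    rows = []
    for label in leaf_order:
        row = ["-"] * len(columns)
        for sid, aa in leaf_seqs[label]:
            row[col_index[sid]] = aa
        rows.append((label, "".join(row)))
    truth = MSA(rows)
    sequences = [
        ProteinSequence(label, truth.degapped(label)) for label in leaf_order
    ]
    truth.check_invariants({s.id: s.residues for s in sequences})
    return sequences, truth, tree


def mean_pairwise_identity(truth: MSA) -> float:
    """Mean over sequence pairs of identical-column fraction (relative to
    columns where both sequences have residues)."""
    rows = truth.rows
    idents = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = rows[i][1], rows[j][1]
            both = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if both:
                idents.append(sum(1 for x, y in both if x == y) / len(both))
    return float(np.mean(idents)) if idents else 0.0
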