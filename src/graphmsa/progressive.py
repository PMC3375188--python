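"""Progressive alignment over the guide tree.

At each internal node two sub-alignments are merged by a heaviest-common-
subsequence dynamic program over their columns: the benefit of pairing
column i of the left profile with column j of the right profile is the
summed per-residue-pair weight of every graph edge whose two residues sit
in those columns (each edge's weight spread uniformly over its residue
pairs, w/length per pair).  Gaps cost nothing — all gap economics live in
the edge weights — and the DP maximises total benefit, a per-merge
approximation of the maximum weight trace.
"""

from __future__ import annotations

import numpy as np

from .graph import AlignmentGraph
from .msa import GAP, MSA
from .tree import GuideTree, TreeNode


def _column_benefits(
    g: AlignmentGraph, left: MSA, right: MSA
) -> np.ndarray:
    """Benefit matrix B[i, j] for pairing left column i with right column j."""
    left_ids = set(left.ids)
    right_ids = set(right.ids)
    lcols = left.position_to_column()
    rcols = right.position_to_column()
    B = np.zeros((left.ncol, right.ncol))
    for u in g.vertices:
        if u.seq not in left_ids:
            continue
        for v, w in g.neighbors(u).items():
            if v.seq not in right_ids:
                continue
            per_pair = w / u.length
            ucols, vcols = lcols[u.seq], rcols[v.seq]
            for t in range(u.length):
                B[ucols[u.begin + t], vcols[v.begin + t]] += per_pair
    return B


def align_profiles(g: AlignmentGraph, left: MSA, right: MSA) -> MSA:
    """Merge two sub-alignments by the heaviest-common-subsequence DP.

    Row order is left rows then right rows; unmatched columns are
    interleaved (with zero connecting benefit, all left columns come before
    all right columns).  Tie-break: pairing beats gapping, and a left-side
    column is emitted before a right-side one.
    """
    if set(left.ids) & set(right.ids):
        raise ValueError("profiles must cover disjoint sequence sets")
    B = _column_benefits(g, left, right)
    L, R = left.ncol, right.ncol
    H = np.zeros((L + 1, R + 1))
    for i in range(1, L + 1):
        Hp, Hc = H[i - 1], H[i]
        Bi = B[i - 1]
        for j in range(1, R + 1):
            Hc[j] = max(Hp[j - 1] + Bi[j - 1], Hp[j], Hc[j - 1])
    # Traceback.  Pairing is preferred over gapping, but only when it
    # carries weight: zero-benefit columns are never paired (a gap route of
    # equal score always exists by monotonicity), so unconnected profiles
    # come out concatenated, left columns first.
    steps: list[tuple[int, int]] = []  # (left col or -1, right col or -1)
    i, j = L, R
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and B[i - 1, j - 1] > 0
            and H[i, j] == H[i - 1, j - 1] + B[i - 1, j - 1]
        ):
            steps.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif j > 0 and H[i, j] == H[i, j - 1]:
            steps.append((-1, j - 1))
            j -= 1
        else:
            steps.append((i - 1, -1))
            i -= 1
    steps.reverse()
    lrows = [row for _, row in left.rows]
    rrows = [row for _, row in right.rows]
    out_left = [[] for _ in lrows]
    out_right = [[] for _ in rrows]
    for li, rj in steps:
        for k, row in enumerate(lrows):
            out_left[k].append(row[li] if li >= 0 else GAP)
        for k, row in enumerate(rrows):
            out_right[k].append(row[rj] if rj >= 0 else GAP)
    rows = [
        (rid, "".join(chars))
        for (rid, _), chars in zip(left.rows, out_left)
    ] + [
        (rid, "".join(chars))
        for (rid, _), chars in zip(right.rows, out_right)
    ]
    return MSA(rows).drop_allgap_columns()


def progressive_align(g: AlignmentGraph, tree: GuideTree) -> MSA:
    """Align all sequences in guide-tree post-order.

    Leaves become single-row alignments of the ungapped input sequences;
    each internal node merges its children with :func:`align_profiles`.
    """
    seq_ids = set(g.sequences)
    tree_ids = set(tree.leaves())
    if tree_ids != seq_ids:
        raise ValueError(
            f"tree leaves {sorted(tree_ids)} do not match graph sequences "
            f"{sorted(seq_ids)}"
        )

    def build(node: TreeNode) -> MSA:
        if node.is_leaf:
            return MSA([(node.label, g.sequences[node.label].residues)])
        sub = [build(c) for c in node.children]
        return align_profiles(g, sub[0], sub[1])

    msa = build(tree.root)
    msa.check_invariants({sid: s.residues for sid, s in g.sequences.items()})
    return msa
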