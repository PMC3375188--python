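"""Pairwise information sources.

Three kinds of pairwise evidence feed the alignment graph:

* optimal global alignment under Gotoh's affine gap model,
* the top-k (default 4) Smith-Waterman local alignments, declumped
  Waterman-Eggert style so later alignments may overlap earlier ones,
* one longest common subsequence.

Every alignment is decomposed into its maximal ungapped blocks, emitted as
:class:`~graphmsa.io.SegmentMatch` objects.

Gap convention: a gap of length L costs ``gap_open + L * gap_extend``
(opening charged once per gap, extension per gapped residue), so the
default -13/-1 prices a length-1 gap at -14.  Terminal gaps are charged
full cost unless ``free_end_gaps`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .io import ALPHABET, ProteinSequence, SegmentMatch

NEG = -np.inf


def blosum62() -> dict[tuple[str, str], float]:
    """The BLOSUM62 substitution table restricted to the 20+X alphabet."""
    m = substitution_matrices.load("BLOSUM62")
    return {(a, b): float(m[a][b]) for a in ALPHABET for b in ALPHABET}


@dataclass(frozen=True)
class ScoringParams:
    """Substitution matrix and affine gap penalties.

    ``offset`` is added to every matrix entry when weighting graph edges so
    all edge weights are strictly positive; the default +5 lifts BLOSUM62's
    minimum entry (-4) to +1, the smallest strictly positive shift.
    """

    matrix: dict[tuple[str, str], float] = field(default_factory=blosum62)
    gap_open: float = -13.0
    gap_extend: float = -1.0
    offset: float = 5.0
    free_end_gaps: bool = False

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")
        if self.offset + min(self.matrix.values()) < 1:
            raise ValueError("offset must lift the smallest matrix entry to >= 1")

    def score(self, x: str, y: str) -> float:
        return self.matrix[(x, y)]

    def weight(self, x: str, y: str) -> float:
        """Edge-weight contribution of one aligned residue pair."""
        return self.matrix[(x, y)] + self.offset

    def as_array(self) -> np.ndarray:
        arr = np.empty((len(ALPHABET), len(ALPHABET)))
        for i, x in enumerate(ALPHABET):
            for j, y in enumerate(ALPHABET):
                arr[i, j] = self.matrix[(x, y)]
        return arr


@dataclass
class PairwiseResult:
    """Segment matches plus the score of the alignment(s) they came from.

    ``identity`` (global alignments only) is the fraction of aligned
    residue pairs that are identical; 0 when nothing is aligned.  For
    ``local_align_topk`` the per-alignment scores are in ``all_scores``
    (non-increasing) and ``score`` is the best of them.
    """

    matches: list[SegmentMatch]
    score: float
    identity: float = 0.0
    all_scores: list[float] = field(default_factory=list)


def _encode(s: str) -> np.ndarray:
    return np.fromiter((ALPHABET.index(c) for c in s), dtype=np.intp, count=len(s))


def _blocks_to_matches(
    a: ProteinSequence,
    b: ProteinSequence,
    pairs: list[tuple[int, int]],
    source: str,
    raw_score: float,
) -> list[SegmentMatch]:
    """Group aligned residue pairs into maximal ungapped blocks."""
    matches: list[SegmentMatch] = []
    start = 0
    for t in range(1, len(pairs) + 1):
        if (
            t == len(pairs)
            or pairs[t][0] != pairs[t - 1][0] + 1
            or pairs[t][1] != pairs[t - 1][1] + 1
        ):
            i0, j0 = pairs[start]
            matches.append(
                SegmentMatch(a.id, i0, b.id, j0, t - start, source, raw_score)
            )
            start = t
    return matches


def _gotoh_fill(
    sa: np.ndarray, sb: np.ndarray, S: np.ndarray, go: float, ge: float,
    free_ends: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill the three Gotoh state matrices.

    M: a[i-1] aligned to b[j-1]; Ix: gap in b (a[i-1] consumed);
    Iy: gap in a (b[j-1] consumed).  Gap-to-gap transitions are excluded
    (never optimal here: the worst substitution outprices two openings).
    """
    n, m = len(sa), len(sb)
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    rng_i = np.arange(1, n + 1)
    rng_j = np.arange(1, m + 1)
    Ix[1:, 0] = 0.0 if free_ends else go + rng_i * ge
    Iy[0, 1:] = 0.0 if free_ends else go + rng_j * ge
    sub = S[sa][:, sb]  # (n, m) substitution scores
    karr = np.arange(m)
    for i in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = sub[i - 1] + best_prev[:-1]
        if i == 1:
            M[1, 1] = sub[0, 0]  # only entry reachable through M[0,0]
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] + go + ge, Ix[i - 1, 1:] + ge)
        if free_ends:
            Ix[i, 0] = 0.0
        # Iy scan: Iy[i,j] = max_{k<j} M[i,k] + go + ge*(j-k)
        c = M[i, :-1] + go + ge - ge * karr
        Iy[i, 1:] = np.maximum.accumulate(c) + ge * karr
    return M, Ix, Iy


def _traceback_global(
    M: np.ndarray, Ix: np.ndarray, Iy: np.ndarray,
    sub: np.ndarray, go: float, ge: float, start: tuple[int, int, str],
    free_ends: bool,
) -> list[tuple[int, int]]:
    """Recover aligned residue pairs (0-based) walking the state matrices.

    Tie-break: prefer the diagonal (M) predecessor, then the vertical gap
    (Ix), then the horizontal gap (Iy) — deterministic across platforms.
    """
    i, j, state = start
    pairs: list[tuple[int, int]] = []
    while i > 0 or j > 0:
        if state == "M":
            pairs.append((i - 1, j - 1))
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for st, mat in (("M", M), ("Ix", Ix), ("Iy", Iy)):
                if mat[i, j] == target:
                    state = st
                    break
            else:  # pragma: no cover - defensive
                raise AssertionError("broken traceback in global alignment")
        elif state == "Ix":
            if j == 0 and (free_ends or Ix[i, 0] == go + i * ge):
                break
            if M[i - 1, j] + go + ge == Ix[i, j]:
                state = "M"
            i -= 1
        else:  # Iy
            if i == 0 and (free_ends or Iy[0, j] == go + j * ge):
                break
            if M[i, j - 1] + go + ge == Iy[i, j]:
                state = "M"
            j -= 1
    return pairs[::-1]


def global_align(
    a: ProteinSequence, b: ProteinSequence, params: ScoringParams | None = None
) -> PairwiseResult:
    """Optimal affine-gap global alignment of two sequences.

    Returns the maximal ungapped blocks of one optimal alignment (source
    ``global``), the optimal score, and the identity fraction over aligned
    pairs.  An empty sequence forces an all-gap alignment scoring
    ``gap_open + len * gap_extend`` over the other's length.
    """
    params = params or ScoringParams()
    go, ge = params.gap_open, params.gap_extend
    if len(a) == 0 and len(b) == 0:
        return PairwiseResult([], 0.0, 0.0)
    if len(a) == 0 or len(b) == 0:
        other = len(a) or len(b)
        score = 0.0 if params.free_end_gaps else go + other * ge
        return PairwiseResult([], score, 0.0)
    sa, sb = _encode(a.residues), _encode(b.residues)
    S = params.as_array()
    M, Ix, Iy = _gotoh_fill(sa, sb, S, go, ge, params.free_end_gaps)
    n, m = len(sa), len(sb)
    if params.free_end_gaps:
        # optimum may end anywhere on the last row/column, remainder gapped free
        best, start = NEG, (n, m, "M")
        cells = [(i, m) for i in range(n + 1)] + [(n, j) for j in range(m)]
        for i, j in cells:
            for st, mat in (("M", M), ("Ix", Ix), ("Iy", Iy)):
                if mat[i, j] > best:
                    best, start = mat[i, j], (i, j, st)
        score = best
    else:
        score, start = NEG, (n, m, "M")
        for st, mat in (("M", M), ("Ix", Ix), ("Iy", Iy)):
            if mat[n, m] > score:
                score, start = mat[n, m], (n, m, st)
    sub = S[sa][:, sb]
    pairs = _traceback_global(M, Ix, Iy, sub, go, ge, start, params.free_end_gaps)
    ident = (
        sum(1 for i, j in pairs if a.residues[i] == b.residues[j]) / len(pairs)
        if pairs
        else 0.0
    )
    matches = _blocks_to_matches(a, b, pairs, "global", score)
    return PairwiseResult(matches, float(score), ident)


def local_align_topk(
    a: ProteinSequence,
    b: ProteinSequence,
    params: ScoringParams | None = None,
    k: int = 4,
) -> PairwiseResult:
    """Top-k Smith-Waterman local alignments with affine gaps.

    Suboptimal alignments are obtained by declumping: the residue pairs of
    each reported alignment are forbidden from aligning again and the DP is
    recomputed, so later alignments may still overlap earlier ones on one
    sequence.  Only strictly positive scores are reported, in non-increasing
    order; no positive cell at all yields an empty result.
    """
    params = params or ScoringParams()
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(a) == 0 or len(b) == 0:
        return PairwiseResult([], 0.0)
    go, ge = params.gap_open, params.gap_extend
    sa, sb = _encode(a.residues), _encode(b.residues)
    S = params.as_array()
    sub = S[sa][:, sb]
    n, m = len(sa), len(sb)
    forbidden = np.zeros((n, m), dtype=bool)
    matches: list[SegmentMatch] = []
    scores: list[float] = []
    karr = np.arange(m)
    for _ in range(k):
        M = np.full((n + 1, m + 1), NEG)
        Ix = np.full((n + 1, m + 1), NEG)
        Iy = np.full((n + 1, m + 1), NEG)
        M[0, :] = M[:, 0] = NEG
        for i in range(1, n + 1):
            best_prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
            start_here = np.maximum(best_prev[:-1], 0.0)
            row = sub[i - 1] + start_here
            row[forbidden[i - 1]] = NEG
            M[i, 1:] = row
            Ix[i, 1:] = np.maximum(M[i - 1, 1:] + go + ge, Ix[i - 1, 1:] + ge)
            c = M[i, :-1] + go + ge - ge * karr
            Iy[i, 1:] = np.maximum.accumulate(c) + ge * karr
        flat = np.nan_to_num(M, neginf=-1e30)
        idx = int(np.argmax(flat))
        bi, bj = divmod(idx, m + 1)
        best = M[bi, bj]
        if not best > 0:
            break
        # traceback until the zero-start option was taken
        i, j, state = bi, bj, "M"
        pairs: list[tuple[int, int]] = []
        while True:
            if state == "M":
                pairs.append((i - 1, j - 1))
                target = M[i, j] - sub[i - 1, j - 1]
                i, j = i - 1, j - 1
                if target == 0:
                    break  # the fresh-start option was taken here
                for st, mat in (("M", M), ("Ix", Ix), ("Iy", Iy)):
                    if mat[i, j] == target:
                        state = st
                        break
                else:  # pragma: no cover - defensive
                    raise AssertionError("broken traceback in local alignment")
            elif state == "Ix":
                if M[i - 1, j] + go + ge == Ix[i, j]:
                    state = "M"
                i -= 1
            else:
                if M[i, j - 1] + go + ge == Iy[i, j]:
                    state = "M"
                j -= 1
        pairs.reverse()
        for pi, pj in pairs:
            forbidden[pi, pj] = True
        scores.append(float(best))
        matches.extend(_blocks_to_matches(a, b, pairs, "local", float(best)))
    return PairwiseResult(matches, scores[0] if scores else 0.0, all_scores=scores)


def lcs_align(a: ProteinSequence, b: ProteinSequence) -> PairwiseResult:
    """One longest common subsequence, as segment matches (source ``lcs``).

    Unit score per identical letter, no gap cost; ties resolved toward the
    earliest coordinates in ``a``.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return PairwiseResult([], 0.0)
    ra, rb = a.residues, b.residues
    # suffix table: L[i][j] = LCS length of a[i:], b[j:]
    L = np.zeros((n + 1, m + 1), dtype=np.int64)
    eq = (
        np.frombuffer(ra.encode(), dtype=np.uint8)[:, None]
        == np.frombuffer(rb.encode(), dtype=np.uint8)[None, :]
    )
    for i in range(n - 1, -1, -1):
        L[i, :-1] = np.where(
            eq[i], L[i + 1, 1:] + 1, 0
        )
        np.maximum(L[i], L[i + 1, : m + 1], out=L[i])
        np.maximum.accumulate(L[i, ::-1], out=L[i, ::-1])
    pairs: list[tuple[int, int]] = []
    i = j = 0
    while i < n and j < m and L[i, j] > 0:
        if ra[i] == rb[j] and L[i, j] == L[i + 1, j + 1] + 1:
            pairs.append((i, j))
            i, j = i + 1, j + 1
        elif L[i, j + 1] == L[i, j]:
            j += 1
        else:
            i += 1
    score = float(L[0, 0])
    return PairwiseResult(_blocks_to_matches(a, b, pairs, "lcs", score), score)
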