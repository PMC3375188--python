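"""Reference-based alignment accuracy scores.

SP and TC follow the BAliBASE convention (optionally restricted to
annotated core columns of the reference): SP is the fraction of reference
residue pairs reproduced by the test alignment, TC the fraction of
reference columns whose full set of non-gap residues is mutually aligned
in one test column.  FD and FM follow the SABmark convention: correct
pairs over reference pairs (FD, identical to SP over all columns) and
correct pairs over test pairs (FM).  The PREFAB Q score is simply SP
computed against a 2-sequence reference and needs no separate code path.

All scores are fractions in [0, 1]; multiply by 100 for the conventional
0-100 presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import ReferenceAnnotation
from .msa import GAP, MSA

Pair = tuple[str, int, str, int]


@dataclass
class EvalReport:
    sp: float
    tc: float
    fd: float
    fm: float
    correct_pairs: int
    reference_pairs: int
    test_pairs: int
    correct_columns: int
    reference_columns: int


def aligned_pairs(msa: MSA, columns: frozenset[int] | None = None) -> set[Pair]:
    """All residue pairs placed in one (core) column.

    Pairs are ``(seqA, posA, seqB, posB)`` with seqA < seqB and positions
    in ungapped sequence coordinates.
    """
    pairs: set[Pair] = set()
    pos = {rid: -1 for rid in msa.ids}
    rows = sorted(msa.rows)
    for j in range(msa.ncol):
        present: list[tuple[str, int]] = []
        for rid, row in rows:
            if row[j] != GAP:
                pos[rid] += 1
                if columns is None or j in columns:
                    present.append((rid, pos[rid]))
        if columns is not None and j not in columns:
            continue
        for i, (ra, pa) in enumerate(present):
            for rb, pb in present[i + 1 :]:
                pairs.add((ra, pa, rb, pb))
    return pairs


def _check_same_sequences(test: MSA, ref: MSA) -> None:
    if set(test.ids) != set(ref.ids):
        raise ValueError("test and reference alignments cover different sequences")
    for rid in test.ids:
        if test.degapped(rid) != ref.degapped(rid):
            raise ValueError(f"sequence {rid!r} differs between test and reference")


def sp_tc(
    test: MSA, ref: MSA, ann: ReferenceAnnotation | None = None
) -> tuple[float, float]:
    """Sum-of-pairs and true-column scores of ``test`` against ``ref``.

    Only the annotated core columns of the reference count; an empty
    annotation means all columns.  A reference with no core residue pairs
    is an error.
    """
    _check_same_sequences(test, ref)
    core = ann.core_columns if ann is not None and ann.core_columns else None
    if ann is not None:
        ann.validate_against(ref)
    ref_pairs = aligned_pairs(ref, core)
    if not ref_pairs:
        raise ValueError("reference alignment has no core residue pairs")
    test_pairs = aligned_pairs(test)
    sp = len(ref_pairs & test_pairs) / len(ref_pairs)

    # TC: a core reference column is correct when all its non-gap residues
    # appear together in one test column (rows gapped in the reference
    # column are ignored).
    test_col_of: dict[tuple[str, int], int] = {}
    pos = {rid: -1 for rid in test.ids}
    for j in range(test.ncol):
        for rid, row in test.rows:
            if row[j] != GAP:
                pos[rid] += 1
                test_col_of[(rid, pos[rid])] = j
    ncols = 0
    ncorrect = 0
    pos = {rid: -1 for rid in ref.ids}
    for j in range(ref.ncol):
        members: list[tuple[str, int]] = []
        for rid, row in ref.rows:
            if row[j] != GAP:
                pos[rid] += 1
                members.append((rid, pos[rid]))
        if core is not None and j not in core:
            continue
        if not members:
            continue
        ncols += 1
        cols = {test_col_of[m] for m in members}
        if len(cols) == 1:
            ncorrect += 1
    tc = ncorrect / ncols if ncols else 0.0
    return sp, tc


def fd_fm(test: MSA, ref: MSA) -> tuple[float, float]:
    """Developer and modeller scores: correct pairs over reference pairs
    (FD) and over test pairs (FM); 0 where a denominator is 0."""
    _check_same_sequences(test, ref)
    rp = aligned_pairs(ref)
    tp = aligned_pairs(test)
    correct = len(rp & tp)
    fd = correct / len(rp) if rp else 0.0
    fm = correct / len(tp) if tp else 0.0
    return fd, fm


def evaluate(
    test: MSA, ref: MSA, ann: ReferenceAnnotation | None = None
) -> EvalReport:
    """Full report: SP/TC over core columns plus FD/FM over all columns."""
    sp, tc = sp_tc(test, ref, ann)
    core = ann.core_columns if ann is not None and ann.core_columns else None
    rp = aligned_pairs(ref, core)
    tp = aligned_pairs(test)
    correct = len(rp & tp)
    fd, fm = fd_fm(test, ref)
    ncols = 0
    pos_cols = [
        j
        for j in range(ref.ncol)
        if any(row[j] != GAP for _, row in ref.rows)
        and (core is None or j in core)
    ]
    ncols = len(pos_cols)
    return EvalReport(
        sp=sp,
        tc=tc,
        fd=fd,
        fm=fm,
        correct_pairs=correct,
        reference_pairs=len(rp),
        test_pairs=len(tp),
        correct_columns=round(tc * ncols),
        reference_columns=ncols,
    )
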