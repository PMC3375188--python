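"""Sequence, alignment and match-library I/O.

External representations handled here: FASTA (unaligned input), aligned
FASTA (MSA in/out), T-Coffee-style libraries of residue-pair matches,
Newick guide trees and plain-text core-column annotations.  Everything
internal is 0-based and half-open; the library format on disk keeps the
conventional 1-based inclusive coordinates and the readers/writers
convert.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .msa import MSA

#: Canonical residue alphabet: the 20 amino acids plus the ambiguity code X.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
ALPHABET = AMINO_ACIDS + "X"

#: Ambiguity codes that are collapsed onto X so substitution-matrix lookup
#: can never fail (B/Z are ambiguous, U/O are non-standard residues).
_REMAP_TO_X = set("BZUOJ")


@dataclass(frozen=True)
class ProteinSequence:
    """An identified, validated amino-acid string.

    ``residues`` is uppercase over the 20 standard letters plus X, with no
    gap characters and no whitespace.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        for pos, ch in enumerate(self.residues):
            if ch not in ALPHABET:
                raise ValueError(
                    f"sequence {self.id!r}: illegal residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


def clean_residues(raw: str, seq_id: str = "?") -> str:
    """Normalise a raw residue string: uppercase, strip terminal '*',
    map non-canonical ambiguity codes (B, Z, U, O, J) to X."""
    s = raw.strip().upper().strip("*")
    if any(c in _REMAP_TO_X for c in s):
        warnings.warn(
            f"sequence {seq_id!r}: non-canonical residue letters mapped to X",
            stacklevel=3,
        )
        s = "".join("X" if c in _REMAP_TO_X else c for c in s)
    return s


@dataclass(frozen=True)
class SegmentMatch:
    """An ungapped correspondence between equal-length segments of two
    different sequences.

    Coordinates are 0-based starts of half-open intervals:
    ``seq_a[begin_a : begin_a + length]`` pairs residue-by-residue with
    ``seq_b[begin_b : begin_b + length]``.
    """

    seq_a: str
    begin_a: int
    seq_b: str
    begin_b: int
    length: int
    source: str = "external"  # one of {global, local, lcs, external}
    raw_score: float | None = None

    def __post_init__(self) -> None:
        if self.seq_a == self.seq_b:
            raise ValueError(f"match pairs sequence {self.seq_a!r} with itself")
        if self.length < 1:
            raise ValueError(f"match length must be >= 1, got {self.length}")
        if self.begin_a < 0 or self.begin_b < 0:
            raise ValueError("match start coordinates must be non-negative")

    def validate_against(self, lengths: dict[str, int]) -> None:
        for seq, begin in ((self.seq_a, self.begin_a), (self.seq_b, self.begin_b)):
            if seq not in lengths:
                raise ValueError(f"match references unknown sequence {seq!r}")
            if begin + self.length > lengths[seq]:
                raise ValueError(
                    f"match [{begin}, {begin + self.length}) out of range for "
                    f"sequence {seq!r} of length {lengths[seq]}"
                )

    def pairs(self) -> Iterable[tuple[int, int]]:
        """Yield the aligned residue positions (pos_a, pos_b)."""
        for t in range(self.length):
            yield self.begin_a + t, self.begin_b + t


@dataclass
class ReferenceAnnotation:
    """Core columns of a reference MSA that count towards scoring.

    An empty set means every column counts.  Indices are 0-based columns
    of the associated reference alignment.
    """

    core_columns: frozenset[int] = field(default_factory=frozenset)

    def validate_against(self, ref: MSA) -> None:
        bad = [c for c in self.core_columns if c < 0 or c >= ref.ncol]
        if bad:
            raise ValueError(f"core columns out of range for reference MSA: {bad}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read unaligned protein sequences from a FASTA file.

    Lowercase input is uppercased and terminal '*' stripped; duplicate ids,
    illegal residues and empty files are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    seqs: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seqs.append(ProteinSequence(rec.id, clean_residues(str(rec.seq), rec.id)))
    return seqs


def write_fasta(sequences: Sequence[ProteinSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Aligned FASTA (MSA)


def read_msa(path: str | Path) -> MSA:
    """Read an aligned-FASTA file into an MSA; rows must be equal length."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records found in {path}")
    rows = [(rec.id, str(rec.seq).upper()) for rec in records]
    ncol = len(rows[0][1])
    for rid, row in rows:
        if len(row) != ncol:
            raise ValueError(
                f"ragged alignment in {path}: row {rid!r} has length "
                f"{len(row)}, expected {ncol}"
            )
    return MSA(rows)


def write_msa(msa: MSA, path: str | Path) -> None:
    records = [SeqRecord(Seq(row), id=rid, description="") for rid, row in msa.rows]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# T-Coffee-style match libraries

_LIB_HEADER = "! TC_LIB_FORMAT_01"


def write_match_library(
    sequences: Sequence[ProteinSequence],
    matches: Iterable[SegmentMatch],
    path: str | Path,
) -> None:
    """Write segment matches in the T-Coffee library dialect.

    The header lists every sequence (name, length, residues); the body holds
    per-residue pair lines ``ra rb weight`` (1-based) grouped under ``#i j``
    sequence-pair headers (1-based sequence indices).
    """
    index = {s.id: i + 1 for i, s in enumerate(sequences)}
    grouped: dict[tuple[int, int], list[tuple[int, int, int]]] = {}
    for m in matches:
        ia, ib = index[m.seq_a], index[m.seq_b]
        w = int(m.raw_score) if m.raw_score is not None else 100
        if ia <= ib:
            key, pairs = (ia, ib), [(a + 1, b + 1, w) for a, b in m.pairs()]
        else:
            key, pairs = (ib, ia), [(b + 1, a + 1, w) for a, b in m.pairs()]
        grouped.setdefault(key, []).extend(pairs)
    with open(path, "w") as fh:
        fh.write(_LIB_HEADER + "\n")
        fh.write(f"{len(sequences)}\n")
        for s in sequences:
            fh.write(f"{s.id} {len(s)} {s.residues}\n")
        for (ia, ib) in sorted(grouped):
            fh.write(f"#{ia} {ib}\n")
            for ra, rb, w in sorted(grouped[(ia, ib)]):
                fh.write(f"{ra} {rb} {w}\n")
        fh.write("! SEQ_1_TO_N\n")


def read_match_library(
    path: str | Path, sequences: Sequence[ProteinSequence]
) -> list[SegmentMatch]:
    """Read a T-Coffee-style library; consecutive residue pairs with a
    constant offset are merged into one SegmentMatch (source ``external``).

    The library may only reference sequences present in ``sequences``;
    coordinates are checked against their lengths.
    """
    by_id = {s.id: s for s in sequences}
    lengths = {s.id: len(s) for s in sequences}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    if lines and lines[0].startswith("!"):
        i += 1
    try:
        nseq = int(lines[i].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"malformed library header in {path}") from exc
    i += 1
    names: list[str] = []
    for _ in range(nseq):
        parts = lines[i].split()
        name, declared_len = parts[0], int(parts[1])
        if name not in by_id:
            raise ValueError(f"library references unknown sequence id {name!r}")
        if declared_len != lengths[name]:
            raise ValueError(
                f"library declares length {declared_len} for {name!r}, "
                f"input sequence has length {lengths[name]}"
            )
        names.append(name)
        i += 1

    matches: list[SegmentMatch] = []
    cur: tuple[str, str] | None = None
    run_start: tuple[int, int] | None = None
    run_len = 0
    run_score = 0.0
    prev: tuple[int, int] | None = None

    def flush() -> None:
        nonlocal run_start, run_len, run_score
        if cur is not None and run_start is not None and run_len > 0:
            m = SegmentMatch(
                cur[0], run_start[0], cur[1], run_start[1], run_len,
                source="external", raw_score=run_score,
            )
            m.validate_against(lengths)
            matches.append(m)
        run_start, run_len, run_score = None, 0, 0.0

    while i < len(lines):
        line = lines[i]
        i += 1
        if line.startswith("!"):
            break
        if line.startswith("#"):
            flush()
            prev = None
            ia, ib = (int(x) for x in line[1:].split())
            if not (1 <= ia <= nseq and 1 <= ib <= nseq):
                raise ValueError(f"library pair header {line!r} out of range")
            cur = (names[ia - 1], names[ib - 1])
            continue
        if cur is None:
            raise ValueError(f"residue pair line before any '#i j' header: {line!r}")
        parts = line.split()
        ra, rb = int(parts[0]) - 1, int(parts[1]) - 1
        w = float(parts[2]) if len(parts) > 2 else 100.0
        for seq, pos in ((cur[0], ra), (cur[1], rb)):
            if not 0 <= pos < lengths[seq]:
                raise ValueError(
                    f"residue index out of range in record {line!r} "
                    f"(sequence {seq!r} has length {lengths[seq]})"
                )
        if prev is not None and ra == prev[0] + 1 and rb == prev[1] + 1:
            run_len += 1
            run_score += w
        else:
            flush()
            run_start, run_len, run_score = (ra, rb), 1, w
        prev = (ra, rb)
    flush()
    return matches


# ---------------------------------------------------------------------------
# Newick and core-column annotations


def write_newick(tree, path: str | Path) -> None:
    """Write a guide tree as Newick (see :meth:`~graphmsa.tree.GuideTree.to_newick`)."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_core_columns(path: str | Path) -> ReferenceAnnotation:
    """Read a plain-text list of 1-based core column indices (whitespace- or
    newline-separated) into a 0-based ReferenceAnnotation."""
    with open(path) as fh:
        tokens = fh.read().split()
    cols = set()
    for tok in tokens:
        idx = int(tok)
        if idx < 1:
            raise ValueError(f"core column indices are 1-based; got {idx}")
        cols.add(idx - 1)
    return ReferenceAnnotation(frozenset(cols))
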