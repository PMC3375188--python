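"""The multiple sequence alignment container."""

from __future__ import annotations

from dataclasses import dataclass

GAP = "-"


@dataclass
class MSA:
    """A rectangular gapped alignment.

    ``rows`` is an ordered list of ``(sequence id, gapped string)``.  The
    invariants every finished alignment satisfies: all rows have equal
    length, degapping a row reproduces the input sequence, and no column is
    entirely gaps.
    """

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.rows:
            ncol = len(self.rows[0][1])
            for rid, row in self.rows:
                if len(row) != ncol:
                    raise ValueError(
                        f"ragged MSA: row {rid!r} has length {len(row)}, "
                        f"expected {ncol}"
                    )

    @property
    def ncol(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def nrow(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, seq_id: str) -> str:
        for rid, row in self.rows:
            if rid == seq_id:
                return row
        raise KeyError(seq_id)

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def column(self, j: int) -> list[str]:
        return [row[j] for _, row in self.rows]

    def position_to_column(self) -> dict[str, list[int]]:
        """For each row, the alignment column of every ungapped residue
        position (residue t of the sequence sits in column mapping[id][t])."""
        out: dict[str, list[int]] = {}
        for rid, row in self.rows:
            cols = [j for j, ch in enumerate(row) if ch != GAP]
            out[rid] = cols
        return out

    def drop_allgap_columns(self) -> "MSA":
        keep = [
            j for j in range(self.ncol) if any(row[j] != GAP for _, row in self.rows)
        ]
        return MSA([(rid, "".join(row[j] for j in keep)) for rid, row in self.rows])

    def subset(self, seq_ids: list[str]) -> "MSA":
        """Row subset in the given order, with all-gap columns dropped."""
        wanted = set(seq_ids)
        sub = MSA([(rid, row) for rid, row in self.rows if rid in wanted])
        return sub.drop_allgap_columns()

    def check_invariants(self, sequences: dict[str, str] | None = None) -> None:
        """Assert the hard MSA invariants, optionally against the inputs."""
        for j in range(self.ncol):
            if all(row[j] == GAP for _, row in self.rows):
                raise AssertionError(f"all-gap column at index {j}")
        if sequences is not None:
            for rid, row in self.rows:
                if row.replace(GAP, "") != sequences[rid]:
                    raise AssertionError(
                        f"degapped row {rid!r} does not reproduce its input sequence"
                    )
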