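"""Aligned-FASTA input, validation, and slicing to query coordinates.

A consensus analysis starts from a protein multiple sequence alignment (MSA)
containing one designated *query* (the wild-type sequence being engineered,
e.g. human G6Pase-alpha) plus homologs retrieved by similarity search. Before
any column statistics are computed, the MSA is *sliced*: columns where the
query row carries a gap are dropped, so that column ``i`` of the sliced
alignment is exactly query residue ``i`` and scores can be reported in the
protein-variant numbering the field uses (S298C and the like). The
:class:`ColumnMap` produced alongside the slice records which original MSA
column each query position came from, so the operation is reversible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from Bio import SeqIO

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    ConskitError,
    EmptyQueryError,
    QueryNotFoundError,
)

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .consensus import VariantScore

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Codes treated as missing data by downstream frequency counting.
AMBIGUOUS: frozenset[str] = frozenset("XBZ*")

GAP = "-"

_ALLOWED = frozenset(AMINO_ACIDS) | AMBIGUOUS | {GAP}

VARIANT_TABLE_COLUMNS = (
    "position",
    "wt_aa",
    "consensus_aa",
    "f_wt",
    "f_consensus",
    "coverage",
    "D_wt",
    "D_consensus",
    "score",
)


@dataclass(frozen=True)
class Alignment:
    """A rectangular, validated protein alignment with one designated query.

    Parameters
    ----------
    ids
        Unique sequence identifiers, one per row, order preserved.
    rows
        Gapped residue strings, all of identical length, upper case,
        restricted to the 20 amino acids, ``-`` gaps and the ambiguity
        codes ``X``, ``B``, ``Z``, ``*``.
    query_id
        Identifier of the query row; must match exactly one id.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    query_id: str

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows) or not self.ids:
            raise AlignmentShapeError("alignment must have matching, nonempty ids and rows")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentShapeError("sequence ids are not unique")
        length = len(self.rows[0])
        if length < 1:
            raise AlignmentShapeError("alignment length must be >= 1")
        for sid, row in zip(self.ids, self.rows):
            if len(row) != length:
                raise AlignmentShapeError(
                    f"record {sid!r} has length {len(row)}, expected {length}"
                )
            for pos, ch in enumerate(row):
                if ch not in _ALLOWED:
                    raise AlphabetError(
                        f"record {sid!r}, column {pos}: character {ch!r} is not an "
                        "amino acid, gap, or ambiguity code"
                    )
        if self.ids.count(self.query_id) != 1:
            raise QueryNotFoundError(
                f"query id {self.query_id!r} does not match exactly one record"
            )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.rows[0])

    @property
    def query_index(self) -> int:
        return self.ids.index(self.query_id)

    @property
    def query_row(self) -> str:
        return self.rows[self.query_index]

    def column(self, msa_column: int) -> tuple[str, ...]:
        """Residues of one alignment column, in row order."""
        return tuple(row[msa_column] for row in self.rows)


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from 1-based query positions to 0-based MSA columns.

    ``msa_columns[i - 1]`` is the original-alignment column holding query
    position ``i``. Columns are strictly increasing by construction.
    """

    msa_columns: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        cols = self.msa_columns
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ConskitError("msa_columns must be strictly increasing")

    def __len__(self) -> int:
        return len(self.msa_columns)

    def pairs(self) -> tuple[tuple[int, int], ...]:
        """``(query_position, msa_column)`` pairs, query positions 1-based."""
        return tuple((i + 1, c) for i, c in enumerate(self.msa_columns))

    def apply(self, alignment: Alignment) -> Alignment:
        """Project ``alignment`` onto the mapped columns (reproduces the slice)."""
        rows = tuple("".join(row[c] for c in self.msa_columns) for row in alignment.rows)
        return Alignment(ids=alignment.ids, rows=rows, query_id=alignment.query_id)


def read_alignment(path: str | Path, query_id: str) -> Alignment:
    """Read an aligned FASTA file and validate it as an :class:`Alignment`.

    Residues are upper-cased and ``.`` gaps normalized to ``-`` (both appear
    in real MAFFT output depending on mode). All records must have identical
    length and ``query_id`` must name exactly one of them.
    """
    path = Path(path)
    ids: list[str] = []
    rows: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        ids.append(record.id)
        rows.append(str(record.seq).upper().replace(".", GAP))
    if not ids:
        raise AlignmentShapeError(f"no FASTA records found in {path}")
    return Alignment(ids=tuple(ids), rows=tuple(rows), query_id=query_id)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    """Write an alignment back to aligned FASTA (one sequence per record)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for sid, row in zip(alignment.ids, alignment.rows):
            fh.write(f">{sid}\n{row}\n")


def slice_to_query(alignment: Alignment) -> tuple[Alignment, ColumnMap]:
    """Drop every column where the query row has a gap.

    Returns the sliced alignment (whose query row is gap-free, so column
    ``i`` is query position ``i+1``) and the :class:`ColumnMap` of retained
    original columns. Idempotent: slicing a sliced alignment is the identity.
    """
    query = alignment.query_row
    kept = tuple(c for c, ch in enumerate(query) if ch != GAP)
    if not kept:
        raise EmptyQueryError(f"query row {alignment.query_id!r} is entirely gaps")
    colmap = ColumnMap(msa_columns=kept)
    return colmap.apply(alignment), colmap


def _fmt(x: float) -> str:
    # 9 significant digits: round-trips comfortably above the documented
    # 6-significant-digit table contract while keeping rows byte-stable.
    return format(float(x), ".9g")


def write_variant_table(scores: Iterable["VariantScore"], path: str | Path) -> None:
    """Write ranked candidate substitutions as a TSV table.

    Columns: position, wt_aa, consensus_aa, f_wt, f_consensus, coverage,
    D_wt, D_consensus, score. Floats are rendered with 9 significant digits
    and ``\\n`` line endings so repeated runs are byte-identical.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(VARIANT_TABLE_COLUMNS) + "\n")
        for s in scores:
            fh.write(
                "\t".join(
                    (
                        str(s.position),
                        s.wt_aa,
                        s.consensus_aa,
                        _fmt(s.f_wt),
                        _fmt(s.f_consensus),
                        str(s.coverage),
                        _fmt(s.d_wt),
                        _fmt(s.d_consensus),
                        _fmt(s.score),
                    )
                )
                + "\n"
            )


def read_variant_table(path: str | Path) -> list["VariantScore"]:
    """Parse a TSV written by :func:`write_variant_table` back into scores."""
    from .consensus import VariantScore

    scores: list[VariantScore] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != VARIANT_TABLE_COLUMNS:
            raise ConskitError(f"unexpected variant-table header in {path}: {header}")
        for line in fh:
            p, w, c, fw, fc, cov, dw, dc, s = line.rstrip("\n").split("\t")
            scores.append(
                VariantScore(
                    position=int(p),
                    wt_aa=w,
                    consensus_aa=c,
                    f_wt=float(fw),
                    f_consensus=float(fc),
                    coverage=int(cov),
                    d_wt=float(dw),
                    d_consensus=float(dc),
                    score=float(s),
                )
            )
    return scores
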