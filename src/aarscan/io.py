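"""Sequence, alignment and annotation I/O.

All residue positions reported by the pipeline use *reference numbering*:
the 1-based coordinate of a residue in the ungapped sequence of a designated
reference row of the alignment, with the initiator Met as residue 1.  The
engineered extra Gly present in expression constructs between Met and the
second residue is never counted — positions always refer to the native
deposited sequence.  :func:`build_reference_map` materialises the mapping
between alignment columns and reference residue numbers that every
downstream residue report relies on.

Conventions
-----------
* amino-acid alphabet: the 20 canonical one-letter codes plus ``X`` for
  ambiguity (``X`` never counts as a match anywhere downstream);
* gap character is ``-``; a ``.`` in input alignments is normalised to ``-``;
* habitat labels: ``marine``, ``freshwater``, ``both`` or ``unknown``;
* all text files are UTF-8; FASTA is written with a 60-column wrap.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS) | {"X"}
GAP = "-"
HABITATS = ("marine", "freshwater", "both", "unknown")

_ALIGNMENT_FORMATS = {"aligned-fasta": "fasta", "clustal": "clustal"}


class FormatError(ValueError):
    """A file or in-memory object violates a format contract."""


@dataclass
class SequenceRecord:
    """One ungapped protein sequence with strain/variant metadata."""

    id: str
    residues: str
    description: str = ""
    habitat: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        self.residues = self.residues.upper()
        if not self.residues:
            raise FormatError(f"empty sequence for record {self.id!r}")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid residue characters {sorted(bad)!r}"
            )
        if self.habitat not in HABITATS:
            raise ValueError(
                f"record {self.id!r}: habitat must be one of {HABITATS}, "
                f"got {self.habitat!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Msa:
    """A gapped multiple sequence alignment as ordered (id, row) pairs."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError("alignment has no rows")
        norm = []
        for rid, row in self.rows:
            row = row.upper().replace(".", GAP)
            bad = set(row) - ALPHABET - {GAP}
            if bad:
                raise FormatError(
                    f"alignment row {rid!r}: invalid characters {sorted(bad)!r}"
                )
            if not row.replace(GAP, ""):
                raise FormatError(f"alignment row {rid!r} is all gaps")
            norm.append((rid, row))
        widths = {len(row) for _, row in norm}
        if len(widths) != 1:
            raise FormatError(f"ragged alignment: row widths {sorted(widths)}")
        ids = [rid for rid, _ in norm]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate alignment ids: {dupes}")
        self.rows = norm

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    def row(self, rid: str) -> str:
        for other, row in self.rows:
            if other == rid:
                return row
        raise KeyError(f"id {rid!r} not in alignment")

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")

    def column(self, index: int) -> list[str]:
        """Residues of 0-based column *index*, in row order."""
        return [row[index] for _, row in self.rows]


@dataclass
class ReferenceMap:
    """Mapping between alignment columns and reference residue numbers.

    ``column_to_residue[i]`` is the 1-based residue number of 0-based
    alignment column ``i`` in the ungapped reference sequence, or ``None``
    where the reference row carries a gap.
    """

    reference_id: str
    column_to_residue: list[int | None]
    _position_to_column: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        numbers = [n for n in self.column_to_residue if n is not None]
        if numbers != list(range(1, len(numbers) + 1)):
            raise ValueError("reference numbering must be 1..L over non-gap columns")
        self._position_to_column = {
            n: col for col, n in enumerate(self.column_to_residue) if n is not None
        }

    @property
    def reference_length(self) -> int:
        return len(self._position_to_column)

    def position_of_column(self, column: int) -> int | None:
        """Reference residue number of a 0-based column (None if reference gap)."""
        return self.column_to_residue[column]

    def column_of_position(self, position: int) -> int:
        """0-based alignment column holding reference residue *position*."""
        try:
            return self._position_to_column[position]
        except KeyError:
            raise KeyError(
                f"reference position {position} out of range "
                f"1..{self.reference_length}"
            ) from None


def build_reference_map(msa: Msa, reference_id: str) -> ReferenceMap:
    """Number alignment columns by the ungapped reference sequence (Met = 1)."""
    row = msa.row(reference_id)  # KeyError on unknown id
    mapping: list[int | None] = []
    n = 0
    for ch in row:
        if ch == GAP:
            mapping.append(None)
        else:
            n += 1
            mapping.append(n)
    return ReferenceMap(reference_id=reference_id, column_to_residue=mapping)


def _first_bad_line(path: Path) -> int | None:
    """1-based number of the first sequence line with a non-alphabet character."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) - ALPHABET:
                return lineno
    return None


def read_fasta(path: str | Path, habitats: dict[str, str] | None = None) -> list[SequenceRecord]:
    """Read ungapped protein sequences from a FASTA file.

    Parameters
    ----------
    path
        FASTA file; multi-line bodies are concatenated, order preserved.
    habitats
        Optional id → habitat mapping used to tag the records.

    Raises
    ------
    FormatError
        Empty file, duplicate ids, or characters outside the amino-acid
        alphabet (the error names the offending line).
    """
    path = Path(path)
    parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        raise FormatError(f"{path}: empty file or not FASTA")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in parsed:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        habitat = (habitats or {}).get(rec.id, "unknown")
        try:
            records.append(
                SequenceRecord(rec.id, str(rec.seq), description=desc, habitat=habitat)
            )
        except FormatError as exc:
            line = _first_bad_line(path)
            where = f" (line {line})" if line is not None else ""
            raise FormatError(f"{path}{where}: {exc}") from None
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as plain FASTA, 60 columns per sequence line."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_alignment(path: str | Path, format: str = "aligned-fasta") -> Msa:
    """Read a protein MSA from aligned FASTA or Clustal (.aln).

    Clustal block structure is reassembled into one row per id; ``.`` gaps
    are normalised to ``-``.  Ragged rows raise :class:`FormatError`.
    """
    path = Path(path)
    try:
        bio_format = _ALIGNMENT_FORMATS[format]
    except KeyError:
        raise ValueError(
            f"unknown alignment format {format!r}; "
            f"expected one of {sorted(_ALIGNMENT_FORMATS)}"
        ) from None
    try:
        aln = AlignIO.read(str(path), bio_format)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None
    return Msa([(rec.id, str(rec.seq)) for rec in aln])


def write_alignment(msa: Msa, path: str | Path, format: str = "aligned-fasta") -> None:
    bio_format = _ALIGNMENT_FORMATS[format]
    from Bio.Align import MultipleSeqAlignment

    aln = MultipleSeqAlignment(
        [_BioSeqRecord(Seq(row), id=rid, description="") for rid, row in msa.rows]
    )
    AlignIO.write(aln, str(path), bio_format)


def read_habitat_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (id, habitat) into an id → habitat mapping."""
    path = Path(path)
    table: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and [c.lower() for c in row[:2]] == ["id", "habitat"]:
                continue
            if len(row) < 2:
                raise FormatError(f"{path} line {lineno}: expected 2 columns")
            rid, habitat = row[0].strip(), row[1].strip().lower()
            if habitat not in HABITATS:
                raise FormatError(
                    f"{path} line {lineno}: habitat {habitat!r} not in {HABITATS}"
                )
            if rid in table:
                raise FormatError(f"{path} line {lineno}: duplicate id {rid!r}")
            table[rid] = habitat
    return table


def write_habitat_table(table: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\thabitat\n")
        for rid, habitat in table.items():
            fh.write(f"{rid}\t{habitat}\n")
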