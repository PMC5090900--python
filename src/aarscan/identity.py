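"""Pairwise global alignment and percent-identity matrices.

Percent identity between two aligned sequences is defined uniformly as

    100 x (columns where both letters are equal, neither is a gap and
           neither is 'X') / (columns where neither letter is a gap)

i.e. the denominator excludes columns where either sequence is gapped, and
the ambiguity code 'X' never counts as a match.  Identities feed both the
distance matrix behind the tree stage and the property-vs-identity
correlation stage.

Alignments are Needleman-Wunsch global alignments with affine gaps under
BLOSUM62 and BLAST protein gap costs (a gap of length k costs
open + k x extend = 11 + k by default).  End gaps are penalized (true
global alignment); acyl-ACP reductase orthologs are near-full-length, so
semi-global alignment is offered only as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import GAP, Msa, SequenceRecord


@dataclass
class ScoringScheme:
    """Substitution matrix and affine gap penalties (positive costs).

    A gap of length k costs ``gap_open + k * gap_extend``, the BLAST
    protein convention (default 11 + k).
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    penalize_end_gaps: bool = True

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        # Biopython charges open on the first gap position and extend on the
        # rest; open + (k-1)*extend == gap_open + k*gap_extend requires this
        # offset.
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        aligner.mode = "global"
        if not self.penalize_end_gaps:
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
        return aligner


class AlignedPair(NamedTuple):
    """Two equal-length gapped strings and the alignment score."""

    a: str
    b: str
    score: float


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix over an ordered id list."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in identity matrix")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 100.0):
            raise ValueError("identity matrix diagonal must be 100")
        if self.values.min() < 0 or self.values.max() > 100 + 1e-9:
            raise ValueError("identities must lie in [0, 100]")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def off_diagonal(self) -> np.ndarray:
        mask = ~np.eye(len(self.ids), dtype=bool)
        return self.values[mask]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for rid, row in zip(self.ids, self.values):
                fh.write(rid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IdentityMatrix":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows.append([float(v) for v in parts[1:]])
        return cls(ids=header, values=np.array(rows))


def _residues(seq: SequenceRecord | str) -> str:
    return seq.residues if isinstance(seq, SequenceRecord) else seq


def global_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    scheme: ScoringScheme | None = None,
) -> AlignedPair:
    """Optimal global alignment of two protein sequences.

    Returns equal-length gapped strings whose ungapped forms recover the
    inputs, plus the maximal score under *scheme*.  The traceback choice
    among co-optimal alignments is deterministic (the aligner's first
    enumeration order).
    """
    sa, sb = _residues(a), _residues(b)
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    scheme = scheme or ScoringScheme()
    aligner = scheme.make_aligner()
    best = aligner.align(sa, sb)[0]
    ga, gb = str(best[0]), str(best[1])
    return AlignedPair(ga, gb, float(best.score))


def percent_identity(a: str, b: str) -> float:
    """Percent identity of two equal-length gapped strings.

    Denominator counts columns where neither letter is a gap; 'X' never
    matches.  Raises :class:`ValueError` when no columns co-align.
    """
    if len(a) != len(b):
        raise ValueError("aligned strings must have equal length")
    overlap = matches = 0
    for ca, cb in zip(a, b):
        if ca == GAP or cb == GAP:
            continue
        overlap += 1
        if ca == cb and ca != "X":
            matches += 1
    if overlap == 0:
        raise ValueError("undefined identity: no columns where both are non-gap")
    return 100.0 * matches / overlap


def identity_matrix(
    records: Sequence[SequenceRecord], scheme: ScoringScheme | None = None
) -> IdentityMatrix:
    """Percent-identity matrix from all-pairs global alignments."""
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    n = len(records)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pair = global_align(records[i], records[j], scheme)
            pid = percent_identity(pair.a, pair.b)
            values[i, j] = values[j, i] = pid
    return IdentityMatrix(ids=ids, values=values)


def msa_identity_matrix(msa: Msa) -> IdentityMatrix:
    """Percent-identity matrix computed on MSA columns.

    Uses the same both-non-gap denominator convention as the pairwise
    route; when the MSA is exactly the stacked pairwise alignment the two
    agree.
    """
    if len(msa.rows) < 2:
        raise ValueError("need an alignment of at least 2 rows")
    n = len(msa.rows)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(msa.rows[i][1], msa.rows[j][1])
            values[i, j] = values[j, i] = pid
    return IdentityMatrix(ids=msa.ids, values=values)
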