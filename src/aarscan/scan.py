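"""Discriminating-position scanning and mutation proposals.

Two alignment-column criteria nominate candidate residues:

strict (activity-determinant) criterion
    every in-group row carries the same non-gap residue r, and at most
    ``max_outgroup_matches`` out-group rows (default 0) also carry r.
    This is how positions conserved in the highly active enzymes but
    absent from the others are found.

similarity (specificity-determinant) criterion
    all in-group residues fall within one amino-acid similarity class
    (Clustal "strong groups" by default, identical residues trivially
    qualifying), while not all out-group residues fall in that class.

Gap handling: a gap in any in-group row disqualifies the column; gaps (and
'X') in out-group rows count as non-matching.  Columns that are gaps in the
numbering reference are still scanned but flagged unnumberable and reported
by alignment column only.

Each strict position found in a target sequence outside the in-group yields
a mutation proposal named wild-type letter + reference position + in-group
consensus, e.g. ``Q15R``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .io import GAP, Msa, ReferenceMap, SequenceRecord

#: Clustal strong groups (the ':' annotation classes of alignment output).
CLUSTAL_STRONG_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g) for g in ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")
)


@dataclass
class SimilarityClasses:
    """A named partition-like family of amino-acid sets (overlap allowed)."""

    classes: tuple[frozenset[str], ...] = CLUSTAL_STRONG_GROUPS

    def __post_init__(self) -> None:
        from .io import AMINO_ACIDS

        for cls in self.classes:
            bad = set(cls) - set(AMINO_ACIDS)
            if bad:
                raise ValueError(f"similarity class contains non-canonical letters {bad}")

    def classes_containing(self, letters: set[str]) -> list[frozenset[str]]:
        """Classes covering all *letters*; identical letters form their own class."""
        out = [cls for cls in self.classes if letters <= cls]
        if len(letters) == 1:
            letter = next(iter(letters))
            if letter not in (GAP, "X"):
                out.append(frozenset([letter]))
        return out


@dataclass
class GroupSpec:
    """Which alignment rows form the in-group, and the criterion to apply."""

    name: str
    ingroup_ids: tuple[str, ...]
    mode: str = "strict"
    max_outgroup_matches: int = 0
    similarity: SimilarityClasses = field(default_factory=SimilarityClasses)

    def __post_init__(self) -> None:
        self.ingroup_ids = tuple(self.ingroup_ids)
        if not self.ingroup_ids:
            raise ValueError("in-group must be non-empty")
        if self.mode not in ("strict", "similarity"):
            raise ValueError(f"mode must be strict|similarity, got {self.mode!r}")
        if self.max_outgroup_matches < 0:
            raise ValueError("max_outgroup_matches must be >= 0")

    def validate_against(self, msa: Msa) -> tuple[list[str], list[str]]:
        ids = msa.ids
        missing = [i for i in self.ingroup_ids if i not in ids]
        if missing:
            raise ValueError(f"in-group ids not in alignment: {missing}")
        if set(self.ingroup_ids) >= set(ids):
            raise ValueError("in-group must be a proper subset of the alignment ids")
        ingroup = [i for i in ids if i in self.ingroup_ids]
        outgroup = [i for i in ids if i not in self.ingroup_ids]
        return ingroup, outgroup


@dataclass
class DiscriminatingPosition:
    """One alignment column satisfying a scan criterion.

    ``column`` is the 0-based alignment column; ``reference_position`` is
    its 1-based residue number in the numbering reference, or None when the
    reference is gapped there (unnumberable).
    """

    reference_position: int | None
    column: int
    criterion: str
    ingroup_residues: str
    outgroup_residues: str

    @property
    def numberable(self) -> bool:
        return self.reference_position is not None


@dataclass
class MutationSuggestion:
    """A proposed single substitution, named like ``Q15R``."""

    target_id: str
    reference_position: int
    wild_type: str
    proposed: str

    def __post_init__(self) -> None:
        if self.wild_type == self.proposed:
            raise ValueError("proposed residue must differ from the wild type")

    @property
    def label(self) -> str:
        return f"{self.wild_type}{self.reference_position}{self.proposed}"

    @property
    def variant_id(self) -> str:
        return f"{self.target_id}_{self.label}"


def _sorted_positions(
    hits: list[DiscriminatingPosition],
) -> list[DiscriminatingPosition]:
    numbered = sorted((h for h in hits if h.numberable), key=lambda h: h.reference_position)
    unnumbered = sorted((h for h in hits if not h.numberable), key=lambda h: h.column)
    return numbered + unnumbered


def scan_strict(
    msa: Msa, spec: GroupSpec, refmap: ReferenceMap
) -> list[DiscriminatingPosition]:
    """Columns strictly conserved in the in-group and rare outside it."""
    if spec.mode != "strict":
        raise ValueError("scan_strict requires a strict-mode GroupSpec")
    ingroup, outgroup = spec.validate_against(msa)
    in_rows = [msa.row(i) for i in ingroup]
    out_rows = [msa.row(i) for i in outgroup]
    hits: list[DiscriminatingPosition] = []
    for col in range(msa.width):
        in_letters = {row[col] for row in in_rows}
        if len(in_letters) != 1:
            continue
        r = next(iter(in_letters))
        if r in (GAP, "X"):
            continue
        out_letters = [row[col] for row in out_rows]
        if sum(1 for ch in out_letters if ch == r) > spec.max_outgroup_matches:
            continue
        hits.append(
            DiscriminatingPosition(
                reference_position=refmap.position_of_column(col),
                column=col,
                criterion="strict",
                ingroup_residues=r,
                outgroup_residues="".join(sorted(set(out_letters))),
            )
        )
    return _sorted_positions(hits)


def scan_similarity(
    msa: Msa, spec: GroupSpec, refmap: ReferenceMap
) -> list[DiscriminatingPosition]:
    """Columns class-similar in the in-group but not across the out-group."""
    if spec.mode != "similarity":
        raise ValueError("scan_similarity requires a similarity-mode GroupSpec")
    ingroup, outgroup = spec.validate_against(msa)
    in_rows = [msa.row(i) for i in ingroup]
    out_rows = [msa.row(i) for i in outgroup]
    hits: list[DiscriminatingPosition] = []
    for col in range(msa.width):
        in_letters = {row[col] for row in in_rows}
        if GAP in in_letters or "X" in in_letters:
            continue
        candidates = spec.similarity.classes_containing(in_letters)
        if not candidates:
            continue
        out_letters = [row[col] for row in out_rows]
        ok = any(
            not all(ch in cls for ch in out_letters) for cls in candidates
        )
        if not ok:
            continue
        hits.append(
            DiscriminatingPosition(
                reference_position=refmap.position_of_column(col),
                column=col,
                criterion="similarity",
                ingroup_residues="".join(sorted(in_letters)),
                outgroup_residues="".join(sorted(set(out_letters))),
            )
        )
    return _sorted_positions(hits)


def scan(msa: Msa, spec: GroupSpec, refmap: ReferenceMap) -> list[DiscriminatingPosition]:
    """Dispatch on the GroupSpec mode."""
    if spec.mode == "strict":
        return scan_strict(msa, spec, refmap)
    return scan_similarity(msa, spec, refmap)


@dataclass
class SkippedPosition:
    """A scan position for which no proposal could be made, with the reason."""

    reference_position: int | None
    column: int
    reason: str


def ingroup_consensus(msa: Msa, spec: GroupSpec, column: int) -> str:
    """Most common in-group residue at a column (alphabetical tie-break)."""
    ingroup, _ = spec.validate_against(msa)
    letters = [msa.row(i)[column] for i in ingroup]
    counts = Counter(ch for ch in letters if ch not in (GAP, "X"))
    if not counts:
        raise ValueError(f"no consensus residue at column {column}")
    best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
    return best[0]


def propose_mutations(
    positions: Sequence[DiscriminatingPosition],
    target: SequenceRecord | str,
    msa: Msa,
    spec: GroupSpec,
) -> tuple[list[MutationSuggestion], list[SkippedPosition]]:
    """Mutation proposals moving a target toward the in-group consensus.

    The target must be an alignment row outside the in-group.  Positions
    where the target already matches the consensus are skipped silently;
    positions where the target is gapped or unnumberable are returned as
    :class:`SkippedPosition` warnings.
    """
    target_id = target.id if isinstance(target, SequenceRecord) else target
    if target_id in spec.ingroup_ids:
        raise ValueError(f"target {target_id!r} is in the in-group")
    row = msa.row(target_id)  # KeyError on unknown target
    suggestions: list[MutationSuggestion] = []
    skipped: list[SkippedPosition] = []
    for pos in positions:
        consensus = ingroup_consensus(msa, spec, pos.column)
        wt = row[pos.column]
        if not pos.numberable:
            skipped.append(
                SkippedPosition(pos.reference_position, pos.column, "reference gap")
            )
            continue
        if wt == GAP:
            skipped.append(
                SkippedPosition(pos.reference_position, pos.column, "target gap")
            )
            continue
        if wt == consensus:
            continue
        suggestions.append(
            MutationSuggestion(
                target_id=target_id,
                reference_position=pos.reference_position,
                wild_type=wt,
                proposed=consensus,
            )
        )
    return suggestions, skipped


def positions_to_tsv(
    positions: Sequence[DiscriminatingPosition], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "reference_position\tcolumn_1based\tcriterion\t"
            "ingroup_residues\toutgroup_residues\n"
        )
        for p in positions:
            ref = p.reference_position if p.numberable else "NA"
            fh.write(
                f"{ref}\t{p.column + 1}\t{p.criterion}\t"
                f"{p.ingroup_residues}\t{p.outgroup_residues}\n"
            )


def mutations_to_tsv(
    suggestions: Sequence[MutationSuggestion], path: str | Path
) -> None:
    """Mutation list keyed by quantification-style variant ids (``6803_Q15R``)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("variant_id\ttarget_id\tlabel\treference_position\twild_type\tproposed\n")
        for s in suggestions:
            fh.write(
                f"{s.variant_id}\t{s.target_id}\t{s.label}\t"
                f"{s.reference_position}\t{s.wild_type}\t{s.proposed}\n"
            )
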