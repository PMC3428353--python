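"""Cysteine-scaffold profiling of OBP multiple sequence alignments.

Classic insect odorant-binding proteins carry six conserved cysteines
(C1..C6, numbered from the N terminus) whose three disulphide bonds
(C1-C3, C2-C5, C4-C6) stabilise the fold.  This module locates the six
canonical cysteine columns in a protein alignment, builds per-sequence
presence/absence profiles and assigns each complete sequence to one of
the classic / minus-C / plus-C subfamilies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import AlignIO, SeqIO

__all__ = [
    "Alignment",
    "CanonicalColumns",
    "CysteineProfile",
    "SubfamilyCall",
    "read_alignment",
    "locate_canonical_columns",
    "profile_sequence",
    "classify_subfamily",
    "profile_table",
]

GAP = "-"
#: default 1-based alignment column where the mature protein starts
#: (positions before it are treated as signal peptide and ignored when
#: counting extra cysteines)
DEFAULT_MATURE_START = 25


@dataclass(frozen=True)
class Alignment:
    """A protein multiple sequence alignment.

    ``records`` maps sequence ids to aligned residue strings (upper case,
    ``-`` for gaps); all strings share the same length.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("no records")
        length = len(self.records[0][1])
        seen: set[str] = set()
        for sid, residues in self.records:
            if not sid:
                raise ValueError("empty sequence id")
            if sid in seen:
                raise ValueError(f"duplicate sequence id: {sid!r}")
            seen.add(sid)
            if len(residues) != length:
                raise ValueError(
                    f"unequal lengths: record {sid!r} has {len(residues)} columns, "
                    f"expected {length}"
                )

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, sequence_id: str) -> str:
        for sid, residues in self.records:
            if sid == sequence_id:
                return residues
        raise KeyError(sequence_id)

    def __contains__(self, sequence_id: str) -> bool:
        return any(sid == sequence_id for sid, _ in self.records)

    def column(self, col: int) -> str:
        """Residues of 1-based column ``col`` in record order."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} outside [1, {self.length}]")
        return "".join(residues[col - 1] for _, residues in self.records)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "Alignment":
        norm = tuple(
            (sid, residues.upper().replace(".", GAP)) for sid, residues in records
        )
        return cls(norm)


@dataclass(frozen=True)
class CanonicalColumns:
    """1-based alignment columns holding the six canonical cysteines C1..C6."""

    columns: tuple[int, int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.columns) != 6:
            raise ValueError(f"expected 6 canonical columns, got {len(self.columns)}")
        if any(b <= a for a, b in zip(self.columns, self.columns[1:])):
            raise ValueError(f"canonical columns must be strictly increasing: {self.columns}")
        if self.columns[0] < 1:
            raise ValueError("canonical columns are 1-based")

    def __iter__(self):
        return iter(self.columns)

    def __getitem__(self, i: int) -> int:
        return self.columns[i]


CYSTEINES = ("C1", "C2", "C3", "C4", "C5", "C6")


@dataclass(frozen=True)
class CysteineProfile:
    """Presence/absence of the canonical cysteines for one sequence.

    ``present[i]`` — a cysteine occupies canonical column i+1;
    ``unknown[i]`` — the column falls in a terminal gap run (truncated or
    otherwise incomplete sequence), so the state is unobserved.  An internal
    gap counts as absent: a deletion removes the cysteine just as a
    substitution does.  ``extra_cysteines`` counts cysteines of the mature
    region outside the canonical columns.
    """

    sequence_id: str
    present: tuple[bool, bool, bool, bool, bool, bool]
    unknown: tuple[bool, bool, bool, bool, bool, bool]
    extra_cysteines: int = 0

    def __post_init__(self) -> None:
        if len(self.present) != 6 or len(self.unknown) != 6:
            raise ValueError("present/unknown must have six entries (C1..C6)")
        if any(p and u for p, u in zip(self.present, self.unknown)):
            raise ValueError("a canonical cysteine cannot be both present and unknown")
        if self.extra_cysteines < 0:
            raise ValueError("extra_cysteines must be non-negative")

    @property
    def is_complete(self) -> bool:
        return not any(self.unknown)

    @property
    def n_present(self) -> int:
        return sum(self.present)

    def absent_cysteines(self) -> frozenset[str]:
        """Names of canonical cysteines observed absent (unknowns excluded)."""
        return frozenset(
            c for c, p, u in zip(CYSTEINES, self.present, self.unknown) if not p and not u
        )

    @classmethod
    def complete(
        cls, sequence_id: str, present: Sequence[bool], extra_cysteines: int = 0
    ) -> "CysteineProfile":
        """Profile with all six states observed (no unknowns)."""
        return cls(sequence_id, tuple(bool(p) for p in present), (False,) * 6, extra_cysteines)


@dataclass(frozen=True)
class SubfamilyCall:
    sequence_id: str
    subfamily: str  # classic | minus-C | plus-C | incomplete

    VALID = ("classic", "minus-C", "plus-C", "incomplete")

    def __post_init__(self) -> None:
        if self.subfamily not in self.VALID:
            raise ValueError(f"unknown subfamily {self.subfamily!r}")


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read a protein alignment from FASTA or Clustal.

    Residues are upper-cased and ``.`` gaps normalised to ``-``.  Ragged
    inputs raise a ``ValueError`` naming the offending record; duplicate
    ids and empty files are rejected.
    """
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    # SeqIO for fasta so ragged records produce a diagnosable error rather
    # than failing inside AlignIO's coercion.
    if format == "fasta":
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    else:
        aln = AlignIO.read(str(path), "clustal")
        records = [(rec.id, str(rec.seq)) for rec in aln]
    if not records:
        raise ValueError(f"no records in {path}")
    return Alignment.from_records(records)


def _occupancy(aln: Alignment, col: int) -> float:
    """Fraction of non-gap residues at ``col`` that are cysteine."""
    residues = [r for r in aln.column(col) if r != GAP]
    if not residues:
        return 0.0
    return sum(r == "C" for r in residues) / len(residues)


def _c2c3_spacing_ok(aln: Alignment, c2: int, c3: int, min_fraction: float) -> bool:
    """True when, among sequences with residues at both columns, a majority
    has exactly three ungapped residues between them (the C2-C3 hallmark of
    the classic OBP scaffold)."""
    n_span = 0
    n_ok = 0
    for _, residues in aln.records:
        a, b = residues[c2 - 1], residues[c3 - 1]
        if a == GAP or b == GAP:
            continue
        n_span += 1
        between = residues[c2 : c3 - 1].replace(GAP, "")
        if len(between) == 3:
            n_ok += 1
    if n_span == 0:
        return False
    return n_ok / n_span >= min_fraction


def locate_canonical_columns(
    aln: Alignment,
    mode: str = "majority",
    reference_ids: Optional[Sequence[str]] = None,
    min_fraction: float = 0.5,
    mature_start: int = DEFAULT_MATURE_START,
) -> CanonicalColumns:
    """Find the six canonical cysteine columns of an OBP alignment.

    ``majority`` mode ranks columns by cysteine occupancy among non-gap
    residues, keeps those at or above ``min_fraction``, and picks the six
    highest-occupancy columns in alignment order, requiring the hallmark
    C2-C3 spacing (exactly three ungapped residues apart in a majority of
    sequences spanning both columns) where a choice among candidate column
    sets exists.  ``reference`` mode reads the columns straight off one or
    more reference sequences that carry exactly six mature-region cysteines.
    """
    if mode == "reference":
        if not reference_ids:
            raise ValueError("reference mode requires reference_ids")
        column_sets = set()
        for rid in reference_ids:
            residues = aln[rid]  # KeyError -> unknown id
            cols = tuple(
                i + 1
                for i, r in enumerate(residues)
                if r == "C" and i + 1 >= min(mature_start, len(residues))
            )
            if len(cols) != 6:
                raise ValueError(
                    f"reference {rid!r} has {len(cols)} mature-region cysteines, need 6"
                )
            column_sets.add(cols)
        if len(column_sets) != 1:
            raise ValueError(f"reference sequences disagree on columns: {sorted(column_sets)}")
        return CanonicalColumns(column_sets.pop())

    if mode != "majority":
        raise ValueError(f"unknown mode {mode!r}")

    candidates = [
        (col, _occupancy(aln, col))
        for col in range(1, aln.length + 1)
        if _occupancy(aln, col) >= min_fraction
    ]
    if len(candidates) < 6:
        raise ValueError(
            f"scaffold not found: only {len(candidates)} columns reach "
            f"cysteine occupancy {min_fraction}"
        )
    # Highest-occupancy six, preferring column sets whose C2-C3 pair shows
    # the 3-residue hallmark spacing.  Ties in occupancy break toward
    # earlier columns for determinism.
    ranked = sorted(candidates, key=lambda t: (-t[1], t[0]))
    best = sorted(col for col, _ in ranked[:6])
    if len(candidates) > 6 and not _c2c3_spacing_ok(aln, best[1], best[2], min_fraction):
        # look for an alternative six-column subset (swap one candidate in)
        # restoring the hallmark; fall back to pure occupancy if none does
        pool = sorted(col for col, _ in ranked[: min(len(ranked), 10)])
        from itertools import combinations

        for combo in combinations(pool, 6):
            if _c2c3_spacing_ok(aln, combo[1], combo[2], min_fraction):
                best = list(combo)
                break
    return CanonicalColumns(tuple(best))


def _terminal_gap_mask(residues: str) -> list[bool]:
    """True for positions inside the leading or trailing gap run."""
    n = len(residues)
    mask = [False] * n
    i = 0
    while i < n and residues[i] == GAP:
        mask[i] = True
        i += 1
    j = n - 1
    while j >= 0 and residues[j] == GAP:
        mask[j] = True
        j -= 1
    return mask


def profile_sequence(
    aln: Alignment,
    cols: CanonicalColumns,
    sequence_id: str,
    mature_start: Optional[int] = None,
) -> CysteineProfile:
    """Build the canonical-cysteine profile of one aligned sequence.

    A cysteine at a canonical column is *present*; a canonical column inside
    a leading/trailing gap run is *unknown* (incomplete sequence); an
    internal gap or any other residue is *absent*.  ``extra_cysteines``
    counts cysteines at non-canonical columns from ``mature_start`` on
    (default column 25, past the signal peptide).
    """
    if sequence_id not in aln:
        raise KeyError(f"unknown sequence id {sequence_id!r}")
    if mature_start is None:
        mature_start = DEFAULT_MATURE_START
    residues = aln[sequence_id]
    terminal = _terminal_gap_mask(residues)
    present = []
    unknown = []
    canonical = set(cols.columns)
    for col in cols:
        r = residues[col - 1]
        present.append(r == "C")
        unknown.append(r == GAP and terminal[col - 1])
    extra = sum(
        1
        for i, r in enumerate(residues, start=1)
        if r == "C" and i not in canonical and i >= mature_start
    )
    return CysteineProfile(sequence_id, tuple(present), tuple(unknown), extra)


def classify_subfamily(p: CysteineProfile, plus_c_min_extra: int = 2) -> SubfamilyCall:
    """Assign the classic / minus-C / plus-C subfamily label.

    Any observed absence of a canonical cysteine makes a sequence minus-C;
    all six present with at least ``plus_c_min_extra`` additional
    mature-region cysteines makes it plus-C (two extras being the minimum
    for an extra disulphide bond); otherwise classic.  Profiles with
    unknown states are reported as ``incomplete`` rather than classified.
    """
    if not p.is_complete:
        return SubfamilyCall(p.sequence_id, "incomplete")
    if not all(p.present):
        return SubfamilyCall(p.sequence_id, "minus-C")
    if p.extra_cysteines >= plus_c_min_extra:
        return SubfamilyCall(p.sequence_id, "plus-C")
    return SubfamilyCall(p.sequence_id, "classic")


def profile_table(
    aln: Alignment,
    cols: CanonicalColumns,
    mature_start: Optional[int] = None,
    plus_c_min_extra: int = 2,
) -> "pandas.DataFrame":
    """Profile and classify every sequence; returns a tidy DataFrame.

    Columns: sequence_id, C1..C6 (P/A/U), extra_cysteines, subfamily.
    """
    import pandas as pd

    rows = []
    for sid in aln.ids:
        p = profile_sequence(aln, cols, sid, mature_start=mature_start)
        call = classify_subfamily(p, plus_c_min_extra=plus_c_min_extra)
        row = {"sequence_id": sid}
        for c, pres, unk in zip(CYSTEINES, p.present, p.unknown):
            row[c] = "P" if pres else ("U" if unk else "A")
        row["extra_cysteines"] = p.extra_cysteines
        row["subfamily"] = call.subfamily
        rows.append(row)
    return pd.DataFrame(rows)
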