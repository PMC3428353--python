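"""Tandem double-domain OBP detection and domain delimitation.

Some OBP genes encode two OBP domains in tandem — in the jewel wasp these
arose from a single fusion of two closely related single-domain genes and
are exceptionally long (more than 250 amino acids).  A tandem arrangement
leaves three independent footprints: an off-main-diagonal run of high
similarity in a self-comparison dotplot, a duplicated exon/intron layout,
and two copies of the cysteine scaffold.  This module scores all three and
combines them into a single / double / vestigial-double call, then places
the inter-domain boundary (first residue of domain 2), snapping it to a
nearby splice site when the gene structure is known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "GeneStructure",
    "DiagonalRun",
    "DotplotResult",
    "ScaffoldMatch",
    "DomainArchitecture",
    "self_dotplot",
    "find_scaffold_hits",
    "detect_architecture",
    "delimit_domains",
    "split_domains",
]

#: allowed residue gaps between consecutive canonical cysteines when
#: scanning an unaligned sequence for the six-cysteine scaffold; the
#: C2->C3 gap of exactly three residues is the fold's hallmark
DEFAULT_SCAFFOLD_GAPS = ((10, 60), (3, 3), (10, 60), (4, 25), (4, 40))


@dataclass(frozen=True)
class GeneStructure:
    """Exon layout of a coding sequence.

    ``exons`` are 1-based inclusive (start, end) nucleotide intervals on the
    spliced CDS, ascending and non-overlapping; ``intron_phases`` (0, 1 or 2)
    give each intron's position within a codon.
    """

    gene_id: str
    exons: tuple[tuple[int, int], ...]
    intron_phases: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("gene structure needs at least one exon")
        prev_end = 0
        for start, end in self.exons:
            if start <= prev_end or end < start:
                raise ValueError(f"exons must be ascending and non-overlapping: {self.exons}")
            prev_end = end
        if len(self.intron_phases) != len(self.exons) - 1:
            raise ValueError("need exactly one intron phase per exon junction")
        if any(p not in (0, 1, 2) for p in self.intron_phases):
            raise ValueError("intron phases must be 0, 1 or 2")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def splice_residues(self) -> list[int]:
        """1-based residue positions of the first residue at/after each
        splice site (the residue containing the first base of each
        downstream exon)."""
        return [end // 3 + 1 for _, end in self.exons[:-1]]


@dataclass(frozen=True)
class DiagonalRun:
    """A contiguous off-main-diagonal run of high windowed similarity.

    ``offset`` is j - i (> 0 by convention; the matrix is symmetric),
    ``start`` the 1-based position of the run's first residue in the
    earlier copy, ``length`` its extent along the diagonal."""

    offset: int
    start: int
    length: int
    mean_score: float


@dataclass
class DotplotResult:
    """Windowed self-similarity of a protein sequence.

    ``scores[i, j]`` is the mean substitution score of the length-``window``
    diagonal window centred on residues (i+1, j+1); symmetric by
    construction.  ``diagonals`` lists detected off-main-diagonal runs.
    """

    window: int
    scores: np.ndarray
    diagonals: list[DiagonalRun]

    @property
    def has_offdiagonal_run(self) -> bool:
        return bool(self.diagonals)

    def best_run(self) -> Optional[DiagonalRun]:
        if not self.diagonals:
            return None
        return max(self.diagonals, key=lambda r: (r.length, r.mean_score))


def _score_lookup(matrix_name: str) -> tuple[np.ndarray, dict[str, int]]:
    mat = substitution_matrices.load(matrix_name)
    alphabet = list(mat.alphabet)
    index = {a: i for i, a in enumerate(alphabet)}
    return np.asarray(mat, dtype=float), index


def self_dotplot(
    sequence: str,
    window: int = 15,
    score_matrix: str = "BLOSUM62",
    min_run: int = 30,
    min_mean: float = 1.0,
) -> DotplotResult:
    """Self-comparison dotplot with a sliding diagonal window.

    For every residue pair (i, j) the mean substitution score over the
    window centred on the diagonal through (i, j) is computed (windows are
    truncated at the sequence ends).  Off-main-diagonal runs where the
    windowed mean stays at or above ``min_mean`` for at least ``min_run``
    consecutive positions are reported; a tandem domain duplication shows
    up as such a run at an offset near the domain length.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and positive, got {window}")
    if n < window:
        raise ValueError(f"sequence length {n} shorter than window {window}")
    mat, index = _score_lookup(score_matrix)
    fallback = index.get("X", 0)
    codes = np.array([index.get(r, fallback) for r in sequence])
    pair = mat[codes[:, None], codes[None, :]]

    half = window // 2
    kernel = np.ones(window)
    scores = np.empty_like(pair)
    counts_cache: dict[int, np.ndarray] = {}
    for k in range(-(n - 1), n):
        diag = np.diagonal(pair, offset=k)
        m = diag.size
        lo = half  # centre slice of the full convolution (works for m < window too)
        if m not in counts_cache:
            counts_cache[m] = np.convolve(np.ones(m), kernel, mode="full")[lo : lo + m]
        smooth = np.convolve(diag, kernel, mode="full")[lo : lo + m] / counts_cache[m]
        if k >= 0:
            idx = np.arange(m)
            scores[idx, idx + k] = smooth
        else:
            idx = np.arange(m)
            scores[idx - k, idx] = smooth

    runs: list[DiagonalRun] = []
    for k in range(1, n):
        diag = np.diagonal(scores, offset=k)
        above = diag >= min_mean
        i = 0
        m = diag.size
        while i < m:
            if above[i]:
                j = i
                while j < m and above[j]:
                    j += 1
                if j - i >= min_run:
                    runs.append(
                        DiagonalRun(
                            offset=k,
                            start=i + 1,
                            length=j - i,
                            mean_score=float(diag[i:j].mean()),
                        )
                    )
                i = j
            else:
                i += 1
    return DotplotResult(window=window, scores=scores, diagonals=runs)


@dataclass(frozen=True)
class ScaffoldMatch:
    """A match of the six-cysteine scaffold (or a partial remnant of one)
    in an unaligned protein sequence; positions are 1-based."""

    cys_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.cys_positions:
            raise ValueError("a scaffold match needs at least one cysteine")
        if any(b <= a for a, b in zip(self.cys_positions, self.cys_positions[1:])):
            raise ValueError("cysteine positions must be strictly increasing")

    @property
    def start(self) -> int:
        return self.cys_positions[0]

    @property
    def end(self) -> int:
        return self.cys_positions[-1]

    @property
    def is_full(self) -> bool:
        return len(self.cys_positions) == 6

    def overlaps(self, other: "ScaffoldMatch") -> bool:
        return not (self.end < other.start or other.end < self.start)


def find_scaffold_hits(
    sequence: str,
    gap_ranges: Sequence[tuple[int, int]] = DEFAULT_SCAFFOLD_GAPS,
) -> list[ScaffoldMatch]:
    """Scan a protein for non-overlapping six-cysteine scaffold matches.

    Cysteine positions are chained left to right subject to the allowed
    inter-cysteine gap ranges (``gap_ranges[i]`` bounds the residue gap
    between C(i+1) and C(i+2), exclusive of both cysteines).  A depth-first
    search takes the left-most complete chain, masks it out, and repeats,
    so tandem duplicated scaffolds yield two non-overlapping matches.
    """
    sequence = sequence.upper()
    cys = [i + 1 for i, r in enumerate(sequence) if r == "C"]
    hits: list[ScaffoldMatch] = []
    used: set[int] = set()

    def extend(chain: list[int]) -> Optional[list[int]]:
        if len(chain) == 6:
            return chain
        lo, hi = gap_ranges[len(chain) - 1]
        for pos in cys:
            if pos in used or pos <= chain[-1]:
                continue
            gap = pos - chain[-1] - 1
            if gap < lo:
                continue
            if gap > hi:
                break
            result = extend(chain + [pos])
            if result is not None:
                return result
        return None

    for start in cys:
        if start in used:
            continue
        chain = extend([start])
        if chain is not None:
            hits.append(ScaffoldMatch(tuple(chain)))
            used.update(chain)
    return hits


@dataclass
class DomainArchitecture:
    """Single- vs double-domain call for one gene.

    ``boundary`` is the 1-based residue index of the first residue of
    domain 2 (set only for double / vestigial_double calls); ``evidence``
    flags which signals supported the call.
    """

    gene_id: str
    call: str  # single | double | vestigial_double
    boundary: Optional[int] = None
    domain_hits: tuple[ScaffoldMatch, ...] = ()
    evidence: dict = field(default_factory=dict)
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.call not in ("single", "double", "vestigial_double"):
            raise ValueError(f"unknown architecture call {self.call!r}")
        if self.call == "single" and self.boundary is not None:
            raise ValueError("single-domain calls carry no boundary")


def detect_architecture(
    sequence: str,
    profile_hits: Optional[Sequence[ScaffoldMatch]] = None,
    structure: Optional[GeneStructure] = None,
    min_double_length: int = 250,
    gene_id: str = "gene",
    dotplot_kwargs: Optional[dict] = None,
) -> DomainArchitecture:
    """Call a protein single, double or vestigial-double domain.

    Double: two non-overlapping full scaffold matches, or an exceptionally
    long protein (> ``min_double_length`` residues) with an off-diagonal
    dotplot run.  Vestigial double: one full scaffold plus a terminal
    remnant supported by at least two of three evidence types — remnant
    cysteine(s), a splice site in the remnant region, extra exons beyond a
    single domain's two.  Otherwise single.
    """
    sequence = sequence.upper()
    if profile_hits is None:
        profile_hits = find_scaffold_hits(sequence)
    full = [h for h in profile_hits if h.is_full]
    evidence = {"dotplot": False, "splice": False, "cysteine": False, "length": False}
    evidence["length"] = len(sequence) > min_double_length

    dotplot = None
    if evidence["length"] or len(full) >= 2:
        dotplot = self_dotplot(sequence, **(dotplot_kwargs or {}))
        evidence["dotplot"] = dotplot.has_offdiagonal_run

    if len(full) >= 2:
        evidence["cysteine"] = True
        return DomainArchitecture(
            gene_id, "double", boundary=None, domain_hits=tuple(full[:2]),
            evidence=evidence, sequence=sequence,
        )
    if evidence["length"] and evidence["dotplot"]:
        return DomainArchitecture(
            gene_id, "double", boundary=None, domain_hits=tuple(full),
            evidence=evidence, sequence=sequence,
        )

    if len(full) == 1:
        hit = full[0]
        # terminal remnant: cysteines outside the full scaffold's span,
        # on the N side or the C side
        remnant_cys = [
            i + 1
            for i, r in enumerate(sequence)
            if r == "C" and (i + 1 < hit.start or i + 1 > hit.end)
        ]
        n_evidence = 0
        if remnant_cys:
            evidence["cysteine"] = True
            n_evidence += 1
        if structure is not None:
            # a lone domain is encoded by two exons in this gene family;
            # extra exons hint at a decayed second domain
            if structure.n_exons > 2:
                n_evidence += 1
            # a splice site falling outside the full domain's span
            lo = min([hit.start] + remnant_cys)
            hi = max([hit.end] + remnant_cys)
            outside = [
                s for s in structure.splice_residues() if s < hit.start or s > hit.end
            ]
            if outside:
                evidence["splice"] = True
                n_evidence += 1
        if remnant_cys and n_evidence >= 2:
            side_n = any(p < hit.start for p in remnant_cys)
            boundary = hit.start if side_n else hit.end + 1
            remnant = ScaffoldMatch(tuple(sorted(remnant_cys)))
            ordered = (remnant, hit) if side_n else (hit, remnant)
            return DomainArchitecture(
                gene_id, "vestigial_double", boundary=boundary,
                domain_hits=ordered, evidence=evidence, sequence=sequence,
            )

    return DomainArchitecture(
        gene_id, "single", boundary=None, domain_hits=tuple(full),
        evidence=evidence, sequence=sequence,
    )


def delimit_domains(
    arch: DomainArchitecture,
    dotplot: Optional[DotplotResult] = None,
    structure: Optional[GeneStructure] = None,
    snap_radius: int = 10,
) -> DomainArchitecture:
    """Place the inter-domain boundary of a double-domain gene.

    The primary estimate is the start of the dotplot run's second copy
    (run start + offset).  When the gene structure is known, the boundary
    snaps to the nearest splice-site residue within ``snap_radius`` —
    tandem fusions inherit a splice site at the junction — but only if the
    snapped boundary keeps each cysteine scaffold wholly inside its domain;
    otherwise the dotplot estimate stands.  Raises on interleaved scaffolds
    for which no consistent boundary exists.
    """
    if arch.call not in ("double", "vestigial_double"):
        raise ValueError("boundary delimitation applies to double-domain calls only")
    if arch.sequence is None:
        raise ValueError("architecture carries no sequence")
    n = len(arch.sequence)

    candidates: list[int] = []
    if dotplot is not None and dotplot.has_offdiagonal_run:
        run = dotplot.best_run()
        candidates.append(run.start + run.offset)
    if len(arch.domain_hits) == 2:
        h1, h2 = arch.domain_hits
        if h1.overlaps(h2):
            raise ValueError(
                f"ambiguous boundary: scaffolds interleave "
                f"({h1.cys_positions} vs {h2.cys_positions})"
            )
        # midpoint of the inter-scaffold gap as fallback estimate
        candidates.append((h1.end + h2.start + 1) // 2)
    if arch.boundary is not None:
        candidates.append(arch.boundary)
    if not candidates:
        raise ValueError("ambiguous boundary: no dotplot run and no scaffold pair")

    def consistent(b: int) -> bool:
        if not 2 <= b <= n:
            return False
        if len(arch.domain_hits) == 2:
            h1, h2 = arch.domain_hits
            return h1.end < b and h2.start >= b
        return True

    boundary = next((b for b in candidates if consistent(b)), None)
    if boundary is None:
        raise ValueError(f"ambiguous boundary: no consistent candidate among {candidates}")

    if structure is not None:
        sites = structure.splice_residues()
        near = [s for s in sites if abs(s - boundary) <= snap_radius and consistent(s)]
        if near:
            boundary = min(near, key=lambda s: (abs(s - boundary), s))

    return DomainArchitecture(
        gene_id=arch.gene_id,
        call=arch.call,
        boundary=boundary,
        domain_hits=arch.domain_hits,
        evidence=dict(arch.evidence),
        sequence=arch.sequence,
    )


def split_domains(sequence: str, boundary: int) -> tuple[str, str]:
    """Split a sequence at a 1-based boundary (first residue of domain 2);
    the two parts concatenate back to the input exactly."""
    if not 2 <= boundary <= len(sequence):
        raise ValueError(f"boundary {boundary} outside [2, {len(sequence)}]")
    return sequence[: boundary - 1], sequence[boundary - 1 :]
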