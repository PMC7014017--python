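"""Global pairwise protein alignment and the percent-identity definition.

Family/subfamily assignment in this package rests entirely on pairwise
amino-acid identity to named reference P450s, so the definition of
"percent identity" is spelled out here once and reused everywhere:

    identity = 100 * (identical aligned columns)
                   / (aligned columns after trimming terminal-gap columns)

Internal gap columns count in the denominator; terminal overhangs (leading or
trailing columns where one sequence has run out) do not.  For near-full-length
homologs this approximates the identity a local aligner would report, while
keeping the alignment itself global and deterministic.  An alternative
denominator (length of the shorter sequence) is available via
``denominator="shorter_sequence"``.

Alignment is Needleman-Wunsch-style global dynamic programming
(``Bio.Align.PairwiseAligner``) under a configurable scoring scheme,
BLOSUM62 with gap open 10 / extend 1 by default.  A gap of length L costs
``open + (L-1) * extend``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "AlignmentError",
    "global_align",
    "percent_identity",
    "best_hits",
]

# 20 standard residues plus X (unknown). B/Z/* are rejected: the pipeline's
# inputs are predicted proteomes, where anything else signals a broken record.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class AlignmentError(ValueError):
    """Raised for invalid sequences or degenerate alignments."""


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix and affine gap penalties (penalties are positive)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")

    def substitution_matrix(self):
        return substitution_matrices.load(self.matrix_name)


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_percent: float


def _check_sequence(seq: str, which: str) -> None:
    if not seq:
        raise AlignmentError(f"{which} sequence is empty")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise AlignmentError(
            f"{which} sequence contains non-residue characters: {sorted(bad)}"
        )


def _make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = scheme.substitution_matrix()
    aligner.open_gap_score = -scheme.gap_open
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def percent_identity(
    aligned_a: str,
    aligned_b: str,
    denominator: str = "trimmed_columns",
) -> float:
    """Percent identity of two equal-length gapped strings.

    ``denominator="trimmed_columns"`` (default) trims terminal-gap columns and
    counts internal gap columns as mismatches; ``"shorter_sequence"`` divides
    by the ungapped length of the shorter input instead.
    """
    if len(aligned_a) != len(aligned_b):
        raise AlignmentError("aligned strings differ in length")
    cols = [
        (x, y)
        for x, y in zip(aligned_a, aligned_b)
    ]
    # terminal trim: first/last column where both rows hold a residue
    first = next((i for i, (x, y) in enumerate(cols) if x != "-" and y != "-"), None)
    if first is None:
        raise AlignmentError("alignment has no column with residues in both rows")
    last = max(i for i, (x, y) in enumerate(cols) if x != "-" and y != "-")
    window = cols[first : last + 1]
    matches = sum(1 for x, y in window if x == y and x != "-")
    if denominator == "trimmed_columns":
        denom = len(window)
    elif denominator == "shorter_sequence":
        denom = min(
            sum(1 for x in aligned_a if x != "-"),
            sum(1 for y in aligned_b if y != "-"),
        )
    else:
        raise ValueError(f"unknown identity denominator {denominator!r}")
    if denom == 0:
        raise AlignmentError("zero-length alignment after trimming")
    return 100.0 * matches / denom


def global_align(
    a: str,
    b: str,
    scheme: ScoringScheme | None = None,
    denominator: str = "trimmed_columns",
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Deterministic and symmetric: among co-optimal alignments the first
    traceback for the lexicographically ordered input pair is used (rows
    swapped back afterwards), so identity(a, b) == identity(b, a) even when
    co-optimal alignments disagree on it.
    """
    scheme = scheme or ScoringScheme()
    _check_sequence(a, "first")
    _check_sequence(b, "second")
    aligner = _make_aligner(scheme)
    swap = a > b
    aln = aligner.align(b, a)[0] if swap else aligner.align(a, b)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])
    if swap:
        aligned_a, aligned_b = aligned_b, aligned_a
    ident = percent_identity(aligned_a, aligned_b, denominator=denominator)
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(aln.score),
        identity_percent=ident,
    )


def best_hits(
    query: str,
    references: Sequence[Tuple[str, str]],
    scheme: ScoringScheme | None = None,
    denominator: str = "trimmed_columns",
) -> List[Tuple[str, float]]:
    """Rank named reference sequences by identity to ``query``.

    ``references`` is a sequence of ``(name, sequence)`` pairs.  Returns the
    full ``(name, identity_percent)`` list sorted by descending identity,
    ties broken by ascending name.  The classifier consumes rank 1.
    """
    if not references:
        raise AlignmentError("reference set is empty")
    scored = [
        (name, global_align(query, seq, scheme, denominator).identity_percent)
        for name, seq in references
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored
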