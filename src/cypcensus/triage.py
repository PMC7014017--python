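"""Partition candidate proteins into full-length P450s, fragments and decoys.

Upstream domain-detection tools hand over a mixed bag: intact P450s, truncated
gene models, and proteins that merely resemble the superfamily.  Only
full-length sequences should reach identity-based classification, so this
module applies two cheap, reproducible rules:

* heme-binding motif: the P450 signature around the axial cysteine,
  F-x-x-G-x-x-x-C-x-G by default.  A candidate without it is a false positive.
* length: a candidate carrying the motif but shorter than ``min_full_length``
  (default 300 aa; typical bacterial P450s run ~400 aa) is a fragment.

These rules are this package's own convention, not a community standard; both
are parameters so users can tighten or loosen them.  An optional second check
for the conserved E-x-x-R motif of the K-helix can be switched on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

__all__ = [
    "CandidateRecord",
    "TriageParams",
    "TriageResult",
    "TriageError",
    "triage_candidate",
    "triage_proteome",
]

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class TriageError(ValueError):
    pass


@dataclass(frozen=True)
class CandidateRecord:
    """One candidate protein from a species proteome."""

    protein_id: str
    species_id: str
    sequence: str
    locus_ref: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise TriageError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise TriageError(
                f"{self.protein_id}: non-residue characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class TriageParams:
    min_full_length: int = 300
    heme_motif: str = r"F..G...C.G"
    require_exxr: bool = False
    exxr_motif: str = r"E..R"


@dataclass(frozen=True)
class TriageResult:
    category: str  # full_length | fragment | false_positive
    reasons: Tuple[str, ...]


def triage_candidate(record: CandidateRecord, params: TriageParams | None = None) -> TriageResult:
    """Categorize one candidate from its sequence alone.

    Decision table: motif absent -> false_positive; motif present but short
    -> fragment; otherwise full_length.  ``reasons`` lists every rule that
    fired, for the audit trail written alongside the partition.
    """
    params = params or TriageParams()
    reasons: List[str] = []
    has_heme = re.search(params.heme_motif, record.sequence) is not None
    has_exxr = (
        re.search(params.exxr_motif, record.sequence) is not None
        if params.require_exxr
        else True
    )
    short = len(record.sequence) < params.min_full_length
    if not has_heme:
        reasons.append("heme_motif_absent")
    if params.require_exxr and not has_exxr:
        reasons.append("exxr_motif_absent")
    if short:
        reasons.append(f"length_below_{params.min_full_length}")

    if not has_heme or not has_exxr:
        category = "false_positive"
    elif short:
        category = "fragment"
    else:
        category = "full_length"
        reasons = ["heme_motif_present", f"length_ge_{params.min_full_length}"]
    return TriageResult(category=category, reasons=tuple(reasons))


def triage_proteome(
    records: Iterable[CandidateRecord],
    params: TriageParams | None = None,
) -> Tuple[List[CandidateRecord], List[CandidateRecord], List[CandidateRecord], Dict[str, int]]:
    """Partition a proteome; returns (full_length, fragments, false_positives, counts).

    The three lists are disjoint and their sizes sum to the input size.
    Duplicate protein ids are an input error (the census counts proteins).
    """
    params = params or TriageParams()
    seen: set = set()
    full: List[CandidateRecord] = []
    frag: List[CandidateRecord] = []
    decoy: List[CandidateRecord] = []
    for rec in records:
        key = (rec.species_id, rec.protein_id)
        if key in seen:
            raise TriageError(f"duplicate protein id {rec.protein_id!r} in {rec.species_id!r}")
        seen.add(key)
        cat = triage_candidate(rec, params).category
        {"full_length": full, "fragment": frag, "false_positive": decoy}[cat].append(rec)
    counts = {
        "full_length": len(full),
        "fragment": len(frag),
        "false_positive": len(decoy),
    }
    return full, frag, decoy, counts
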