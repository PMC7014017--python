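"""Identity-threshold family/subfamily assignment against a named reference set.

The International P450 Nomenclature Committee convention is operational:
a sequence with more than 55% amino-acid identity to a named P450 belongs to
that P450's subfamily; more than 40% (but not more than 55%) to its family;
at or below 40% it founds a new family.  Both thresholds are compared with
strict ``>`` — a query at exactly 55.0% falls to the family level, one at
exactly 40.0% to a new family.  An inclusive mode is available for users who
read the rule the other way.

Queries that land in the 40-55 band, or below 40, cannot be given official
names by software (new numbers are committee-assigned), so they receive
provisional labels from :class:`cypcensus.nomenclature.ProvisionalRegistry`.
Identical query sequences always receive the same label.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO

from .nomenclature import P450Name, P450NameError, ProvisionalRegistry, parse_p450_name
from .pairwise_identity import AlignmentError, ScoringScheme, best_hits
from .triage import CandidateRecord

__all__ = [
    "ReferenceDB",
    "Thresholds",
    "AssignmentResult",
    "ClassificationError",
    "assign",
    "classify_proteome",
]


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class Thresholds:
    """Family / subfamily identity cutoffs in percent."""

    family: float = 40.0
    subfamily: float = 55.0
    inclusive: bool = False  # if True, boundary values promote instead of demote

    def __post_init__(self) -> None:
        if not self.family < self.subfamily:
            raise ValueError("family threshold must be below subfamily threshold")

    def above(self, identity: float, cutoff: float) -> bool:
        return identity >= cutoff if self.inclusive else identity > cutoff


class ReferenceDB:
    """Named P450 sequences the classifier measures identity against."""

    def __init__(self, entries: Sequence[Tuple[P450Name, str]]):
        if not entries:
            raise ClassificationError("reference database is empty")
        seen: set = set()
        for name, seq in entries:
            if name.raw_label in seen:
                raise ClassificationError(f"duplicate reference name {name.raw_label!r}")
            if not seq:
                raise ClassificationError(f"reference {name.raw_label!r} has empty sequence")
            seen.add(name.raw_label)
        self.entries: List[Tuple[P450Name, str]] = list(entries)
        self._by_label: Dict[str, Tuple[P450Name, str]] = {
            n.raw_label: (n, s) for n, s in entries
        }

    def __len__(self) -> int:
        return len(self.entries)

    def name(self, label: str) -> P450Name:
        return self._by_label[label][0]

    def as_pairs(self) -> List[Tuple[str, str]]:
        return [(n.raw_label, s) for n, s in self.entries]

    @classmethod
    def from_fasta(cls, path) -> "ReferenceDB":
        """Load references from FASTA; the first header token is the CYP label."""
        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            label = rec.id.split()[0]
            try:
                name = parse_p450_name(label)
            except P450NameError as exc:
                raise ClassificationError(f"bad reference header {label!r}: {exc}") from exc
            entries.append((name, str(rec.seq).upper()))
        return cls(entries)


@dataclass(frozen=True)
class AssignmentResult:
    protein_id: str
    species_id: str
    best_hit_name: str
    identity_percent: float
    status: str  # known_subfamily | new_subfamily_in_family | new_family
    assigned_family: str
    assigned_subfamily: str


def _status_for(identity: float, thresholds: Thresholds) -> str:
    if thresholds.above(identity, thresholds.subfamily):
        return "known_subfamily"
    if thresholds.above(identity, thresholds.family):
        return "new_subfamily_in_family"
    return "new_family"


def _seq_digest(seq: str) -> str:
    return hashlib.sha256(seq.encode()).hexdigest()


def assign(
    query: CandidateRecord,
    refdb: ReferenceDB,
    thresholds: Thresholds | None = None,
    scheme: ScoringScheme | None = None,
    registry: ProvisionalRegistry | None = None,
    _label_cache: Optional[Dict[Tuple[str, str], str]] = None,
) -> AssignmentResult:
    """Assign one full-length candidate a family and subfamily.

    Only the single best hit (rank 1 of :func:`best_hits`, ties broken
    alphabetically) is consulted.  ``registry`` and ``_label_cache`` let
    :func:`classify_proteome` keep provisional labels consistent across a run;
    called standalone, fresh ones are created.
    """
    thresholds = thresholds or Thresholds()
    registry = registry if registry is not None else ProvisionalRegistry()
    cache = _label_cache if _label_cache is not None else {}
    try:
        ranked = best_hits(query.sequence, refdb.as_pairs(), scheme)
    except AlignmentError as exc:
        raise ClassificationError(f"{query.protein_id}: {exc}") from exc
    hit_label, identity = ranked[0]
    hit_name = refdb.name(hit_label)
    status = _status_for(identity, thresholds)
    digest = _seq_digest(query.sequence)

    if status == "known_subfamily":
        family = hit_name.family_token
        subfamily = hit_name.subfamily_token
        if subfamily is None:
            # best hit is an old-style label without subfamily letters
            subfamily = _cached_provisional(cache, registry, ("sub", family, digest), family)
    elif status == "new_subfamily_in_family":
        family = hit_name.family_token
        subfamily = _cached_provisional(cache, registry, ("sub", family, digest), family)
    else:
        family = _cached_provisional(cache, registry, ("fam", "", digest), None)
        subfamily = f"{family}_NS1"
    return AssignmentResult(
        protein_id=query.protein_id,
        species_id=query.species_id,
        best_hit_name=hit_label,
        identity_percent=identity,
        status=status,
        assigned_family=family,
        assigned_subfamily=subfamily,
    )


def _cached_provisional(cache, registry, key, family) -> str:
    if key not in cache:
        if key[0] == "sub":
            cache[key] = registry.allocate("new_subfamily", family=family).label
        else:
            cache[key] = registry.allocate("new_family").label
    return cache[key]


def classify_proteome(
    records: Iterable[CandidateRecord],
    refdb: ReferenceDB,
    thresholds: Thresholds | None = None,
    scheme: ScoringScheme | None = None,
) -> List[AssignmentResult]:
    """Classify every record, in sorted (species_id, protein_id) order.

    The fixed processing order makes provisional ordinals reproducible
    run-to-run for the same input set.
    """
    thresholds = thresholds or Thresholds()
    registry = ProvisionalRegistry()
    cache: Dict = {}
    ordered = sorted(records, key=lambda r: (r.species_id, r.protein_id))
    results: List[AssignmentResult] = []
    for rec in ordered:
        try:
            results.append(
                assign(rec, refdb, thresholds, scheme, registry, cache)
            )
        except ClassificationError:
            raise
        except Exception as exc:  # pragma: no cover - defensive context wrap
            raise ClassificationError(f"{rec.protein_id}: {exc}") from exc
    return results
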