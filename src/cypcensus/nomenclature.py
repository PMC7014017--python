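"""CYP nomenclature labels: parsing, rendering and provisional identifiers.

A cytochrome P450 label such as ``CYP110C17`` encodes a family number (110),
a run of subfamily letters (``C``, or two letters such as ``AH``) and a
protein number (17).  Family membership is defined operationally by amino-acid
identity thresholds (see :mod:`cypcensus.classify`); this module only deals
with the labels themselves.

Official family and subfamily numbers are assigned by the International P450
Nomenclature Committee.  Sequences that fall below the family threshold are
genuinely novel and cannot be given an official name by software, so this
module also hands out *provisional* identifiers (``CYP_NF3``,
``CYP110_NS1``) whose reserved ``_NF``/``_NS`` infix can never collide with a
well-formed CYP label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Optional

__all__ = [
    "P450Name",
    "P450NameError",
    "ProvisionalId",
    "ProvisionalRegistry",
    "parse_p450_name",
    "family_token",
    "subfamily_token",
]


class P450NameError(ValueError):
    """Raised for labels that do not follow CYP nomenclature."""


# Family digits are consumed greedily, so "CYP1011G1" is family 1011 (not 101).
# A consequence worth knowing: a label without subfamily letters cannot carry a
# protein number ("CYP111" is family 111, never family 11 protein 1) — which
# mirrors real usage, where protein numbers always follow subfamily letters.
# Subfamily runs are capped at two letters: every published cyanobacterial
# label uses one or two (e.g. "C", "AH"); longer runs are rejected loudly
# rather than guessed at.
_LABEL_RE = re.compile(r"^CYP(?P<family>\d+)(?P<letters>[A-Z]{0,2})(?P<protein>\d+)?$")


@dataclass(frozen=True)
class P450Name:
    """A parsed CYP label."""

    raw_label: str
    family_number: int
    subfamily_letters: str = ""
    protein_number: Optional[int] = None

    def __post_init__(self) -> None:
        if self.family_number <= 0:
            raise P450NameError(f"family number must be positive: {self.raw_label!r}")
        if self.protein_number is not None and self.protein_number <= 0:
            raise P450NameError(f"protein number must be positive: {self.raw_label!r}")
        if not re.fullmatch(r"[A-Z]{0,2}", self.subfamily_letters):
            raise P450NameError(
                f"subfamily letters must be 0-2 uppercase A-Z: {self.raw_label!r}"
            )

    def render(self) -> str:
        """Reassemble the canonical label from the parsed components."""
        out = f"CYP{self.family_number}{self.subfamily_letters}"
        if self.protein_number is not None:
            out += str(self.protein_number)
        return out

    @property
    def family_token(self) -> str:
        return f"CYP{self.family_number}"

    @property
    def subfamily_token(self) -> Optional[str]:
        if not self.subfamily_letters:
            return None
        return self.family_token + self.subfamily_letters


def parse_p450_name(label: str) -> P450Name:
    """Parse a CYP label into family number, subfamily letters, protein number.

    >>> parse_p450_name("CYP110C17")
    P450Name(raw_label='CYP110C17', family_number=110, subfamily_letters='C', protein_number=17)

    Raises :class:`P450NameError` for anything without a ``CYP`` prefix, a
    family number, or with more than two subfamily letters.
    """
    if not label:
        raise P450NameError("empty P450 label")
    m = _LABEL_RE.match(label)
    if m is None:
        raise P450NameError(f"malformed P450 label: {label!r}")
    protein = m.group("protein")
    return P450Name(
        raw_label=label,
        family_number=int(m.group("family")),
        subfamily_letters=m.group("letters"),
        protein_number=int(protein) if protein is not None else None,
    )


def family_token(name: P450Name) -> str:
    """``CYP110``-style family token."""
    return name.family_token


def subfamily_token(name: P450Name) -> str:
    """``CYP110C``-style subfamily token; error if the label has no letters."""
    tok = name.subfamily_token
    if tok is None:
        raise P450NameError(f"label {name.raw_label!r} carries no subfamily letters")
    return tok


def subfamily_letter_ordinal(letters: str) -> int:
    """Spreadsheet-column order for subfamily letter runs: A..Z, AA..AZ, BA..

    The committee's ordering of two-letter runs is not published; this is the
    obvious base-26 extension and is only used for stable sorting, never for
    assigning letters.
    """
    n = 0
    for ch in letters:
        if not "A" <= ch <= "Z":
            raise P450NameError(f"invalid subfamily letters {letters!r}")
        n = n * 26 + (ord(ch) - ord("A") + 1)
    return n


@dataclass(frozen=True)
class ProvisionalId:
    """A provisional identifier for a novel family or subfamily."""

    kind: Literal["new_family", "new_subfamily"]
    ordinal: int
    label: str


@dataclass
class ProvisionalRegistry:
    """Tracks issued provisional ordinals so labels are unique within a run.

    New families are numbered globally (``CYP_NF1``, ``CYP_NF2`` ...); new
    subfamilies are numbered per family (``CYP110_NS1``, ``CYP213_NS1``).
    """

    _counters: dict = field(default_factory=dict)

    def allocate(self, kind: str, family: Optional[str] = None) -> ProvisionalId:
        if kind == "new_family":
            scope = "__families__"
            prefix = "CYP_NF"
        elif kind == "new_subfamily":
            if not family:
                raise ValueError("new_subfamily allocation needs a family token")
            scope = family
            prefix = f"{family}_NS"
        else:
            raise ValueError(f"unknown provisional kind {kind!r}")
        ordinal = self._counters.get(scope, 0) + 1
        self._counters[scope] = ordinal
        return ProvisionalId(kind=kind, ordinal=ordinal, label=f"{prefix}{ordinal}")
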