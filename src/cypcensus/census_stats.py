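"""Census tables and comparative diversity statistics.

The census is a species-by-family count matrix built from classifier
assignments.  On top of it sit the comparative statistics used to contrast
bacterial groups:

* P450 diversity percentage        = 100 * F / (P * S)
* gene-cluster diversity percentage = 100 * T / (C * S)

with F families, P P450s, T BGC types, C BGCs and S species analyzed.
Dividing by the number of species normalizes away cohort size, so the
percentages are comparable between groups sequenced to very different depths.
Diversity percentages are reported half-up to two decimals; averages and
shares half-up to the nearest integer — the conventions the comparative
tables in this field print.

``S`` is the *total* number of species analyzed, including species whose
genomes yielded no clusters; ``species_with_results`` is accepted as an
alternative convention but changes the numbers (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .classify import AssignmentResult

__all__ = [
    "CensusTable",
    "DiversitySummary",
    "build_census",
    "dominant_families",
    "conserved_families",
    "p450_diversity_percentage",
    "gene_cluster_diversity_percentage",
    "averages_and_shares",
    "summary_table",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CensusTable:
    """Species x family (and optionally x subfamily) integer count matrices.

    ``family`` columns are ordered by descending total count, ties by name.
    """

    family: pd.DataFrame
    subfamily: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if (self.family.values < 0).any():
            raise ValueError("census counts must be non-negative")

    @property
    def n_species(self) -> int:
        return self.family.shape[0]

    @property
    def n_families(self) -> int:
        return int((self.family.sum(axis=0) > 0).sum())

    @property
    def n_subfamilies(self) -> int:
        if self.subfamily is None:
            return 0
        return int((self.subfamily.sum(axis=0) > 0).sum())

    @property
    def total_p450s(self) -> int:
        return int(self.family.values.sum())

    def to_tsv(self, path) -> None:
        self.family.to_csv(path, sep="\t", index_label="species_id")


def _ordered_pivot(rows: List[Tuple[str, str]]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["species_id", "group"])
    pivot = (
        df.assign(n=1)
        .pivot_table(index="species_id", columns="group", values="n", aggfunc="sum", fill_value=0)
        .astype(int)
    )
    order = sorted(pivot.columns, key=lambda c: (-pivot[c].sum(), c))
    pivot = pivot[order]
    pivot.index.name = "species_id"
    pivot.columns.name = None
    return pivot.sort_index()


def build_census(assignments: Iterable[AssignmentResult]) -> CensusTable:
    """Aggregate assignments into per-species family and subfamily counts."""
    assignments = list(assignments)
    if not assignments:
        empty = pd.DataFrame(dtype=int)
        empty.index.name = "species_id"
        return CensusTable(family=empty, subfamily=empty.copy())
    fam = _ordered_pivot([(a.species_id, a.assigned_family) for a in assignments])
    sub = _ordered_pivot([(a.species_id, a.assigned_subfamily) for a in assignments])
    return CensusTable(family=fam, subfamily=sub)


def dominant_families(census: CensusTable, k: int = 5) -> List[Tuple[str, int]]:
    """Top-k families by total member count ("blooming" ranking)."""
    totals = census.family.sum(axis=0)
    ranked = sorted(totals.items(), key=lambda t: (-t[1], t[0]))
    return [(name, int(n)) for name, n in ranked[:k]]


def conserved_families(census: CensusTable) -> List[str]:
    """Families present (count > 0) in every species of the census."""
    if census.family.empty:
        return []
    mask = (census.family > 0).all(axis=0)
    return sorted(census.family.columns[mask])


def p450_diversity_percentage(n_families: int, n_p450s: int, n_species: int) -> float:
    """100 * families / (P450s * species), half-up to 2 decimals."""
    if n_p450s <= 0 or n_species <= 0:
        raise ValueError("P450 and species counts must be positive")
    return round_half_up(100.0 * n_families / (n_p450s * n_species), 2)


def gene_cluster_diversity_percentage(n_types: int, n_clusters: int, n_species: int) -> float:
    """100 * cluster types / (clusters * species), half-up to 2 decimals."""
    if n_clusters <= 0 or n_species <= 0:
        raise ValueError("cluster and species counts must be positive")
    return round_half_up(100.0 * n_types / (n_clusters * n_species), 2)


def averages_and_shares(
    n_p450s: int, n_species: int, n_bgcs: int, n_in_bgcs: int
) -> Tuple[int, int, int]:
    """(average P450s per species, average BGCs per species, % of P450s in BGCs).

    All three are half-up integers, the convention of the comparative tables.
    """
    if n_species <= 0:
        raise ValueError("species count must be positive")
    if n_in_bgcs > n_p450s:
        raise ValueError("P450s inside BGCs cannot exceed total P450s")
    avg_p450 = int(round_half_up(n_p450s / n_species))
    avg_bgc = int(round_half_up(n_bgcs / n_species))
    pct_in = int(round_half_up(100.0 * n_in_bgcs / n_p450s)) if n_p450s else 0
    return avg_p450, avg_bgc, pct_in


@dataclass
class DiversitySummary:
    """All comparative key-feature statistics for one taxon.

    Count fields are inputs; derived fields are computed by
    :meth:`from_counts` via the formulas above, never stored independently.
    """

    taxon: str
    species_analyzed: int
    p450s: int
    families: int
    subfamilies: int
    bgcs: int
    bgc_types: int
    p450s_in_bgcs: int
    dominant_family: str = ""
    avg_p450: int = 0
    avg_bgc: int = 0
    p450_diversity_pct: float = 0.0
    cluster_diversity_pct: float = 0.0
    pct_p450s_in_bgcs: int = 0

    @classmethod
    def from_counts(
        cls,
        taxon: str,
        species_analyzed: int,
        p450s: int,
        families: int,
        subfamilies: int,
        bgcs: int,
        bgc_types: int,
        p450s_in_bgcs: int,
        dominant_family: str = "",
    ) -> "DiversitySummary":
        avg_p450, avg_bgc, pct_in = averages_and_shares(
            p450s, species_analyzed, bgcs, p450s_in_bgcs
        )
        return cls(
            taxon=taxon,
            species_analyzed=species_analyzed,
            p450s=p450s,
            families=families,
            subfamilies=subfamilies,
            bgcs=bgcs,
            bgc_types=bgc_types,
            p450s_in_bgcs=p450s_in_bgcs,
            dominant_family=dominant_family,
            avg_p450=avg_p450,
            avg_bgc=avg_bgc,
            p450_diversity_pct=p450_diversity_percentage(families, p450s, species_analyzed),
            cluster_diversity_pct=gene_cluster_diversity_percentage(
                bgc_types, bgcs, species_analyzed
            ),
            pct_p450s_in_bgcs=pct_in,
        )

    def as_dict(self) -> Dict:
        return {
            "taxon": self.taxon,
            "species_analyzed": self.species_analyzed,
            "p450s": self.p450s,
            "families": self.families,
            "subfamilies": self.subfamilies,
            "dominant_family": self.dominant_family,
            "bgcs": self.bgcs,
            "bgc_types": self.bgc_types,
            "p450s_in_bgcs": self.p450s_in_bgcs,
            "avg_p450": self.avg_p450,
            "p450_diversity_pct": self.p450_diversity_pct,
            "avg_bgc": self.avg_bgc,
            "cluster_diversity_pct": self.cluster_diversity_pct,
            "pct_p450s_in_bgcs": self.pct_p450s_in_bgcs,
        }


_ROW_ORDER = [
    "species_analyzed",
    "p450s",
    "families",
    "subfamilies",
    "dominant_family",
    "bgcs",
    "bgc_types",
    "p450s_in_bgcs",
    "avg_p450",
    "p450_diversity_pct",
    "avg_bgc",
    "cluster_diversity_pct",
    "pct_p450s_in_bgcs",
]


def summary_table(summaries: Sequence[DiversitySummary]) -> pd.DataFrame:
    """Feature-by-taxon comparative table (one column per taxon)."""
    if not summaries:
        raise ValueError("no summaries given")
    cols = {s.taxon: [s.as_dict()[row] for row in _ROW_ORDER] for s in summaries}
    return pd.DataFrame(cols, index=_ROW_ORDER)
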