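"""Cross-referencing P450 gene loci with secondary-metabolite BGC intervals.

Cluster-detection tools (antiSMASH-style) report, per genome, a set of
intervals with a type string (possibly a hybrid such as ``"NRPS, T1PKS"``),
and optionally the most similar known cluster with a percent similarity.
This module loads those tables plus gene coordinate tables, intersects P450
gene loci with cluster intervals, and produces the membership list, per-type
tallies, per-family breakdowns and the final report table.

Conventions
-----------
* All coordinates are 1-based inclusive (GenBank/GFF3 convention);
  :func:`from_zero_based_half_open` converts BED-style inputs.
* A gene belongs to a cluster when their intervals overlap by at least one
  base on the same species and contig, strand ignored.  A stricter
  "gene fully contained in cluster" rule is available via ``rule``.
* Hybrid type strings are canonicalized by joining the components with
  ", " in their input order (the order the detection tool printed), and each
  distinct canonical string counts as its own cluster type.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GeneLocus",
    "BGCluster",
    "MembershipRecord",
    "BGCParseError",
    "load_gene_loci",
    "load_gene_loci_gff3",
    "load_bgc_table",
    "from_zero_based_half_open",
    "p450s_in_clusters",
    "tally_cluster_types",
    "tally_type_strings",
    "bgc_family_breakdown",
    "similarity_report",
]


class BGCParseError(ValueError):
    pass


@dataclass(frozen=True)
class GeneLocus:
    species_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    protein_id: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise BGCParseError(
                f"locus {self.protein_id}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise BGCParseError(f"locus {self.protein_id}: unknown strand {self.strand!r}")


@dataclass(frozen=True)
class BGCluster:
    cluster_id: str
    species_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    type_components: Tuple[str, ...]
    most_similar_known: Optional[str] = None
    similarity_percent: Optional[float] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise BGCParseError(
                f"cluster {self.cluster_id}: invalid coordinates {self.start}..{self.end}"
            )
        if not self.type_components:
            raise BGCParseError(f"cluster {self.cluster_id}: empty type string")
        if self.similarity_percent is not None and not (
            0 <= self.similarity_percent <= 100
        ):
            raise BGCParseError(
                f"cluster {self.cluster_id}: similarity {self.similarity_percent} outside 0-100"
            )

    @property
    def type_string(self) -> str:
        return ", ".join(self.type_components)


@dataclass(frozen=True)
class MembershipRecord:
    protein_id: str
    species_id: str
    cluster_id: str
    p450_family: str
    overlap_bases: int

    def __post_init__(self) -> None:
        if self.overlap_bases < 1:
            raise BGCParseError("membership requires >= 1 base of overlap")


def from_zero_based_half_open(start: int, end: int) -> Tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    if end <= start:
        raise BGCParseError(f"empty half-open interval [{start}, {end})")
    return start + 1, end


def _split_types(raw: str) -> Tuple[str, ...]:
    return tuple(t.strip() for t in raw.split(",") if t.strip())


def load_gene_loci(path) -> List[GeneLocus]:
    """Load gene loci from a TSV with header
    ``species_id contig start end strand protein_id``."""
    loci: List[GeneLocus] = []
    seen: set = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"species_id", "contig", "start", "end", "strand", "protein_id"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise BGCParseError(f"{path}: missing columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                locus = GeneLocus(
                    species_id=row["species_id"],
                    contig=row["contig"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    protein_id=row["protein_id"],
                )
            except (BGCParseError, ValueError) as exc:
                raise BGCParseError(f"{path}:{lineno}: {exc}") from exc
            key = (locus.species_id, locus.protein_id)
            if key in seen:
                raise BGCParseError(
                    f"{path}:{lineno}: duplicate protein id {locus.protein_id!r}"
                )
            seen.add(key)
            loci.append(locus)
    return loci


def load_gene_loci_gff3(path, species_id: str, feature_types=("gene", "CDS")) -> List[GeneLocus]:
    """Load gene loci from GFF3; the feature ``ID`` attribute is the protein id."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    loci: List[GeneLocus] = []
    seen: set = set()
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            pid = feat.attributes.get("protein_id", feat.attributes.get("ID", [feat.id]))[0]
            if pid in seen:
                continue
            seen.add(pid)
            loci.append(
                GeneLocus(
                    species_id=species_id,
                    contig=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand if feat.strand in "+-" else "+",
                    protein_id=pid,
                )
            )
    return sorted(loci, key=lambda l: (l.contig, l.start, l.protein_id))


def load_bgc_table(path) -> List[BGCluster]:
    """Load clusters from a TSV with header ``cluster_id species_id contig
    start end type most_similar_known similarity_percent`` (last two optional
    per row)."""
    clusters: List[BGCluster] = []
    seen: set = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"cluster_id", "species_id", "contig", "start", "end", "type"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise BGCParseError(f"{path}: missing columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            sim_raw = (row.get("similarity_percent") or "").strip()
            known = (row.get("most_similar_known") or "").strip()
            try:
                cluster = BGCluster(
                    cluster_id=row["cluster_id"],
                    species_id=row["species_id"],
                    contig=row["contig"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    type_components=_split_types(row["type"]),
                    most_similar_known=known or None,
                    similarity_percent=float(sim_raw) if sim_raw else None,
                )
            except (BGCParseError, ValueError) as exc:
                raise BGCParseError(f"{path}:{lineno}: {exc}") from exc
            if cluster.cluster_id in seen:
                raise BGCParseError(
                    f"{path}:{lineno}: duplicate cluster id {cluster.cluster_id!r}"
                )
            seen.add(cluster.cluster_id)
            clusters.append(cluster)
    return clusters


def p450s_in_clusters(
    loci: Sequence[GeneLocus],
    clusters: Sequence[BGCluster],
    assignments: Optional[Dict[str, str]] = None,
    rule: str = "overlap",
) -> List[MembershipRecord]:
    """Intersect P450 gene loci with cluster intervals.

    ``assignments`` maps protein_id -> family token; when given, only those
    proteins are considered (they are the classified P450s) and the family is
    carried onto the membership record.  ``rule`` is ``"overlap"`` (>= 1 base)
    or ``"contained"`` (gene fully inside the cluster).
    """
    if rule not in {"overlap", "contained"}:
        raise ValueError(f"unknown overlap rule {rule!r}")
    trees: Dict[Tuple[str, str], IntervalTree] = {}
    by_interval: Dict[Tuple[str, str, int, int], BGCluster] = {}
    for cl in clusters:
        key = (cl.species_id, cl.contig)
        trees.setdefault(key, IntervalTree()).addi(cl.start, cl.end + 1, cl.cluster_id)
        by_interval[(cl.species_id, cl.contig, cl.start, cl.end)] = cl
    cluster_by_id = {cl.cluster_id: cl for cl in clusters}

    members: List[MembershipRecord] = []
    for locus in sorted(loci, key=lambda l: (l.species_id, l.protein_id)):
        if assignments is not None and locus.protein_id not in assignments:
            continue
        family = assignments.get(locus.protein_id, "") if assignments else ""
        tree = trees.get((locus.species_id, locus.contig))
        if tree is None:
            continue
        hits = {iv.data for iv in tree.overlap(locus.start, locus.end + 1)}
        for cid in sorted(hits):
            cl = cluster_by_id[cid]
            if rule == "contained" and not (cl.start <= locus.start and locus.end <= cl.end):
                continue
            overlap = min(locus.end, cl.end) - max(locus.start, cl.start) + 1
            if overlap >= 1:
                members.append(
                    MembershipRecord(
                        protein_id=locus.protein_id,
                        species_id=locus.species_id,
                        cluster_id=cid,
                        p450_family=family,
                        overlap_bases=overlap,
                    )
                )
    return members


def tally_type_strings(type_strings: Iterable[str]) -> Counter:
    """Count canonical type strings; hybrids count as their own type."""
    return Counter(type_strings)


def tally_cluster_types(clusters: Sequence[BGCluster]) -> Counter:
    return tally_type_strings(cl.type_string for cl in clusters)


def bgc_family_breakdown(
    memberships: Sequence[MembershipRecord] | Sequence[str],
) -> pd.DataFrame:
    """Per-family membership counts and integer-rounded percentage shares.

    Accepts membership records or bare family tokens.  Shares are
    100 * count / total rounded half-up; ranked by descending count, then name.
    """
    from .census_stats import round_half_up

    families = [
        m.p450_family if isinstance(m, MembershipRecord) else m for m in memberships
    ]
    counts = Counter(families)
    total = sum(counts.values())
    rows = [
        {
            "family": fam,
            "count": n,
            "share_percent": int(round_half_up(100.0 * n / total)) if total else 0,
        }
        for fam, n in sorted(counts.items(), key=lambda t: (-t[1], t[0]))
    ]
    return pd.DataFrame(rows, columns=["family", "count", "share_percent"])


def similarity_report(
    clusters: Sequence[BGCluster],
    memberships: Sequence[MembershipRecord],
    display_names: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """One row per membership: P450 name, cluster type string, most similar
    known cluster and its similarity (blank where the detector reported none).
    """
    cluster_by_id = {cl.cluster_id: cl for cl in clusters}
    rows = []
    for m in memberships:
        if m.cluster_id not in cluster_by_id:
            raise BGCParseError(
                f"membership {m.protein_id} references unknown cluster {m.cluster_id!r}"
            )
        cl = cluster_by_id[m.cluster_id]
        name = display_names.get(m.protein_id, m.protein_id) if display_names else m.protein_id
        rows.append(
            {
                "p450_name": name,
                "cluster_types": cl.type_string,
                "most_similar_known": cl.most_similar_known or "",
                "similarity_percent": (
                    "" if cl.similarity_percent is None else f"{cl.similarity_percent:g}"
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["p450_name", "cluster_types", "most_similar_known", "similarity_percent"]
    )
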