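"""Small, deterministic writers/readers for the pipeline's file formats."""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .triage import CandidateRecord

__all__ = [
    "write_fasta",
    "read_proteome_fasta",
    "write_loci_tsv",
    "write_clusters_tsv",
    "write_assignments_tsv",
    "read_assignments_tsv",
    "write_triage_tsv",
]


def write_fasta(path, entries: Sequence[Tuple[str, str]]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries]
    SeqIO.write(records, str(path), "fasta")


def read_proteome_fasta(path, species_id: str | None = None) -> List[CandidateRecord]:
    """Read candidates from FASTA.

    Headers may carry the species as ``species|protein_id``; otherwise
    ``species_id`` must be given and the whole first token is the protein id.
    """
    records: List[CandidateRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        token = rec.id.split()[0]
        if "|" in token:
            sp, pid = token.split("|", 1)
        elif species_id is not None:
            sp, pid = species_id, token
        else:
            raise ValueError(
                f"header {token!r} has no species; pass species_id or use 'species|protein' headers"
            )
        records.append(CandidateRecord(pid, sp, str(rec.seq).upper()))
    return records


def write_loci_tsv(path, loci) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["species_id", "contig", "start", "end", "strand", "protein_id"])
        for l in loci:
            w.writerow([l.species_id, l.contig, l.start, l.end, l.strand, l.protein_id])


def write_clusters_tsv(path, clusters) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            [
                "cluster_id",
                "species_id",
                "contig",
                "start",
                "end",
                "type",
                "most_similar_known",
                "similarity_percent",
            ]
        )
        for c in clusters:
            w.writerow(
                [
                    c.cluster_id,
                    c.species_id,
                    c.contig,
                    c.start,
                    c.end,
                    c.type_string,
                    c.most_similar_known or "",
                    "" if c.similarity_percent is None else f"{c.similarity_percent:g}",
                ]
            )


def write_triage_tsv(path, categorized) -> None:
    """``categorized``: iterable of (CandidateRecord, category, reasons)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein_id", "species_id", "category", "reasons"])
        for rec, category, reasons in categorized:
            w.writerow([rec.protein_id, rec.species_id, category, ";".join(reasons)])


_ASSIGN_COLS = [
    "protein_id",
    "species_id",
    "best_hit",
    "identity_percent",
    "status",
    "family",
    "subfamily",
]


def write_assignments_tsv(path, assignments) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_ASSIGN_COLS)
        for a in assignments:
            w.writerow(
                [
                    a.protein_id,
                    a.species_id,
                    a.best_hit_name,
                    f"{a.identity_percent:.4f}",
                    a.status,
                    a.assigned_family,
                    a.assigned_subfamily,
                ]
            )


def read_assignments_tsv(path):
    from .classify import AssignmentResult

    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                AssignmentResult(
                    protein_id=row["protein_id"],
                    species_id=row["species_id"],
                    best_hit_name=row["best_hit"],
                    identity_percent=float(row["identity_percent"]),
                    status=row["status"],
                    assigned_family=row["family"],
                    assigned_subfamily=row["subfamily"],
                )
            )
    return out
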