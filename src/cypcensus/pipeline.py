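"""End-to-end orchestration: simulate -> triage -> classify -> census -> BGC -> stats.

Every stage is a pure function from files (or in-memory objects) to files;
the CLI in :mod:`cypcensus.cli` is a thin wrapper over these.  All outputs
are written with fixed orderings and number formats, so identical inputs and
seed give byte-identical output trees (the determinism contract the tests
hash-check).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import io_utils
from .bgc_crossref import (
    bgc_family_breakdown,
    load_bgc_table,
    load_gene_loci,
    p450s_in_clusters,
    similarity_report,
    tally_cluster_types,
)
from .census_stats import CensusTable, DiversitySummary, build_census
from .classify import ReferenceDB, Thresholds, classify_proteome
from .pairwise_identity import ScoringScheme
from .profiles import encode_presence, export_heatmap, hierarchical_cluster
from .triage import TriageParams, triage_candidate, triage_proteome

__all__ = ["RunConfig", "run_simulate", "run_classify", "run_census", "run_bgc", "run_stats", "run_report"]

_CONFIG_VERSION = 1


@dataclasses.dataclass
class RunConfig:
    """Flat, versioned run configuration.

    Unknown keys in a config file are rejected loudly rather than ignored:
    a typo in a threshold name must not silently run with defaults.
    """

    out_dir: str
    seed: int = 0
    proteome: Optional[str] = None
    reference_db: Optional[str] = None
    loci: Optional[str] = None
    clusters: Optional[str] = None
    taxon: str = "synthetic"
    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    family_threshold: float = 40.0
    subfamily_threshold: float = 55.0
    inclusive_thresholds: bool = False
    min_full_length: int = 300
    overlap_rule: str = "overlap"
    config_version: int = _CONFIG_VERSION

    def __post_init__(self) -> None:
        if self.config_version != _CONFIG_VERSION:
            raise ValueError(
                f"unsupported config_version {self.config_version} (expected {_CONFIG_VERSION})"
            )
        if self.overlap_rule not in {"overlap", "contained"}:
            raise ValueError(f"unknown overlap_rule {self.overlap_rule!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**raw)

    def scheme(self) -> ScoringScheme:
        return ScoringScheme(self.matrix_name, self.gap_open, self.gap_extend)

    def thresholds(self) -> Thresholds:
        return Thresholds(
            self.family_threshold, self.subfamily_threshold, self.inclusive_thresholds
        )

    def triage_params(self) -> TriageParams:
        return TriageParams(min_full_length=self.min_full_length)

    def write_copy(self, out_dir: Path) -> None:
        with open(out_dir / "run_config.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _outdir(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.write_copy(out)
    return out


def _require(path: Optional[str], what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"config does not name a {what} file")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} file not found: {p}")
    return p


def run_simulate(config: RunConfig):
    """Generate the default synthetic study into the output directory."""
    from .synthetic_data import default_bundle

    out = _outdir(config)
    bundle = default_bundle(seed=config.seed)
    paths = bundle.write(out)
    return bundle, paths


def run_classify(config: RunConfig) -> Dict[str, int]:
    """Triage the proteome, classify full-length candidates, write TSVs."""
    out = _outdir(config)
    proteome = io_utils.read_proteome_fasta(_require(config.proteome, "proteome"))
    refdb = ReferenceDB.from_fasta(_require(config.reference_db, "reference"))
    params = config.triage_params()
    full, frag, decoy, counts = triage_proteome(proteome, params)
    io_utils.write_triage_tsv(
        out / "triage.tsv",
        [
            (rec, res.category, res.reasons)
            for rec in sorted(proteome, key=lambda r: (r.species_id, r.protein_id))
            for res in [triage_candidate(rec, params)]
        ],
    )
    assignments = classify_proteome(full, refdb, config.thresholds(), config.scheme())
    io_utils.write_assignments_tsv(out / "assignments.tsv", assignments)
    counts["classified"] = len(assignments)
    return counts


def run_census(config: RunConfig) -> CensusTable:
    """Build census tables and the clustered presence/absence heat map."""
    out = _outdir(config)
    assignments = io_utils.read_assignments_tsv(_require(str(Path(config.out_dir) / "assignments.tsv"), "assignments"))
    census = build_census(assignments)
    census.to_tsv(out / "census_family.tsv")
    if census.subfamily is not None:
        census.subfamily.to_csv(out / "census_subfamily.tsv", sep="\t", index_label="species_id")
    if census.family.shape[0] >= 2 and census.family.shape[1] >= 2:
        presence = encode_presence(census)
        orders = hierarchical_cluster(presence)
        export_heatmap(presence, orders, out / "presence_heatmap.tsv")
        (out / "presence_rows.nwk").write_text(orders.row_newick + "\n")
        (out / "presence_cols.nwk").write_text(orders.col_newick + "\n")
    return census


def run_bgc(config: RunConfig) -> Dict[str, int]:
    """Intersect loci with clusters; write membership, tallies and report."""
    out = _outdir(config)
    loci = load_gene_loci(_require(config.loci, "loci"))
    clusters = load_bgc_table(_require(config.clusters, "clusters"))
    assignments = io_utils.read_assignments_tsv(
        _require(str(Path(config.out_dir) / "assignments.tsv"), "assignments")
    )
    fam_by_pid = {a.protein_id: a.assigned_family for a in assignments}
    members = p450s_in_clusters(loci, clusters, fam_by_pid, rule=config.overlap_rule)
    with open(out / "membership.tsv", "w") as fh:
        fh.write("protein_id\tspecies_id\tcluster_id\tfamily\toverlap_bases\n")
        for m in members:
            fh.write(
                f"{m.protein_id}\t{m.species_id}\t{m.cluster_id}\t{m.p450_family}\t{m.overlap_bases}\n"
            )
    tally = tally_cluster_types(clusters)
    with open(out / "cluster_type_tally.tsv", "w") as fh:
        fh.write("type\tcount\n")
        for t, n in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{t}\t{n}\n")
    bgc_family_breakdown(members).to_csv(out / "bgc_family_breakdown.tsv", sep="\t", index=False)
    similarity_report(clusters, members).to_csv(out / "bgc_report.tsv", sep="\t", index=False)
    return {"clusters": len(clusters), "memberships": len(members)}


def run_stats(config: RunConfig) -> DiversitySummary:
    """Summarize a finished run into one DiversitySummary (JSON on disk)."""
    out = _outdir(config)
    assignments = io_utils.read_assignments_tsv(
        _require(str(Path(config.out_dir) / "assignments.tsv"), "assignments")
    )
    census = build_census(assignments)
    clusters = load_bgc_table(_require(config.clusters, "clusters"))
    membership_path = _require(str(Path(config.out_dir) / "membership.tsv"), "membership")
    with open(membership_path) as fh:
        in_bgc = {line.split("\t")[0] for line in fh.read().splitlines()[1:] if line}
    dominant = ""
    if census.total_p450s:
        from .census_stats import dominant_families

        dominant = dominant_families(census, 1)[0][0]
    summary = DiversitySummary.from_counts(
        taxon=config.taxon,
        species_analyzed=census.n_species,
        p450s=census.total_p450s,
        families=census.n_families,
        subfamilies=census.n_subfamilies,
        bgcs=len(clusters),
        bgc_types=len(tally_cluster_types(clusters)),
        p450s_in_bgcs=len(in_bgc),
        dominant_family=dominant,
    )
    with open(out / "diversity_summary.json", "w") as fh:
        json.dump(summary.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def run_report(config: RunConfig) -> DiversitySummary:
    """simulate (if no inputs named) -> classify -> census -> bgc -> stats."""
    out = Path(config.out_dir)
    if config.proteome is None:
        _, paths = run_simulate(config)
        config = dataclasses.replace(
            config,
            proteome=str(paths["proteome"]),
            reference_db=str(paths["reference"]),
            loci=str(paths["loci"]),
            clusters=str(paths["clusters"]),
        )
    run_classify(config)
    run_census(config)
    run_bgc(config)
    return run_stats(config)
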