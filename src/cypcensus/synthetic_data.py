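"""Ground-truthed synthetic inputs for every pipeline stage.

Real inputs to this pipeline are species proteomes, a named P450 reference
set, gene coordinates, and antiSMASH-style cluster tables.  None of those can
ship with the package, so this module fabricates all four with *known truth*:

* a reference database of invented families (numbered from 9001 to stay clear
  of real CYP families), rejection-sampled so distinct families sit below
  30% pairwise identity while subfamily exemplars sit at 60-90% identity to
  their family founder;
* proteomes with planted P450s mutated to a controlled identity against a
  chosen reference, plus decoy proteins (no heme motif) and fragments
  (truncated, motif retained);
* one synthetic contig per species with non-overlapping gene loci, and
  clusters placed so that the planted membership is exactly the
  interval-intersection result.

The mutation model is substitution-only by default (uniform over the 19
non-identical residues), which keeps measured identity controllable; an indel
mode exists for stress-testing the aligner.  The heme-motif window of planted
sequences is protected from mutation so triage categories hold by
construction.  All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import ReferenceDB
from .nomenclature import parse_p450_name
from .pairwise_identity import ScoringScheme, global_align
from .triage import TriageParams

__all__ = [
    "GenerationError",
    "PlantSpec",
    "SpeciesSpec",
    "ClusterSpec",
    "TruthBundle",
    "make_reference_db",
    "mutate_to_identity",
    "make_proteome",
    "make_genome_annotation",
    "default_bundle",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# canonical heme-binding motif instance stamped into every synthetic P450
HEME_MOTIF_SEQ = "FGAGRHRCIG"
HEME_MOTIF_RE = re.compile(r"F..G...C.G")


class GenerationError(RuntimeError):
    pass


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _stamp_motif(seq: str, offset_from_end: int = 60) -> str:
    """Place the heme motif at a fixed window near the C terminus."""
    pos = max(0, len(seq) - offset_from_end)
    return seq[:pos] + HEME_MOTIF_SEQ + seq[pos + len(HEME_MOTIF_SEQ) :]


def _motif_window(seq: str, offset_from_end: int = 60) -> range:
    pos = max(0, len(seq) - offset_from_end)
    return range(pos, pos + len(HEME_MOTIF_SEQ))


def mutate_to_identity(
    seq: str,
    target_percent: float,
    seed: int,
    protected: Sequence[int] = (),
    scheme: ScoringScheme | None = None,
    tolerance: float = 2.0,
    max_iter: int = 10000,
) -> str:
    """Substitute residues until measured global identity hits the target.

    The contract is checked, not assumed: identity is re-measured with
    :func:`cypcensus.pairwise_identity.global_align` after every adjustment
    and the result is within ``tolerance`` points of ``target_percent`` or a
    :class:`GenerationError` is raised.
    """
    if not 10 <= target_percent <= 100:
        raise GenerationError(f"target identity {target_percent} outside [10, 100]")
    if target_percent == 100:
        return seq
    rng = np.random.default_rng(seed)
    protected_set = set(protected)
    mutable = [i for i in range(len(seq)) if i not in protected_set]
    if not mutable:
        raise GenerationError("no mutable positions")
    current = list(seq)
    mutated: List[int] = []

    def measure() -> float:
        return global_align(seq, "".join(current), scheme).identity_percent

    # first guess: identity drops ~1 point per substituted position
    n_subs = min(len(mutable), int(round(len(seq) * (1 - target_percent / 100.0))))
    order = list(rng.permutation(mutable))
    for pos in order[:n_subs]:
        choices = [a for a in AMINO_ACIDS if a != seq[pos]]
        current[pos] = choices[rng.integers(len(choices))]
        mutated.append(pos)

    for _ in range(max_iter):
        ident = measure()
        if abs(ident - target_percent) <= tolerance:
            return "".join(current)
        if ident > target_percent:  # mutate one more position
            remaining = [p for p in order if p not in mutated]
            if not remaining:
                break
            pos = remaining[0]
            choices = [a for a in AMINO_ACIDS if a != seq[pos]]
            current[pos] = choices[rng.integers(len(choices))]
            mutated.append(pos)
        else:  # overshot: revert the most recent mutation
            if not mutated:
                break
            pos = mutated.pop()
            current[pos] = seq[pos]
    raise GenerationError(
        f"could not reach identity {target_percent}% within {max_iter} iterations"
    )


def make_reference_db(
    n_families: int,
    subfamilies_per_family: int = 1,
    seq_length: int = 350,
    seed: int = 0,
    max_family_identity: float = 30.0,
    max_retries: int = 50,
) -> ReferenceDB:
    """Reference database of invented families with controlled divergence.

    Family founders are named ``CYP<9000+i>A1``; additional subfamily
    exemplars ``CYP<9000+i>B1``, ``C1`` ... are mutated to 60-90% identity to
    the founder.  Founders are rejection-sampled until all inter-family
    identities fall below ``max_family_identity``.
    """
    if n_families < 1 or subfamilies_per_family < 1:
        raise GenerationError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    founders: List[str] = []
    for i in range(n_families):
        for attempt in range(max_retries):
            cand = _stamp_motif(_random_protein(rng, seq_length))
            if all(
                global_align(cand, f).identity_percent < max_family_identity
                for f in founders
            ):
                founders.append(cand)
                break
        else:
            raise GenerationError(
                f"could not sample founder {i} below {max_family_identity}% identity"
            )
    entries = []
    letters = "ABCDEFGHIJ"
    for i, founder in enumerate(founders):
        fam_num = 9001 + i
        entries.append((parse_p450_name(f"CYP{fam_num}A1"), founder))
        for s in range(1, subfamilies_per_family):
            target = 60 + 30 * (s / max(1, subfamilies_per_family))
            exemplar = mutate_to_identity(
                founder,
                target_percent=target,
                seed=int(rng.integers(2**31)),
                protected=_motif_window(founder),
            )
            entries.append((parse_p450_name(f"CYP{fam_num}{letters[s]}1"), exemplar))
    return ReferenceDB(entries)


@dataclass(frozen=True)
class PlantSpec:
    """One planted P450: which reference it descends from and how far."""

    ref_label: str
    target_identity: float


@dataclass(frozen=True)
class SpeciesSpec:
    species_id: str
    planted: Tuple[PlantSpec, ...] = ()
    n_decoys: int = 0
    n_fragments: int = 0


@dataclass(frozen=True)
class ClusterSpec:
    """One synthetic BGC: which planted proteins it must contain."""

    cluster_id: str
    species_id: str
    member_protein_ids: Tuple[str, ...]
    type_components: Tuple[str, ...] = ("NRPS",)
    most_similar_known: Optional[str] = None
    similarity_percent: Optional[float] = None


@dataclass
class TruthBundle:
    """Everything one synthetic study produces, files plus ground truth."""

    reference_db: ReferenceDB
    proteome: List  # list of triage.CandidateRecord
    truth: pd.DataFrame  # per-protein ground truth
    loci: List = field(default_factory=list)
    clusters: List = field(default_factory=list)

    def write(self, run_dir) -> Dict[str, Path]:
        from .io_utils import write_fasta, write_loci_tsv, write_clusters_tsv

        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference": run_dir / "reference.fasta",
            "proteome": run_dir / "proteome.fasta",
            "truth": run_dir / "truth.tsv",
            "loci": run_dir / "loci.tsv",
            "clusters": run_dir / "clusters.tsv",
        }
        write_fasta(paths["reference"], self.reference_db.as_pairs())
        write_fasta(
            paths["proteome"],
            [(f"{r.species_id}|{r.protein_id}", r.sequence) for r in self.proteome],
        )
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        write_loci_tsv(paths["loci"], self.loci)
        write_clusters_tsv(paths["clusters"], self.clusters)
        return paths


def make_proteome(
    species_specs: Sequence[SpeciesSpec],
    refdb: ReferenceDB,
    seed: int = 0,
    triage_params: TriageParams | None = None,
) -> TruthBundle:
    """Generate proteomes with planted P450s, decoys and fragments.

    Planted proteins are mutated copies of the named reference at the
    requested identity (heme motif protected); decoys are random proteins
    with any heme-motif match scrubbed; fragments are truncated planted
    sequences that keep the motif but fall below the full-length cutoff.
    """
    from .triage import CandidateRecord

    params = triage_params or TriageParams()
    rng = np.random.default_rng(seed)
    ref_by_label = dict(refdb.as_pairs())
    records: List[CandidateRecord] = []
    truth_rows: List[Dict] = []
    for spec in species_specs:
        counter = 0
        for plant in spec.planted:
            if plant.ref_label not in ref_by_label:
                raise GenerationError(f"unknown reference {plant.ref_label!r}")
            counter += 1
            pid = f"{spec.species_id}_p{counter:03d}"
            source = ref_by_label[plant.ref_label]
            seq = mutate_to_identity(
                source,
                plant.target_identity,
                seed=int(rng.integers(2**31)),
                protected=_motif_window(source),
            )
            name = refdb.name(plant.ref_label)
            records.append(CandidateRecord(pid, spec.species_id, seq))
            truth_rows.append(
                {
                    "protein_id": pid,
                    "species_id": spec.species_id,
                    "category": "full_length",
                    "ref_label": plant.ref_label,
                    "family": name.family_token,
                    "subfamily": name.subfamily_token or "",
                    "target_identity": plant.target_identity,
                }
            )
        for _ in range(spec.n_fragments):
            counter += 1
            pid = f"{spec.species_id}_p{counter:03d}"
            label, source = refdb.as_pairs()[int(rng.integers(len(refdb)))]
            frag_len = min(len(source), params.min_full_length - 50)
            seq = source[len(source) - frag_len :]  # C-terminal half keeps the motif
            if not HEME_MOTIF_RE.search(seq):
                raise GenerationError("fragment lost the heme motif")
            records.append(CandidateRecord(pid, spec.species_id, seq))
            truth_rows.append(
                {
                    "protein_id": pid,
                    "species_id": spec.species_id,
                    "category": "fragment",
                    "ref_label": label,
                    "family": "",
                    "subfamily": "",
                    "target_identity": np.nan,
                }
            )
        for _ in range(spec.n_decoys):
            counter += 1
            pid = f"{spec.species_id}_p{counter:03d}"
            seq = _random_protein(rng, 350)
            while HEME_MOTIF_RE.search(seq):
                m = HEME_MOTIF_RE.search(seq)
                seq = seq[: m.start()] + "P" + seq[m.start() + 1 :]
            records.append(CandidateRecord(pid, spec.species_id, seq))
            truth_rows.append(
                {
                    "protein_id": pid,
                    "species_id": spec.species_id,
                    "category": "false_positive",
                    "ref_label": "",
                    "family": "",
                    "subfamily": "",
                    "target_identity": np.nan,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "protein_id",
            "species_id",
            "category",
            "ref_label",
            "family",
            "subfamily",
            "target_identity",
        ],
    )
    return TruthBundle(reference_db=refdb, proteome=records, truth=truth)


def make_genome_annotation(
    bundle: TruthBundle,
    cluster_specs: Sequence[ClusterSpec],
    seed: int = 0,
    gene_spacing: int = 2000,
    cluster_margin: int = 100,
) -> TruthBundle:
    """Lay genes on one synthetic contig per species and place clusters.

    Genes are spaced ``gene_spacing`` bases apart (non-overlapping by
    construction).  Each cluster's member genes are laid out consecutively and
    the cluster interval spans them plus a margin smaller than the spacing,
    so the planted membership is exactly what interval intersection finds.
    """
    from .bgc_crossref import BGCluster, GeneLocus

    rng = np.random.default_rng(seed)
    by_species: Dict[str, List] = {}
    for rec in bundle.proteome:
        by_species.setdefault(rec.species_id, []).append(rec)
    clusters_by_species: Dict[str, List[ClusterSpec]] = {}
    known_ids = {rec.protein_id for rec in bundle.proteome}
    for cs in cluster_specs:
        for pid in cs.member_protein_ids:
            if pid not in known_ids:
                raise GenerationError(f"cluster {cs.cluster_id}: unknown protein {pid!r}")
        clusters_by_species.setdefault(cs.species_id, []).append(cs)

    loci: List[GeneLocus] = []
    clusters: List[BGCluster] = []
    membership_truth: Dict[str, str] = {}
    for species_id, recs in sorted(by_species.items()):
        contig = f"{species_id}_contig1"
        specs = clusters_by_species.get(species_id, [])
        in_cluster = [pid for cs in specs for pid in cs.member_protein_ids]
        ordered = [r for cs in specs for r in recs if r.protein_id in cs.member_protein_ids]
        ordered += [r for r in recs if r.protein_id not in in_cluster]
        pos: Dict[str, Tuple[int, int]] = {}
        cursor = 1 + int(rng.integers(0, 500))
        for rec in ordered:
            glen = 3 * len(rec.sequence)
            if glen >= gene_spacing - 2 * cluster_margin:
                raise GenerationError(
                    f"gene {rec.protein_id} too long for spacing {gene_spacing}"
                )
            strand = "+" if rng.integers(2) else "-"
            loci.append(
                GeneLocus(species_id, contig, cursor, cursor + glen - 1, strand, rec.protein_id)
            )
            pos[rec.protein_id] = (cursor, cursor + glen - 1)
            cursor += gene_spacing
        for cs in specs:
            starts = [pos[p][0] for p in cs.member_protein_ids]
            ends = [pos[p][1] for p in cs.member_protein_ids]
            clusters.append(
                BGCluster(
                    cluster_id=cs.cluster_id,
                    species_id=cs.species_id,
                    contig=contig,
                    start=max(1, min(starts) - cluster_margin),
                    end=max(ends) + cluster_margin,
                    type_components=cs.type_components,
                    most_similar_known=cs.most_similar_known,
                    similarity_percent=cs.similarity_percent,
                )
            )
            for pid in cs.member_protein_ids:
                membership_truth[pid] = cs.cluster_id

    truth = bundle.truth.copy()
    truth["cluster_id"] = truth["protein_id"].map(membership_truth).fillna("")
    return TruthBundle(
        reference_db=bundle.reference_db,
        proteome=bundle.proteome,
        truth=truth,
        loci=loci,
        clusters=clusters,
    )


def default_bundle(seed: int = 0) -> TruthBundle:
    """The default study: 3 species, 4 families (2 subfamilies each),
    30 planted P450s, a few decoys/fragments, 6 clusters.

    Planted identities stay at least 5 points away from the 40/55 thresholds
    so the expected classification is unambiguous.
    """
    refdb = make_reference_db(
        n_families=4, subfamilies_per_family=2, seq_length=350, seed=seed
    )
    labels = [n.raw_label for n, _ in refdb.entries]
    rng = np.random.default_rng(seed + 1)
    species = []
    pid_by_species: Dict[str, List[str]] = {}
    for s in range(3):
        sid = f"sp{s + 1}"
        planted = tuple(
            PlantSpec(
                ref_label=labels[int(rng.integers(len(labels)))],
                target_identity=float(rng.choice([65, 70, 75, 80, 85, 90])),
            )
            for _ in range(10)
        )
        species.append(SpeciesSpec(sid, planted=planted, n_decoys=2, n_fragments=1))
        pid_by_species[sid] = [f"{sid}_p{i:03d}" for i in range(1, 11)]
    bundle = make_proteome(species, refdb, seed=seed + 2)
    cluster_specs = []
    types = [("NRPS",), ("terpene",), ("NRPS", "T1PKS"), ("bacteriocin",), ("T3PKS",), ("terpene",)]
    k = 0
    for s in range(3):
        sid = f"sp{s + 1}"
        for c in range(2):
            members = tuple(pid_by_species[sid][2 * c : 2 * c + 2][: 1 + c])
            cluster_specs.append(
                ClusterSpec(
                    cluster_id=f"{sid}_bgc{c + 1}",
                    species_id=sid,
                    member_protein_ids=members,
                    type_components=types[k % len(types)],
                )
            )
            k += 1
    return make_genome_annotation(bundle, cluster_specs, seed=seed + 3)
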