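import numpy as np
import pytest

from cypcensus.pairwise_identity import global_align
from cypcensus.synthetic_data import (
    ClusterSpec,
    GenerationError,
    PlantSpec,
    SpeciesSpec,
    default_bundle,
    make_genome_annotation,
    make_proteome,
    make_reference_db,
    mutate_to_identity,
)
from oracles import brute_force_memberships


def test_reference_db_divergence_and_labels():
    refdb = make_reference_db(n_families=3, subfamilies_per_family=2, seq_length=300, seed=7)
    pairs = refdb.as_pairs()
    assert len(pairs) == 6
    founders = {n.family_token: s for n, s in refdb.entries if n.subfamily_letters == "A"}
    fams = list(founders)
    for i in range(len(fams)):
        for j in range(i + 1, len(fams)):
            ident = global_align(founders[fams[i]], founders[fams[j]]).identity_percent
            assert ident < 30.0
    for name, seq in refdb.entries:
        assert name.render() == name.raw_label  # labels are well-formed
        if name.subfamily_letters != "A":
            founder = founders[name.family_token]
            ident = global_align(seq, founder).identity_percent
            assert 55.0 < ident <= 95.0


def test_reference_db_deterministic_per_seed():
    a = make_reference_db(2, 1, 250, seed=7)
    b = make_reference_db(2, 1, 250, seed=7)
    c = make_reference_db(2, 1, 250, seed=8)
    assert a.as_pairs() == b.as_pairs()
    assert a.as_pairs() != c.as_pairs()


@pytest.mark.parametrize("target", [70.0, 45.0, 25.0])
def test_mutate_to_identity_hits_target(target):
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=300))
    mutated = mutate_to_identity(seq, target, seed=3)
    measured = global_align(seq, mutated).identity_percent
    assert abs(measured - target) <= 2.0
    assert mutate_to_identity(seq, target, seed=3) == mutated  # same seed, same output


def test_mutate_to_identity_edge_cases():
    seq = "ACDEFGHIKLMNPQRSTVWY" * 10
    assert mutate_to_identity(seq, 100.0, seed=0) == seq
    with pytest.raises(GenerationError):
        mutate_to_identity(seq, 5.0, seed=0)
    protected = range(len(seq))
    with pytest.raises(GenerationError):
        mutate_to_identity(seq, 50.0, seed=0, protected=protected)


def test_proteome_truth_matches_triage():
    from cypcensus.triage import triage_proteome

    refdb = make_reference_db(2, 1, 350, seed=3)
    labels = [n.raw_label for n, _ in refdb.entries]
    spec = SpeciesSpec(
        "spA",
        planted=tuple(PlantSpec(labels[i % 2], 70.0) for i in range(5)),
        n_decoys=2,
        n_fragments=1,
    )
    bundle = make_proteome([spec], refdb, seed=4)
    assert len(bundle.proteome) == 8
    _, _, _, counts = triage_proteome(bundle.proteome)
    assert counts == {"full_length": 5, "fragment": 1, "false_positive": 2}
    assert set(bundle.truth["category"].value_counts().to_dict().items()) == set(
        counts.items()
    )


def test_proteome_rejects_unknown_reference():
    refdb = make_reference_db(1, 1, 300, seed=0)
    spec = SpeciesSpec("spA", planted=(PlantSpec("CYP9999A1", 70.0),))
    with pytest.raises(GenerationError, match="unknown reference"):
        make_proteome([spec], refdb, seed=0)


def test_zero_species_spec_gives_empty_outputs():
    refdb = make_reference_db(1, 1, 300, seed=0)
    bundle = make_proteome([], refdb, seed=0)
    assert bundle.proteome == [] and len(bundle.truth) == 0


def test_annotation_membership_matches_interval_oracle(bundle):
    got = brute_force_memberships(bundle.loci, bundle.clusters)
    truth_members = {
        (row.protein_id, row.cluster_id)
        for row in bundle.truth.itertuples()
        if row.cluster_id
    }
    assert truth_members == got


def test_annotation_type_tallies_match_spec(bundle):
    from cypcensus.bgc_crossref import tally_cluster_types

    tally = tally_cluster_types(bundle.clusters)
    assert sum(tally.values()) == len(bundle.clusters) == 6


def test_annotation_rejects_unknown_member():
    refdb = make_reference_db(1, 1, 300, seed=0)
    b = make_proteome([SpeciesSpec("spA", planted=(PlantSpec("CYP9001A1", 80.0),))], refdb, seed=1)
    with pytest.raises(GenerationError, match="unknown protein"):
        make_genome_annotation(b, [ClusterSpec("c1", "spA", ("missing",))], seed=0)


def test_bundle_files_roundtrip_and_are_deterministic(tmp_path):
    b1 = default_bundle(seed=23)
    b2 = default_bundle(seed=23)
    d1, d2 = tmp_path / "r1", tmp_path / "r2"
    p1, p2 = b1.write(d1), b2.write(d2)
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key
    from cypcensus.io_utils import read_proteome_fasta

    back = read_proteome_fasta(p1["proteome"])
    assert [(r.species_id, r.protein_id, r.sequence) for r in back] == [
        (r.species_id, r.protein_id, r.sequence) for r in b1.proteome
    ]


def test_end_to_end_recovery(bundle):
    """The full pipeline on the default synthetic study recovers 100% of
    planted families and memberships, and its diversity statistics equal
    direct formula evaluation on the truth counts."""
    from cypcensus.bgc_crossref import p450s_in_clusters, tally_cluster_types
    from cypcensus.census_stats import (
        DiversitySummary,
        build_census,
        gene_cluster_diversity_percentage,
        p450_diversity_percentage,
    )
    from cypcensus.classify import classify_proteome
    from cypcensus.triage import triage_proteome

    full, _, _, _ = triage_proteome(bundle.proteome)
    assignments = classify_proteome(full, bundle.reference_db)
    truth = bundle.truth.set_index("protein_id")
    assert all(a.assigned_family == truth.loc[a.protein_id, "family"] for a in assignments)

    census = build_census(assignments)
    fam_by_pid = {a.protein_id: a.assigned_family for a in assignments}
    members = p450s_in_clusters(bundle.loci, bundle.clusters, fam_by_pid)
    got_pairs = {(m.protein_id, m.cluster_id) for m in members}
    want_pairs = {
        (r.protein_id, r.cluster_id) for r in bundle.truth.itertuples() if r.cluster_id
    }
    assert got_pairs == want_pairs

    summary = DiversitySummary.from_counts(
        taxon="synthetic",
        species_analyzed=census.n_species,
        p450s=census.total_p450s,
        families=census.n_families,
        subfamilies=census.n_subfamilies,
        bgcs=len(bundle.clusters),
        bgc_types=len(tally_cluster_types(bundle.clusters)),
        p450s_in_bgcs=len({p for p, _ in got_pairs}),
    )
    S, P, F = census.n_species, census.total_p450s, census.n_families
    assert summary.p450_diversity_pct == p450_diversity_percentage(F, P, S)
    T, C = len(tally_cluster_types(bundle.clusters)), len(bundle.clusters)
    assert summary.cluster_diversity_pct == gene_cluster_diversity_percentage(T, C, S)
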