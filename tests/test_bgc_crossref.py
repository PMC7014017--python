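import numpy as np
import pytest

from cypcensus.bgc_crossref import (
    BGCluster,
    BGCParseError,
    GeneLocus,
    MembershipRecord,
    bgc_family_breakdown,
    from_zero_based_half_open,
    load_bgc_table,
    load_gene_loci,
    p450s_in_clusters,
    similarity_report,
    tally_cluster_types,
    tally_type_strings,
)
from cypcensus.io_utils import write_clusters_tsv, write_loci_tsv
from oracles import brute_force_memberships


def _cluster(cid, start, end, types=("NRPS",), species="sp1", contig="c1", **kw):
    return BGCluster(cid, species, contig, start, end, tuple(types), **kw)


def _locus(pid, start, end, species="sp1", contig="c1"):
    return GeneLocus(species, contig, start, end, "+", pid)


def test_overlap_membership_examples():
    cl = _cluster("bgc1", 1, 1000)
    inside = p450s_in_clusters([_locus("g1", 100, 500)], [cl])
    assert len(inside) == 1 and inside[0].overlap_bases == 401
    outside = p450s_in_clusters([_locus("g2", 1001, 1500)], [cl])
    assert outside == []
    touching = p450s_in_clusters([_locus("g3", 1000, 1200)], [cl])
    assert len(touching) == 1 and touching[0].overlap_bases == 1


def test_contained_rule_is_stricter():
    cl = _cluster("bgc1", 200, 1000)
    straddler = [_locus("g1", 100, 500)]
    assert len(p450s_in_clusters(straddler, [cl], rule="overlap")) == 1
    assert p450s_in_clusters(straddler, [cl], rule="contained") == []


def test_assignments_restrict_and_annotate_membership():
    cl = _cluster("bgc1", 1, 1000)
    loci = [_locus("g1", 10, 50), _locus("g2", 60, 90)]
    members = p450s_in_clusters(loci, [cl], assignments={"g2": "CYP110"})
    assert [(m.protein_id, m.p450_family) for m in members] == [("g2", "CYP110")]


@pytest.mark.parametrize("seed", range(20))
def test_membership_equals_quadratic_oracle(seed):
    """Interval-tree membership equals brute-force all-pairs intersection on
    randomized toy genomes."""
    rng = np.random.default_rng(seed)
    loci, clusters = [], []
    for s in range(2):
        species = f"sp{s}"
        for contig in ("c1", "c2"):
            for g in range(rng.integers(3, 8)):
                start = int(rng.integers(1, 5000))
                loci.append(
                    _locus(f"{species}_{contig}_g{g}", start, start + int(rng.integers(10, 800)),
                           species=species, contig=contig)
                )
            for c in range(rng.integers(1, 4)):
                start = int(rng.integers(1, 5000))
                clusters.append(
                    _cluster(f"{species}_{contig}_b{c}", start, start + int(rng.integers(100, 2500)),
                             species=species, contig=contig)
                )
    got = {(m.protein_id, m.cluster_id) for m in p450s_in_clusters(loci, clusters)}
    assert got == brute_force_memberships(loci, clusters)


def test_tallies_on_worked_example(bgc_report):
    tally = tally_type_strings(bgc_report["cluster_types"])
    assert tally["NRPS, T1PKS"] == 9
    assert tally["terpene"] == 5
    assert tally["bacteriocin"] == 3
    assert len(tally) == 10
    assert sum(tally.values()) == 27


def test_tally_invariant_under_reordering():
    clusters = [_cluster("a", 1, 10, ("NRPS", "T1PKS")), _cluster("b", 1, 10, ("terpene",)),
                _cluster("c", 1, 10, ("NRPS", "T1PKS"))]
    fwd = tally_cluster_types(clusters)
    rev = tally_cluster_types(list(reversed(clusters)))
    assert fwd == rev == {"NRPS, T1PKS": 2, "terpene": 1}


def test_family_breakdown_on_worked_example(bgc_report):
    from cypcensus.nomenclature import parse_p450_name

    families = [parse_p450_name(n).family_token for n in bgc_report["p450_name"]]
    table = bgc_family_breakdown(families)
    assert len(table) == 6
    top = table.iloc[0]
    assert (top["family"], top["count"], top["share_percent"]) == ("CYP110", 17, 63)
    assert dict(zip(table["family"], table["count"]))["CYP213"] == 4
    assert dict(zip(table["family"], table["count"]))["CYP120"] == 3
    assert table["count"].sum() == 27
    assert abs(table["share_percent"].sum() - 100) <= 1


def test_single_membership_breakdown():
    m = MembershipRecord("g1", "sp1", "bgc1", "CYP9001", 10)
    table = bgc_family_breakdown([m])
    assert table.iloc[0].tolist() == ["CYP9001", 1, 100]


def test_similarity_report_rows_and_blanks():
    clusters = [
        _cluster("bgc1", 1, 1000, ("NRPS",), most_similar_known="Anabaenopeptin NZ 857/nostamide A",
                 similarity_percent=100.0),
        _cluster("bgc2", 2000, 3000, ("terpene",)),
    ]
    members = [
        MembershipRecord("g1", "sp1", "bgc1", "CYP110", 50),
        MembershipRecord("g2", "sp1", "bgc2", "CYP110", 80),
    ]
    report = similarity_report(clusters, members, display_names={"g1": "CYP110AH1"})
    assert report.iloc[0].tolist() == [
        "CYP110AH1", "NRPS", "Anabaenopeptin NZ 857/nostamide A", "100",
    ]
    assert report.iloc[1].tolist() == ["g2", "terpene", "", ""]
    with pytest.raises(BGCParseError, match="unknown cluster"):
        similarity_report(clusters, [MembershipRecord("g3", "sp1", "nope", "CYP110", 5)])


def test_cluster_and_locus_validation():
    with pytest.raises(BGCParseError):
        _cluster("bad", 500, 100)
    with pytest.raises(BGCParseError):
        _cluster("bad", 1, 10, types=())
    with pytest.raises(BGCParseError):
        _cluster("bad", 1, 10, similarity_percent=150.0)
    with pytest.raises(BGCParseError):
        GeneLocus("sp1", "c1", 5, 10, "?", "g1")
    assert from_zero_based_half_open(0, 10) == (1, 10)
    with pytest.raises(BGCParseError):
        from_zero_based_half_open(5, 5)


def test_table_loaders_roundtrip_and_errors(tmp_path, bundle):
    loci_path = tmp_path / "loci.tsv"
    clusters_path = tmp_path / "clusters.tsv"
    write_loci_tsv(loci_path, bundle.loci)
    write_clusters_tsv(clusters_path, bundle.clusters)
    assert load_gene_loci(loci_path) == bundle.loci
    assert load_bgc_table(clusters_path) == bundle.clusters

    bad = tmp_path / "bad.tsv"
    header = "cluster_id\tspecies_id\tcontig\tstart\tend\ttype\tmost_similar_known\tsimilarity_percent\n"
    bad.write_text(header + "b1\tsp1\tc1\t500\t100\tNRPS\t\t\n")
    with pytest.raises(BGCParseError, match="bad.tsv:2"):
        load_bgc_table(bad)
    empty = tmp_path / "empty.tsv"
    empty.write_text(header)
    assert load_bgc_table(empty) == []
    dup = tmp_path / "dup.tsv"
    dup.write_text(header + "b1\tsp1\tc1\t1\t10\tNRPS\t\t\nb1\tsp1\tc1\t20\t30\tNRPS\t\t\n")
    with pytest.raises(BGCParseError, match="duplicate"):
        load_bgc_table(dup)


def test_gff3_locus_loading(tmp_path):
    gff = tmp_path / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "c1\tsrc\tgene\t100\t400\t.\t+\t.\tID=g1\n"
        "c1\tsrc\tgene\t900\t1300\t.\t-\t.\tID=g2\n"
    )
    from cypcensus.bgc_crossref import load_gene_loci_gff3

    loci = load_gene_loci_gff3(gff, species_id="sp1")
    assert [(l.protein_id, l.start, l.end, l.strand) for l in loci] == [
        ("g1", 100, 400, "+"),
        ("g2", 900, 1300, "-"),
    ]
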