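import pandas as pd
import pytest

from cypcensus.census_stats import (
    DiversitySummary,
    averages_and_shares,
    build_census,
    conserved_families,
    dominant_families,
    gene_cluster_diversity_percentage,
    p450_diversity_percentage,
    round_half_up,
    summary_table,
)
from cypcensus.classify import AssignmentResult
from cypcensus.nomenclature import parse_p450_name


def _assignment(pid, species, family, subfamily):
    return AssignmentResult(pid, species, "", 0.0, "known_subfamily", family, subfamily)


@pytest.fixture(scope="module")
def pseudo_census(bgc_report):
    """The 27 worked-example P450 labels counted as one pseudo-species."""
    assignments = []
    for i, label in enumerate(bgc_report["p450_name"]):
        name = parse_p450_name(label)
        assignments.append(
            _assignment(f"m{i:02d}", "cyano", name.family_token, name.subfamily_token)
        )
    return build_census(assignments)


def test_census_from_worked_example_labels(pseudo_census):
    totals = pseudo_census.family.sum(axis=0)
    assert totals.to_dict() == {
        "CYP110": 17,
        "CYP213": 4,
        "CYP120": 3,
        "CYP1011": 1,
        "CYP1185": 1,
        "CYP197": 1,
    }
    # columns ordered by descending total, ties by name
    assert list(pseudo_census.family.columns[:3]) == ["CYP110", "CYP213", "CYP120"]
    assert dominant_families(pseudo_census, 1) == [("CYP110", 17)]


def test_empty_census():
    table = build_census([])
    assert table.n_species == 0 and table.total_p450s == 0


def test_census_column_sums_conserve_assignments(bundle):
    from cypcensus.classify import classify_proteome
    from cypcensus.triage import triage_proteome

    full, _, _, _ = triage_proteome(bundle.proteome)
    assignments = classify_proteome(full, bundle.reference_db)
    census = build_census(assignments)
    assert census.total_p450s == len(assignments)
    assert census.subfamily.values.sum() == len(assignments)
    planted = bundle.truth[bundle.truth.category == "full_length"]
    expected = planted.groupby("family").size().to_dict()
    assert census.family.sum(axis=0).to_dict() == expected


def test_conserved_families():
    fam = pd.DataFrame(
        [[2, 1, 0], [1, 3, 0], [5, 0, 1]],
        index=["s1", "s2", "s3"],
        columns=["CYP9001", "CYP9002", "CYP9003"],
    )
    from cypcensus.census_stats import CensusTable

    assert conserved_families(CensusTable(family=fam)) == ["CYP9001"]
    single = CensusTable(family=fam.iloc[[0]])
    assert conserved_families(single) == ["CYP9001", "CYP9002"]


@pytest.mark.parametrize(
    "families, p450s, species, expected",
    [(36, 341, 114, 0.09), (13, 507, 128, 0.02), (77, 1784, 60, 0.07), (144, 1625, 48, 0.18), (1, 1, 1, 100.0)],
)
def test_p450_diversity_percentage(families, p450s, species, expected):
    assert p450_diversity_percentage(families, p450s, species) == expected


@pytest.mark.parametrize(
    "types, clusters, species, expected",
    [(73, 770, 114, 0.08), (33, 1098, 128, 0.02), (18, 898, 60, 0.03), (159, 1461, 48, 0.23), (1, 1, 1, 100.0)],
)
def test_gene_cluster_diversity_percentage(types, clusters, species, expected):
    assert gene_cluster_diversity_percentage(types, clusters, species) == expected


def test_diversity_domain_errors():
    with pytest.raises(ValueError):
        p450_diversity_percentage(1, 0, 10)
    with pytest.raises(ValueError):
        gene_cluster_diversity_percentage(1, 10, 0)


@pytest.mark.parametrize(
    "p, s, c, n_in, expected",
    [
        (341, 114, 770, 27, (3, 7, 8)),
        (507, 128, 1098, 112, (4, 9, 22)),
        (1784, 60, 898, 204, (30, 15, 11)),
        (1625, 48, 1461, 554, (34, 30, 34)),
        (10, 10, 0, 0, (1, 0, 0)),
    ],
)
def test_averages_and_shares(p, s, c, n_in, expected):
    assert averages_and_shares(p, s, c, n_in) == expected


def test_averages_consistency_error():
    with pytest.raises(ValueError):
        averages_and_shares(10, 5, 3, 11)


def test_rounding_is_half_up():
    assert round_half_up(0.085, 2) == 0.09
    assert round_half_up(2.5) == 3.0
    assert round_half_up(0.084999, 2) == 0.08


def test_doubling_species_halves_both_diversity_percentages():
    base_p = p450_diversity_percentage(40, 400, 50)
    base_c = gene_cluster_diversity_percentage(60, 600, 50)
    assert p450_diversity_percentage(40, 400, 100) == pytest.approx(base_p / 2)
    assert gene_cluster_diversity_percentage(60, 600, 100) == pytest.approx(base_c / 2)


def test_summary_table_reproduces_all_derived_cells(comparative_counts):
    """Feeding the four taxa's raw counts through the formulas reproduces
    every derived cell of the comparative key-features table."""
    summaries = [
        DiversitySummary.from_counts(
            taxon=r.taxon,
            species_analyzed=r.species_analyzed,
            p450s=r.p450s,
            families=r.families,
            subfamilies=r.subfamilies,
            bgcs=r.bgcs,
            bgc_types=r.bgc_types,
            p450s_in_bgcs=r.p450s_in_bgcs,
            dominant_family=r.dominant_family,
        )
        for r in comparative_counts.itertuples()
    ]
    table = summary_table(summaries)
    expected = {
        "avg_p450": [3, 4, 30, 34],
        "p450_diversity_pct": [0.09, 0.02, 0.07, 0.18],
        "avg_bgc": [7, 9, 15, 30],
        "cluster_diversity_pct": [0.08, 0.02, 0.03, 0.23],
        "pct_p450s_in_bgcs": [8, 22, 11, 34],
    }
    taxa = ["Cyanobacteria", "Bacillus", "Mycobacteria", "Streptomyces"]
    assert list(table.columns) == taxa
    for row, values in expected.items():
        assert list(table.loc[row, taxa]) == values


def test_summary_table_single_taxon():
    s = DiversitySummary.from_counts("solo", 10, 20, 5, 8, 30, 6, 4)
    table = summary_table([s])
    assert table.shape[1] == 1
    assert table.loc["p450_diversity_pct", "solo"] == 2.5
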