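"""Packaged worked-example datasets.

Two small tables from a published comparative census of bacterial P450s and
secondary-metabolite BGCs ship with the package:

* ``comparative_counts`` — the raw count rows (species analyzed, P450s,
  families, subfamilies, BGCs, BGC types, P450s inside BGCs) for four
  bacterial groups: Cyanobacteria, *Bacillus*, mycobacteria, *Streptomyces*.
  All derived statistics (averages, diversity percentages, shares) are
  recomputed from these counts, never stored.
* ``bgc_p450_report`` — the 27 cyanobacterial P450-in-BGC report rows
  (P450 name, antiSMASH-style cluster type string, most similar known
  cluster, similarity %).  Three P450s sit in two clusters each, so rows are
  memberships, not distinct proteins.
"""

from __future__ import annotations

from importlib import resources
from typing import List

import pandas as pd

from .census_stats import DiversitySummary

__all__ = [
    "load_comparative_counts",
    "load_bgc_p450_report",
    "comparative_summaries",
]


def _data_path(name: str):
    return resources.files("cypcensus").joinpath("data", name)


def load_comparative_counts() -> pd.DataFrame:
    """Count rows of the four-taxa comparative table, one row per taxon."""
    with resources.as_file(_data_path("comparative_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_bgc_p450_report() -> pd.DataFrame:
    """The 27 P450-in-BGC membership rows for the cyanobacterial census."""
    with resources.as_file(_data_path("cyanobacteria_bgc_p450s.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"p450_name": str, "cluster_types": str})
    for col in ("most_similar_known", "similarity_percent"):
        if col not in df:
            df[col] = pd.NA
    return df


def comparative_summaries() -> List[DiversitySummary]:
    """Derived comparative statistics recomputed from the packaged counts."""
    df = load_comparative_counts()
    return [
        DiversitySummary.from_counts(
            taxon=row.taxon,
            species_analyzed=int(row.species_analyzed),
            p450s=int(row.p450s),
            families=int(row.families),
            subfamilies=int(row.subfamilies),
            bgcs=int(row.bgcs),
            bgc_types=int(row.bgc_types),
            p450s_in_bgcs=int(row.p450s_in_bgcs),
            dominant_family=row.dominant_family,
        )
        for row in df.itertuples()
    ]
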