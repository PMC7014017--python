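"""Presence/absence heat-map clustering and an identity-distance NJ tree.

Encodes a synthetic census as 3 (family present) / -3 (absent), clusters
both axes with Euclidean average linkage, then builds a neighbor-joining
tree of a few P450 sequences and scores how well same-family sequences
group together (1.0 = every multi-member family is monophyletic).
"""

from cypcensus.census_stats import build_census
from cypcensus.classify import classify_proteome
from cypcensus.phylogeny import distance_matrix, family_grouping_score, nj_tree
from cypcensus.profiles import encode_presence, hierarchical_cluster
from cypcensus.synthetic_data import default_bundle
from cypcensus.triage import triage_proteome

bundle = default_bundle(seed=42)
full, _, _, _ = triage_proteome(bundle.proteome)
assignments = classify_proteome(full, bundle.reference_db)
census = build_census(assignments)

presence = encode_presence(census)
orders = hierarchical_cluster(presence)
print("clustered species order:", orders.row_order)
print("clustered family order:", orders.col_order)
print("family dendrogram:", orders.col_newick)

subset = sorted(full, key=lambda r: r.protein_id)[:9]
tree = nj_tree(distance_matrix([(r.protein_id, r.sequence) for r in subset]))
fams = {a.protein_id: a.assigned_family for a in assignments}
score = family_grouping_score(tree, {r.protein_id: fams[r.protein_id] for r in subset})
print(f"\nfamily grouping score on the NJ tree: {score:.2f} "
      "(fraction of multi-member families forming exclusive clades)")
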