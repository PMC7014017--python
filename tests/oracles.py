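"""Independent brute-force oracles the test suite checks the package against.

Each oracle re-derives a result by exhaustive enumeration or direct
definition, sharing no code path with the implementation it validates.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, List, Sequence, Tuple

import numpy as np


def brute_force_global_score(
    a: str, b: str, sub, gap_open: float, gap_extend: float
) -> float:
    """Best global alignment score by enumerating every monotone path.

    Affine gaps: a run of L gap columns in one row costs
    gap_open + (L - 1) * gap_extend.  Exponential in len(a) + len(b); only
    for short sequences.
    """
    best = [-np.inf]

    def walk(i: int, j: int, last: str, score: float) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, "M", score + sub[a[i], b[j]])
        if i < len(a):
            walk(i + 1, j, "D", score - (gap_extend if last == "D" else gap_open))
        if j < len(b):
            walk(i, j + 1, "I", score - (gap_extend if last == "I" else gap_open))

    walk(0, 0, "", 0.0)
    return best[0]


def brute_force_memberships(loci, clusters) -> set:
    """All (protein_id, cluster_id) pairs overlapping >= 1 base, by direct
    all-pairs interval comparison (1-based inclusive coordinates)."""
    out = set()
    for locus in loci:
        for cl in clusters:
            if locus.species_id != cl.species_id or locus.contig != cl.contig:
                continue
            overlap = min(locus.end, cl.end) - max(locus.start, cl.start) + 1
            if overlap >= 1:
                out.add((locus.protein_id, cl.cluster_id))
    return out


def brute_force_average_linkage_merges(
    labels: Sequence[str], vectors: np.ndarray
) -> List[Tuple[Tuple[str, ...], Tuple[str, ...], float]]:
    """Agglomerative average-linkage merge sequence, recomputing every
    cluster-pair distance directly as the mean Euclidean distance over all
    inter-cluster point pairs (no Lance-Williams update)."""
    points: Dict[str, np.ndarray] = {lab: vectors[i] for i, lab in enumerate(labels)}
    clusters: List[Tuple[str, ...]] = [(lab,) for lab in labels]
    merges = []
    while len(clusters) > 1:
        best_pair = None
        best_d = np.inf
        for ca, cb in combinations(sorted(clusters), 2):
            d = float(
                np.mean(
                    [np.linalg.norm(points[x] - points[y]) for x in ca for y in cb]
                )
            )
            key = tuple(sorted(ca + cb))
            if (
                best_pair is None
                or d < best_d - 1e-12
                or (abs(d - best_d) <= 1e-12 and key < tuple(sorted(best_pair[0] + best_pair[1])))
            ):
                best_pair, best_d = (ca, cb), d
        ca, cb = best_pair
        merges.append(tuple(sorted((tuple(sorted(ca)), tuple(sorted(cb))))) + (best_d,))
        clusters = [c for c in clusters if c not in (ca, cb)] + [tuple(sorted(ca + cb))]
    return merges


def tree_path_lengths(newick: str) -> Dict[Tuple[str, str], float]:
    """Leaf-to-leaf path lengths of a Newick tree (via skbio)."""
    from skbio import TreeNode

    tree = TreeNode.read([newick], convert_underscores=False)
    tips = sorted(t.name for t in tree.tips())
    return {
        (x, y): tree.find(x).distance(tree.find(y))
        for x, y in combinations(tips, 2)
    }


def additive_matrix_from_tree(newick: str):
    """Distance matrix implied by a tree's branch lengths (the NJ input
    whose correct output is the tree itself)."""
    from skbio import DistanceMatrix

    paths = tree_path_lengths(newick)
    labels = sorted({l for pair in paths for l in pair})
    n = len(labels)
    d = np.zeros((n, n))
    for (x, y), v in paths.items():
        i, j = labels.index(x), labels.index(y)
        d[i, j] = d[j, i] = v
    return DistanceMatrix(d, ids=labels)
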