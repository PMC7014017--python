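"""Identity-distance trees and a family-grouping sanity check.

Correctly assigned P450 families should come out as coherent groups on a
sequence tree.  This module builds that check from three pieces:

1. a distance matrix d(a, b) = 1 - identity(a, b) / 100 over all sequence
   pairs (global alignment identity from :mod:`cypcensus.pairwise_identity`);
2. a neighbor-joining tree on those distances (deterministic: Q-matrix ties
   are broken by the lexicographically smallest sorted label pair);
3. ``family_grouping_score`` — the fraction of multi-member families that are
   monophyletic on the unrooted tree (singleton families are trivially
   monophyletic and excluded from the denominator).

NJ is exact on additive distances: it recovers the generating topology and
branch lengths, which the test-suite exploits.  Identity distances from real
proteins are not additive, so the tree is a classification sanity check, not
a published phylogeny; negative NJ branch lengths, if they arise, are kept
as computed.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .pairwise_identity import ScoringScheme, global_align

__all__ = [
    "distance_matrix",
    "nj_tree",
    "family_grouping_score",
    "write_phylip",
]


def distance_matrix(
    sequences: Sequence[Tuple[str, str]],
    scheme: ScoringScheme | None = None,
) -> DistanceMatrix:
    """Pairwise identity distances over labelled sequences.

    ``sequences`` is a list of (label, sequence).  Distances are
    1 - identity/100, symmetric with a zero diagonal.
    """
    labels = [lab for lab, _ in sequences]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate sequence labels: {dupes}")
    if len(labels) < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = global_align(sequences[i][1], sequences[j][1], scheme).identity_percent
            d[i, j] = d[j, i] = 1.0 - ident / 100.0
    return DistanceMatrix(d, ids=labels)


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree as a Newick string (unrooted, trifurcating root).

    Accepts a ``skbio.DistanceMatrix`` or anything with ``.ids`` and
    ``.data``.  Ties in the Q matrix are broken by the smallest sorted label
    pair, making the output a pure function of the input.
    """
    labels = list(dm.ids)
    D = np.array(dm.data, dtype=float)
    if D.shape[0] != D.shape[1] or len(labels) != D.shape[0]:
        raise ValueError("distance matrix is not square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    if (D < -1e-12).any():
        raise ValueError("distance matrix has negative entries")
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    # working state: node label (for tie-breaks), newick fragment, distances
    names: List[str] = list(labels)
    nwk: List[str] = list(labels)
    D = D.copy()

    while len(names) > 3:
        m = len(names)
        r = D.sum(axis=1)
        # Q(i, j) = (m - 2) d(i, j) - r_i - r_j
        best = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = tuple(sorted((names[i], names[j])))
                if (
                    best is None
                    or q < best_q - 1e-12
                    or (abs(q - best_q) <= 1e-12 and key < best[2])
                ):
                    best, best_q = (i, j, key), q
        i, j, _ = best
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        new_nwk = f"({nwk[i]}:{_fmt(li)},{nwk[j]}:{_fmt(lj)})"
        new_name = min(names[i], names[j])
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], d_new[keep]])
        D = np.hstack([D, np.append(d_new[keep], 0.0)[:, None]])
        names = [names[k] for k in keep] + [new_name]
        nwk = [nwk[k] for k in keep] + [new_nwk]

    # terminal 3-star: closed-form branch lengths
    (a, b, c) = range(3)
    la = (D[a, b] + D[a, c] - D[b, c]) / 2.0
    lb = (D[a, b] + D[b, c] - D[a, c]) / 2.0
    lc = (D[a, c] + D[b, c] - D[a, b]) / 2.0
    order = sorted(range(3), key=lambda k: names[k])
    lens = {a: la, b: lb, c: lc}
    parts = ",".join(f"{nwk[k]}:{_fmt(lens[k])}" for k in order)
    return f"({parts});"


def _bipartition_subsets(tree: TreeNode) -> set:
    """Leaf-name frozensets below each node (one side of every bipartition)."""
    subsets = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            subsets.add(frozenset([node.name]))
        else:
            subsets.add(frozenset(t.name for t in node.tips()))
    return subsets


def family_grouping_score(newick: str, families: Dict[str, str]) -> float:
    """Fraction of multi-member families monophyletic on the unrooted tree.

    ``families`` maps every leaf label to its family token; an unlabeled leaf
    is an error.  A family is counted monophyletic when some bipartition of
    the tree separates exactly its members from everything else.
    """
    tree = TreeNode.read([newick], convert_underscores=False)
    tips = {t.name for t in tree.tips()}
    missing = sorted(tips - set(families))
    if missing:
        raise ValueError(f"leaves without family labels: {missing}")
    subsets = _bipartition_subsets(tree)
    by_family: Dict[str, set] = {}
    for leaf, fam in families.items():
        if leaf in tips:
            by_family.setdefault(fam, set()).add(leaf)
    multi = {f: members for f, members in by_family.items() if len(members) > 1}
    if not multi:
        return 1.0
    mono = 0
    for members in multi.values():
        fs = frozenset(members)
        if fs == tips or fs in subsets or frozenset(tips - fs) in subsets:
            mono += 1
    return mono / len(multi)


def write_phylip(dm: DistanceMatrix, path) -> None:
    """Square PHYLIP-style distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for label in dm.ids:
            row = " ".join(_fmt(v) for v in dm[label])
            fh.write(f"{label} {row}\n")
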