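"""Partner-type combination matrix, mismatch distances and UPGMA.

Mating-spectrum similarity between categories is summarized by listing,
for every category, the partner types it was ever observed mating with
(a binary vector), and comparing these lists with the simple mismatch
coefficient

    SMC(i, j) = (f_10 + f_01) / (f_11 + f_10 + f_01 + f_00),

the fraction of positions at which the two binary vectors disagree
(joint absences count in the denominator).  The resulting distance
matrices — one over active-male categories, one over passive
categories — are clustered with UPGMA.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode

from .records import CopulationRecord
from .taxonomy import ALL_ACTIVE_CATEGORIES, ALL_PASSIVE_CATEGORIES


def combination_presence(
    records: Sequence[CopulationRecord], drop_empty: bool = False
) -> pd.DataFrame:
    """Boolean passive x active matrix of observed partner-type combinations.

    A cell is True iff the combination appears with non-zero observed
    frequency in any stratum.  With ``drop_empty`` rows/columns never
    observed at all are removed (the published table omits them).
    """
    if not records:
        raise ValueError("combination_presence requires at least one record")
    index = [c.label for c in ALL_PASSIVE_CATEGORIES]
    columns = [c.label for c in ALL_ACTIVE_CATEGORIES]
    matrix = pd.DataFrame(False, index=index, columns=columns)
    for rec in records:
        matrix.at[rec.passive.label, rec.active.label] = True
    if drop_empty:
        matrix = matrix.loc[matrix.any(axis=1), matrix.any(axis=0)]
    return matrix


def smc_distance(matrix: pd.DataFrame, margin: str) -> DistanceMatrix:
    """Pairwise simple-mismatch distances along one margin of the matrix.

    ``margin="active_columns"`` compares the mating spectra of active
    male categories (columns); ``margin="passive_rows"`` those of
    passive categories (rows).
    """
    if margin == "active_columns":
        data = matrix.to_numpy(dtype=bool).T
        labels = list(matrix.columns)
    elif margin == "passive_rows":
        data = matrix.to_numpy(dtype=bool)
        labels = list(matrix.index)
    else:
        raise ValueError(f"unknown margin {margin!r}")
    if len(labels) < 2:
        raise ValueError("need at least two categories on the chosen margin")
    if data.shape[1] == 0:
        raise ValueError("zero-length comparison vectors")
    mism = (data[:, None, :] != data[None, :, :]).mean(axis=2)
    return DistanceMatrix(mism, ids=labels)


def upgma(dist: DistanceMatrix) -> TreeNode:
    """Cluster a distance matrix with UPGMA into a rooted ultrametric tree.

    Agglomeration uses arithmetic-average linkage with cluster-size
    weights; a node joining at distance d sits at height d/2, and branch
    lengths are height differences, so all leaves are equidistant from
    the root.  Ties are broken deterministically by sorting labels
    before clustering.
    """
    ids = list(dist.ids)
    if len(ids) < 2:
        raise ValueError("UPGMA requires at least two labels")
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    labels = [ids[i] for i in order]
    square = dist.data[np.ix_(order, order)]
    links = linkage(squareform(square, checks=False), method="average")

    nodes: dict[int, tuple[TreeNode, float]] = {
        i: (TreeNode(name=lab), 0.0) for i, lab in enumerate(labels)
    }
    n = len(labels)
    for k, (a, b, d, _size) in enumerate(links):
        height = d / 2.0
        left, h_left = nodes.pop(int(a))
        right, h_right = nodes.pop(int(b))
        left.length = height - h_left
        right.length = height - h_right
        nodes[n + k] = (TreeNode(children=[left, right]), height)
    (root, _h), = nodes.values()
    return root


def leaf_heights(tree: TreeNode) -> dict[str, float]:
    """Root-to-leaf path lengths (equal for an ultrametric tree)."""
    return {tip.name: tree.distance(tip) for tip in tree.tips()}
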