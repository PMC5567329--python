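"""Strain trees from gene-family presence/absence profiles and ANI matrices.

The gene-family tree is a distance surrogate: strains are compared by the
Jaccard distance between their family presence sets and the distance matrix
is resolved with classical neighbor joining.  An ANI matrix can likewise be
turned into distances d = (100 - ANI)/100.  On an additive distance matrix
neighbor joining recovers the generating tree exactly (branch lengths
included), which is the correctness oracle used by the tests.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .pangenome import PanGenomeResult

__all__ = [
    "PhyloTree",
    "presence_matrix",
    "profile_distance",
    "neighbor_joining",
    "ani_distance",
    "write_distance_tsv",
]


@dataclass
class PhyloTree:
    """Unrooted tree with non-negative branch lengths.

    ``negative_branches_clamped`` flags whether any NJ branch length came out
    negative and was clamped to zero.
    """

    tree: TreeNode
    negative_branches_clamped: bool = False

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf)
        return buf.getvalue().strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def tip_names(self) -> List[str]:
        return sorted(t.name for t in self.tree.tips())

    def midpoint_rooted(self) -> "PhyloTree":
        return PhyloTree(self.tree.root_at_midpoint(), self.negative_branches_clamped)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        return cls(TreeNode.read(io.StringIO(newick)))


def presence_matrix(result: PanGenomeResult) -> pd.DataFrame:
    """Strains x clusters binary matrix from a pan-genome result."""
    strains = result.strain_order
    data = np.zeros((len(strains), len(result.clusters)), dtype=np.int8)
    index = {s: i for i, s in enumerate(strains)}
    for j, cluster in enumerate(result.clusters):
        for strain in cluster.presence:
            data[index[strain], j] = 1
    return pd.DataFrame(data, index=strains, columns=[c.cluster_id for c in result.clusters])


def profile_distance(matrix: pd.DataFrame, metric: str = "jaccard") -> DistanceMatrix:
    """Pairwise Jaccard distances between strain family-presence profiles:
    d(i,j) = 1 - |intersection| / |union|."""
    if metric != "jaccard":
        raise ValueError(f"unsupported metric: {metric!r}")
    if matrix.shape[0] < 2:
        raise ValueError("at least 2 strains are required")
    arr = matrix.to_numpy(dtype=bool)
    empty = np.flatnonzero(~arr.any(axis=1))
    if empty.size:
        raise ValueError(f"strain(s) with zero families: {list(matrix.index[empty])}")
    dm = squareform(pdist(arr, metric="jaccard"))
    return DistanceMatrix(dm, ids=list(matrix.index))


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Classical NJ agglomeration; negative branch lengths are clamped to 0
    and flagged.  A 2-taxon matrix resolves to a single edge split evenly."""
    if isinstance(d, pd.DataFrame):
        d = DistanceMatrix(d.to_numpy(dtype=float), ids=list(d.index))
    if np.any(d.data < 0):
        raise ValueError("distance matrix has negative entries")
    ids = list(d.ids)
    if len(ids) < 2:
        raise ValueError("at least 2 taxa are required")
    if len(ids) == 2:
        half = d[ids[0], ids[1]] / 2.0
        tree = TreeNode.read(io.StringIO(f"({ids[0]}:{half},{ids[1]}:{half});"))
        return PhyloTree(tree)
    tree = nj(d, neg_as_zero=False)
    clamped = False
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    return PhyloTree(tree, negative_branches_clamped=clamped)


def ani_distance(ani: pd.DataFrame) -> DistanceMatrix:
    """d = (100 - ANI_mean) / 100 from a complete symmetric ANI matrix."""
    if ani.isna().any().any():
        missing = [
            (i, j) for i in ani.index for j in ani.columns if pd.isna(ani.loc[i, j])
        ]
        raise ValueError(f"missing ANI value(s): {missing[:5]}")
    arr = (100.0 - ani.to_numpy(dtype=float)) / 100.0
    np.fill_diagonal(arr, 0.0)
    arr = (arr + arr.T) / 2.0  # guard against asymmetric rounding in input files
    return DistanceMatrix(arr, ids=list(ani.index))


def write_distance_tsv(d: DistanceMatrix, path) -> None:
    df = pd.DataFrame(d.data, index=list(d.ids), columns=list(d.ids))
    df.to_csv(path, sep="\t")
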