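"""Shared-peptide counts between subfamilies and Ward dendrograms.

Two subfamilies are related to the extent that their conserved-peptide
lists intersect.  The pairwise intersection counts form a symmetric
matrix; converting each count S to the dissimilarity d = L - S (L = the
list-size cap, 70 by default) gives a bounded distance fed to Ward
agglomerative clustering, whose tree is exported as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode

from .ppr import PeptideGroup


@dataclass
class SharedPeptideMatrix:
    """Symmetric counts of peptides shared between subfamily lists.

    ``ids`` are the group ids in lexicographic order; ``S[i][j]`` counts
    hexapeptides present in both group i's and group j's lists, and the
    diagonal holds each list's size.
    """

    ids: list[str]
    S: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="group_id")


def shared_peptide_matrix(groups: Sequence[PeptideGroup]) -> SharedPeptideMatrix:
    """Exact pairwise intersection counts of the groups' peptide lists."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ordered = sorted(groups, key=lambda g: g.id)
    ids = [g.id for g in ordered]
    sets = [frozenset(g.peptides) for g in ordered]
    n = len(sets)
    S = np.zeros((n, n), dtype=int)
    for i in range(n):
        S[i, i] = len(sets[i])
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = len(sets[i] & sets[j])
    return SharedPeptideMatrix(ids=ids, S=S)


def ward_linkage(matrix: SharedPeptideMatrix, list_size: int = 70) -> np.ndarray:
    """Ward linkage on the dissimilarity ``d = list_size - S``."""
    S = matrix.S
    if S.shape[0] != S.shape[1] or not np.array_equal(S, S.T):
        raise ValueError("shared-peptide matrix must be symmetric")
    D = float(list_size) - S.astype(float)
    np.fill_diagonal(D, 0.0)
    if (D < 0).any():
        raise ValueError(f"shared counts exceed list_size={list_size}")
    return linkage(squareform(D, checks=False), method="ward")


def ward_dendrogram(matrix: SharedPeptideMatrix, list_size: int = 70) -> TreeNode:
    """Ward dendrogram as a tree with branch lengths from merge heights.

    Leaves are labelled by group id.  Deterministic given the matrix:
    ids are sorted, and equal dissimilarities resolve to the first
    (lexicographically smallest) pair in that ordering.
    """
    Z = ward_linkage(matrix, list_size)
    tree = TreeNode.from_linkage_matrix(Z, matrix.ids)
    # from_linkage_matrix can leave tiny negative lengths from float noise
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")
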