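"""Reproducibility analysis: pairwise sample correlations and clustering.

Samples are compared as per-bin ratio vectors on a shared bin grid (Pearson
correlation), and the correlation matrix is turned into distances ``1 - r``
for agglomerative hierarchical clustering.  Cells amplified with the same
method share built-in bias and cluster together; MDA-like cells correlate
with nothing.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import squareform

from .binning import RatioVector


@dataclasses.dataclass
class CorrelationMatrix:
    """Symmetric Pearson-correlation matrix over samples.

    Entries are NaN where a correlation is undefined (constant vector).
    """

    labels: list[str]
    matrix: np.ndarray
    n_bins_used: int
    n_bins_excluded: int
    scope: str = "all"

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", float_format="%.6f"
        )


@dataclasses.dataclass
class ClusteringResult:
    labels: list[str]
    linkage_matrix: np.ndarray  # scipy linkage encoding, n-1 merges
    method: str
    distance: str = "1 - pearson r"

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in leaves_list(self.linkage_matrix)]

    def subtree_leaf_sets(self) -> list[frozenset[str]]:
        """Leaf-label sets of every internal node (the clusters of the tree)."""
        tree = to_tree(self.linkage_matrix)
        sets: list[frozenset[str]] = []

        def collect(node) -> frozenset[str]:
            if node.is_leaf():
                return frozenset({self.labels[node.id]})
            s = collect(node.left) | collect(node.right)
            sets.append(s)
            return s

        collect(tree)
        return sets

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def fmt(node, parent_dist: float) -> str:
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6f}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6f}"

        return f"({fmt(tree.left, tree.dist)},{fmt(tree.right, tree.dist)});"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def pairwise_correlation(samples: list[RatioVector]) -> CorrelationMatrix:
    """Pearson correlations between per-bin ratio vectors.

    All vectors must come from the same bin set and scope.  Bins that are zero
    in every sample are excluded (and counted); a sample that is constant over
    the retained bins has undefined correlations, reported as NaN.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    scopes = {s.scope for s in samples}
    if len(scopes) != 1:
        raise ValueError("samples use different scopes")
    lengths = {s.scope_values.shape[0] for s in samples}
    if len(lengths) != 1:
        raise ValueError("samples have different bin counts")
    data = np.vstack([s.scope_values for s in samples])
    keep = ~np.all(data == 0, axis=0)
    excluded = int((~keep).sum())
    data = data[:, keep]
    sd = data.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.corrcoef(data)
    mat = np.asarray(mat, dtype=np.float64)
    for i, s in enumerate(sd):
        if s == 0:
            warnings.warn(
                f"sample {samples[i].sample_id!r} is constant; correlations undefined"
            )
            mat[i, :] = np.nan
            mat[:, i] = np.nan
    np.fill_diagonal(mat, 1.0)
    return CorrelationMatrix(
        labels=[s.sample_id for s in samples],
        matrix=mat,
        n_bins_used=int(keep.sum()),
        n_bins_excluded=excluded,
        scope=samples[0].scope,
    )


def cluster_samples(
    corr: CorrelationMatrix, method: str = "average"
) -> ClusteringResult:
    """Agglomerative clustering of samples at distance ``1 - r``.

    Missing correlations are imputed as the maximum observed distance (with a
    warning), so an uncorrelatable sample joins the tree last rather than
    crashing it.
    """
    if len(corr.labels) < 3:
        raise ValueError("need at least 3 samples to cluster")
    dist = 1.0 - corr.matrix
    np.fill_diagonal(dist, 0.0)
    if np.isnan(dist).any():
        finite_max = np.nanmax(dist)
        warnings.warn("missing correlations imputed as the maximum distance")
        dist = np.where(np.isnan(dist), finite_max, dist)
    dist = np.maximum(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    z = linkage(squareform(dist, checks=False), method=method)
    return ClusteringResult(labels=list(corr.labels), linkage_matrix=z, method=method)
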