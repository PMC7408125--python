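"""Strain-level metabolite-profile analytics.

Presence calls, producing-strain sets and strain-exclusive compound counts;
the new-compound-in-reference statistic; and the heatmap transform used for
profile comparison: generalized-log (glog) variance stabilization followed
by Pareto scaling, then agglomerative hierarchical clustering with
Euclidean distance and complete linkage on both axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .compounds import CompoundRecord
from .quantify import StrainCompoundMatrix

__all__ = ["PresenceMatrix", "ProfileStats", "ProfileClustering", "presence_matrix",
           "producing_strains", "new_in_reference", "glog_pareto", "cluster_profiles",
           "linkage_to_newick"]


@dataclass
class PresenceMatrix:
    """Binary strains × compounds matrix plus the threshold that produced it."""

    values: pd.DataFrame
    threshold: float
    source: str = ""


@dataclass
class ProfileStats:
    producing: dict[str, frozenset[str]]        # compound -> producing strains
    exclusive_count: int                        # compounds made by exactly one strain
    per_strain_counts: pd.Series                # compounds produced per strain
    all_zero_count: int                         # compounds produced by no strain


@dataclass
class ProfileClustering:
    transformed: pd.DataFrame
    row_linkage: np.ndarray
    col_linkage: np.ndarray

    def cut_rows(self, k: int) -> pd.Series:
        labels = hierarchy.fcluster(self.row_linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.transformed.index, name="cluster")

    def cut_cols(self, k: int) -> pd.Series:
        labels = hierarchy.fcluster(self.col_linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.transformed.columns, name="cluster")


def presence_matrix(m: StrainCompoundMatrix | pd.DataFrame, threshold: float = 0.0) -> PresenceMatrix:
    """Binary presence calls: 1 iff abundance > threshold × column max (and > 0)."""
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    df = m.values if isinstance(m, StrainCompoundMatrix) else m
    colmax = df.max(axis=0)
    cutoff = colmax * threshold
    binary = (df.gt(cutoff, axis=1) & df.gt(0)).astype(int)
    return PresenceMatrix(values=binary, threshold=threshold)


def producing_strains(p: PresenceMatrix) -> ProfileStats:
    """Producing-strain sets, exclusive-compound count and per-strain tallies."""
    producing = {
        c: frozenset(p.values.index[p.values[c] == 1]) for c in p.values.columns
    }
    n_producers = p.values.sum(axis=0)
    return ProfileStats(
        producing=producing,
        exclusive_count=int((n_producers == 1).sum()),
        per_strain_counts=p.values.sum(axis=1),
        all_zero_count=int((n_producers == 0).sum()),
    )


def new_in_reference(
    records: Sequence[CompoundRecord], reference: str
) -> tuple[int, float]:
    """How many newly identified compounds the reference strain also produces.

    Considers the records flagged as not previously known; returns the count
    whose producing-strain set contains *reference* and that count as a
    percentage of all new records.  Raises if no record is new.
    """
    new = [r for r in records if not r.known]
    if not new:
        raise ValueError("no new (previously unreported) compounds among the records")
    count = sum(1 for r in new if reference in r.producing_strains)
    return count, 100.0 * count / len(new)


def glog_pareto(m: pd.DataFrame, lam: float | None = None) -> pd.DataFrame:
    """Generalized-log transform then Pareto scaling, column-wise.

    glog(x) = log((x + sqrt(x² + λ²)) / 2); λ defaults to the smallest
    nonzero entry of the matrix.  Pareto scaling centres each column and
    divides by the square root of its standard deviation; a zero-variance
    column is centred only, with a warning.
    """
    x = m.to_numpy(dtype=float)
    if lam is None:
        nonzero = x[x > 0]
        lam = float(nonzero.min()) if nonzero.size else 1.0
    if lam <= 0:
        raise ValueError("glog lambda must be positive")
    g = np.log((x + np.sqrt(x**2 + lam**2)) / 2.0)
    centred = g - g.mean(axis=0, keepdims=True)
    sd = g.std(axis=0, ddof=1) if g.shape[0] > 1 else np.zeros(g.shape[1])
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance columns left centred", stacklevel=2)
    scale = np.sqrt(np.where(flat, 1.0, sd))
    return pd.DataFrame(centred / scale, index=m.index, columns=m.columns)


def cluster_profiles(transformed: pd.DataFrame) -> ProfileClustering:
    """Hierarchical clustering (Euclidean, complete linkage) on both axes."""
    if transformed.shape[0] < 2:
        raise ValueError("clustering needs at least two rows")
    row_link = hierarchy.linkage(pdist(transformed.to_numpy(), metric="euclidean"),
                                 method="complete")
    if transformed.shape[1] >= 2:
        col_link = hierarchy.linkage(pdist(transformed.to_numpy().T, metric="euclidean"),
                                     method="complete")
    else:
        col_link = np.empty((0, 4))
    return ProfileClustering(transformed=transformed, row_linkage=row_link,
                             col_linkage=col_link)


def linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(link)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def plot_heatmap(transformed: pd.DataFrame, clustering: ProfileClustering, path) -> None:
    """Optional clustered-heatmap rendering (requires matplotlib/seaborn)."""
    import matplotlib
    matplotlib.use("Agg")
    import seaborn as sns

    cg = sns.clustermap(
        transformed,
        row_linkage=clustering.row_linkage,
        col_linkage=clustering.col_linkage if clustering.col_linkage.size else None,
        cmap="vlag",
    )
    cg.savefig(path)
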