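"""Ward clustering of cells of interest, cluster summaries and embedding.

Cells are merged agglomeratively on Euclidean distances in the assembled
feature space with Ward's variance-minimization linkage, and the tree is cut
to K clusters. K is a design choice (set to the approximate number of known
columnar types when typing a real connectome; set to the number of generated
types when benchmarking recovery on synthetic data). Cluster indices are
assigned by dendrogram leaf order so identical input always yields identical
labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .exceptions import InvalidArgumentError
from .features import FeatureMatrix, depth_bin_edges

__all__ = [
    "ClusterAssignment",
    "ward_cluster",
    "cut_to_k",
    "cluster_summary",
    "embed_2d",
    "annotate_layers",
    "linkage_to_newick",
    "DEFAULT_LAYER_BOUNDARIES",
    "DEFAULT_LAYER_NAMES",
]

#: Approximate layer-boundary depths (um) relative to the reference surface.
#: The reference layer sits at depth 0 (~layer 2/3 of the lobula); boundaries
#: are placed at 10 um steps on either side and are explicitly approximate.
DEFAULT_LAYER_BOUNDARIES = (-10.0, 0.0, 10.0, 20.0, 30.0)
DEFAULT_LAYER_NAMES = ("Lo1", "Lo2", "Lo3", "Lo4", "Lo5", "Lo6")


@dataclass
class ClusterAssignment:
    """Cell -> cluster labels (1..K) plus the full Ward merge tree."""

    labels: dict[int, int]
    linkage: np.ndarray   # scipy linkage matrix, (n-1, 4)
    K: int
    cell_ids: list[int]

    def label_array(self) -> np.ndarray:
        return np.array([self.labels[c] for c in self.cell_ids], dtype=int)

    def members(self, cluster: int) -> list[int]:
        return [c for c in self.cell_ids if self.labels[c] == cluster]


def _relabel_by_leaf_order(Z: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Renumber clusters 1..K by first appearance along the dendrogram leaves."""
    order = leaves_list(Z)
    mapping: dict[int, int] = {}
    nxt = 1
    for leaf in order:
        r = int(raw[leaf])
        if r not in mapping:
            mapping[r] = nxt
            nxt += 1
    return np.array([mapping[int(r)] for r in raw], dtype=int)


def cut_to_k(Z: np.ndarray, K: int) -> np.ndarray:
    """Cut a linkage tree into K clusters, labels 1..K in leaf order."""
    n = Z.shape[0] + 1
    if not 1 <= K <= n:
        raise InvalidArgumentError(f"K must be in [1, {n}], got {K}")
    raw = fcluster(Z, t=K, criterion="maxclust")
    return _relabel_by_leaf_order(Z, raw)


def ward_cluster(features: FeatureMatrix | np.ndarray | pd.DataFrame, K: int) -> ClusterAssignment:
    """Agglomerative Ward clustering on Euclidean distances, cut to K."""
    if isinstance(features, FeatureMatrix):
        X = features.array
        cell_ids = list(features.cell_ids)
    elif isinstance(features, pd.DataFrame):
        X = features.to_numpy(dtype=float)
        cell_ids = list(features.index)
    else:
        X = np.asarray(features, dtype=float)
        cell_ids = list(range(X.shape[0]))
    n = X.shape[0]
    if not 1 <= K <= n:
        raise InvalidArgumentError(f"K must be in [1, {n}], got {K}")
    Z = linkage(X, method="ward")
    labels = cut_to_k(Z, K)
    return ClusterAssignment(
        labels={cid: int(l) for cid, l in zip(cell_ids, labels)},
        linkage=Z,
        K=K,
        cell_ids=cell_ids,
    )


def cluster_summary(
    assignment: ClusterAssignment,
    depth_hists: pd.DataFrame,
    spreads: pd.DataFrame,
    edges: pd.DataFrame,
    top_n: int | None = None,
) -> list[dict]:
    """Per-cluster means with SEM, plus targets ranked by mean synapses/cell.

    Mean synapses/cell for a cluster onto a target type is the cluster's
    total synapse count onto all cells of that type divided by the cluster's
    cell count (cells with no such edges count in the denominator).
    """
    summaries = []
    for k in range(1, assignment.K + 1):
        members = assignment.members(k)
        n = len(members)
        dh = depth_hists.loc[members].to_numpy(dtype=float)
        sp = spreads.loc[members].to_numpy(dtype=float)
        sub = edges[edges["source_id"].isin(members) & (edges["target_type"] != "")]
        per_type = sub.groupby("target_type")["weight"].sum().sort_values(ascending=False) / n
        top = [(t, float(v)) for t, v in per_type.items()]
        if top_n is not None:
            top = top[:top_n]
        summaries.append(
            {
                "cluster": k,
                "n_cells": n,
                "mean_depth_hist": dh.mean(axis=0).tolist(),
                "sem_depth_hist": (dh.std(axis=0, ddof=1) / np.sqrt(n)).tolist() if n > 1 else [0.0] * dh.shape[1],
                "mean_spread": sp.mean(axis=0).tolist(),
                "sem_spread": (sp.std(axis=0, ddof=1) / np.sqrt(n)).tolist() if n > 1 else [0.0, 0.0, 0.0],
                "top_targets": top,
            }
        )
    return summaries


def embed_2d(features: FeatureMatrix | np.ndarray, seed: int, **umap_kw) -> np.ndarray:
    """2-D UMAP embedding of the feature matrix, for visualization only."""
    X = features.array if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise InvalidArgumentError("need at least 4 cells to embed")
    import umap  # deferred: heavy import (numba compilation)

    umap_kw.setdefault("n_neighbors", min(15, n - 1))
    reducer = umap.UMAP(n_components=2, random_state=seed, **umap_kw)
    return np.asarray(reducer.fit_transform(X), dtype=float)


def annotate_layers(
    mean_depth_hist,
    layer_boundaries: Sequence[float] = DEFAULT_LAYER_BOUNDARIES,
    layer_names: Sequence[str] = DEFAULT_LAYER_NAMES,
    lo: float = -20.0,
    width: float = 5.0,
    dominance_threshold: float = 0.25,
) -> tuple[dict[str, float], list[str]]:
    """Apportion depth-histogram mass to named layers; flag dominant layers.

    Bins straddling a boundary contribute proportionally to the overlap.
    Layers holding at least ``dominance_threshold`` of the total mass are
    reported dominant.
    """
    b = np.asarray(layer_boundaries, dtype=float)
    if np.any(np.diff(b) <= 0):
        raise InvalidArgumentError("layer boundaries must be strictly increasing")
    if len(layer_names) != len(b) + 1:
        raise InvalidArgumentError("need one more layer name than boundaries")
    h = np.asarray(mean_depth_hist, dtype=float)
    edges = lo + width * np.arange(len(h) + 1)
    cuts = np.concatenate([[-np.inf], b, [np.inf]])
    mass = np.zeros(len(layer_names))
    for i, hi_val in enumerate(h):
        b0, b1 = edges[i], edges[i + 1]
        for j in range(len(layer_names)):
            overlap = max(0.0, min(b1, cuts[j + 1]) - max(b0, cuts[j]))
            mass[j] += hi_val * overlap / width
    total = mass.sum()
    fractions = {name: (m / total if total > 0 else 0.0) for name, m in zip(layer_names, mass)}
    dominant = [name for name, f in fractions.items() if f >= dominance_threshold]
    return fractions, dominant


def linkage_to_newick(Z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Serialize a scipy linkage tree as a Newick string with branch lengths."""
    from scipy.cluster.hierarchy import to_tree

    root = to_tree(Z)

    def height(node):
        return 0.0 if node.is_leaf() else node.dist

    def render(node, parent_height):
        length = parent_height - height(node)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.10g}"
        left = render(node.left, height(node))
        right = render(node.right, height(node))
        return f"({left},{right}):{length:.10g}"

    left = render(root.left, height(root))
    right = render(root.right, height(root))
    return f"({left},{right});"
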