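"""Relative synaptic input from clusters to visual projection neuron types.

For each target type (the LC/LPLC panel), the synapses it receives from the
cells of interest are partitioned by the senders' cluster membership and
expressed as fractions of the total it receives from cells of interest, so
each row of the target x cluster matrix sums to 1. Minor contributors can be
lumped into an "others" column for display, and the target types themselves
can be clustered by their input profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .cluster import ClusterAssignment, linkage_to_newick
from .exceptions import InvalidArgumentError

__all__ = [
    "RelativeConnectivity",
    "relative_input_fractions",
    "lump_minor_clusters",
    "cluster_targets",
]

OTHERS = "others"


@dataclass
class RelativeConnectivity:
    """Target-type x cluster matrix of relative synaptic input.

    ``fractions`` rows are target types, columns are cluster indices (plus an
    optional "others" column after lumping). Rows of targets that receive no
    input from cells of interest are flagged and left all-zero.
    """

    fractions: pd.DataFrame
    flagged: list[str] = field(default_factory=list)
    # integer synapse counts behind the fractions, when known; lumping on
    # counts is exact where float re-summation would drift by an ulp
    counts: pd.DataFrame | None = None

    @property
    def target_types(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def clusters(self) -> list:
        return list(self.fractions.columns)

    def row_sums(self) -> pd.Series:
        return self.fractions.sum(axis=1)

    def save(self, path: str | Path, comments: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for c in comments:
                fh.write(f"# {c}\n")
            if self.flagged:
                fh.write(f"# flagged_zero_input={','.join(self.flagged)}\n")
            self.fractions.rename_axis("target_type").to_csv(fh, sep="\t", float_format="%.12g")


def relative_input_fractions(
    edges: pd.DataFrame,
    assignment: ClusterAssignment | Mapping[int, int],
    target_types: Sequence[str],
) -> RelativeConnectivity:
    """Fraction of each target type's input contributed by each cluster.

    fraction(t, c) = synapses from cluster-c cells onto cells of type t,
    divided by total synapses from all assigned cells onto type t.
    """
    if len(target_types) == 0:
        raise InvalidArgumentError("target_types must be non-empty")
    labels = assignment.labels if isinstance(assignment, ClusterAssignment) else dict(assignment)
    clusters = sorted(set(labels.values()))
    sub = edges[edges["source_id"].isin(labels.keys()) & edges["target_type"].isin(target_types)].copy()
    sub["cluster"] = sub["source_id"].map(labels)
    counts = sub.pivot_table(
        index="target_type", columns="cluster", values="weight", aggfunc="sum", fill_value=0
    )
    cmat = pd.DataFrame(0, index=list(target_types), columns=clusters, dtype=np.int64)
    common = counts.index.intersection(cmat.index)
    shared = [c for c in clusters if c in counts.columns]
    cmat.loc[common, shared] = counts.loc[common, shared].astype(np.int64)
    totals = cmat.sum(axis=1)
    flagged = [t for t in cmat.index if totals[t] == 0]
    mat = cmat.astype(float)
    nonzero = totals > 0
    mat.loc[nonzero] = mat.loc[nonzero].div(totals[nonzero], axis=0)
    return RelativeConnectivity(fractions=mat, flagged=flagged, counts=cmat)


def lump_minor_clusters(rc: RelativeConnectivity, threshold: float = 0.05) -> RelativeConnectivity:
    """Per target row, sum contributions below ``threshold`` into "others".

    Lumped entries are moved, not dropped, so row sums are conserved — in
    exact integer arithmetic when the underlying synapse counts are known,
    and to within float summation order otherwise.
    """
    if not 0.0 <= threshold < 1.0:
        raise InvalidArgumentError("threshold must be in [0, 1)")
    mat = rc.fractions
    cols = [c for c in mat.columns if c != OTHERS]
    minor = mat[cols] < threshold
    if rc.counts is not None:
        cbody = rc.counts[cols]
        cothers = rc.counts[OTHERS] if OTHERS in rc.counts.columns else pd.Series(0, index=mat.index)
        cothers = cothers + cbody.where(minor, 0).sum(axis=1)
        ckept = cbody.where(~minor, 0)
        counts_out = ckept.copy()
        counts_out[OTHERS] = cothers
        totals = rc.counts.sum(axis=1)
        out = counts_out.astype(float)
        nonzero = totals > 0
        out.loc[nonzero] = out.loc[nonzero].div(totals[nonzero], axis=0)
        return replace(rc, fractions=out, counts=counts_out)
    others = mat[OTHERS].copy() if OTHERS in mat.columns else pd.Series(0.0, index=mat.index)
    others = others + mat[cols].where(minor, 0.0).sum(axis=1)
    out = mat[cols].where(~minor, 0.0)
    out[OTHERS] = others
    return replace(rc, fractions=out, counts=None)


def cluster_targets(rc: RelativeConnectivity, method: str = "ward") -> tuple[np.ndarray, list[str], str]:
    """Agglomerative clustering of target types by their input profiles.

    Ward linkage on Euclidean distances between the (un-lumped) rows of the
    relative-connectivity matrix; flagged zero-input targets are excluded.
    Returns (linkage matrix, ordered target names, Newick string).
    """
    valid = [t for t in rc.target_types if t not in rc.flagged]
    if len(valid) < 2:
        raise InvalidArgumentError("need at least 2 targets with non-zero input to cluster")
    X = rc.fractions.loc[valid].to_numpy(dtype=float)
    # rows are observations; square fraction matrices trip scipy's
    # "looks like a distance matrix" heuristic, so hand it the condensed
    # pairwise distances explicitly
    Z = linkage(pdist(X), method=method)
    return Z, valid, linkage_to_newick(Z, valid)
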