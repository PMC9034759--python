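"""Recovery benchmarks on synthetic connectomes.

Runs the library-level pipeline (generate -> frame -> features -> Ward) in
memory and scores the clustering against the generator's ground truth with
the adjusted Rand index. Used by the validation drivers and the acceptance
suite; kept here so they all measure exactly the same computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import features as ft
from . import io as cio
from .cluster import ClusterAssignment, ward_cluster
from .geometry import LayerFrame, build_layer_frame, frame_points
from .synth import SyntheticConnectome, default_fixture

__all__ = ["RecoveryResult", "extract_feature_matrix", "recover_types"]


@dataclass
class RecoveryResult:
    ari: float
    assignment: ClusterAssignment
    feature_matrix: ft.FeatureMatrix
    depth_hists: pd.DataFrame
    spreads: pd.DataFrame
    frame: LayerFrame
    connectome: SyntheticConnectome


def extract_feature_matrix(
    sc: SyntheticConnectome,
    frame: LayerFrame,
    weights=ft.DEFAULT_WEIGHTS,
    kernel=ft.DEFAULT_KERNEL,
):
    """Inclusion filter + per-cell features + assembled matrix, in memory."""
    cells = cio.summarize_cells(sc.synapses, sc.cell_types)
    coi = sorted(cio.select_cells_of_interest(cells))
    syn = sc.synapses
    pre = syn[(syn["polarity"] == "pre") & syn["cell_id"].isin(coi)]
    framed = frame_points(pre[["x", "y", "z"]].to_numpy(), frame)
    framed["cell_id"] = pre["cell_id"].to_numpy()
    idx = pd.Index(coi, name="cell_id")
    spreads, hists, smoothed = [], [], []
    for cid in coi:
        g = framed[framed["cell_id"] == cid]
        spreads.append(ft.synapse_spread(g))
        h = ft.innervation_depth_hist(g["depth"].to_numpy())
        hists.append(h)
        smoothed.append(ft.smooth_depth_hist(h, kernel))
    spreads = pd.DataFrame(spreads, index=idx, columns=["e1", "e2", "e3"])
    hists = pd.DataFrame(hists, index=idx, columns=[f"bin{i + 1:02d}" for i in range(14)])
    smoothed = pd.DataFrame(np.asarray(smoothed), index=idx, columns=hists.columns)
    conn = ft.connectivity_matrix(coi, sc.edges)
    fm = ft.assemble_feature_matrix(conn, spreads, smoothed, weights=weights)
    return fm, hists, spreads


def recover_types(seed: int, K: int = 8, noise_scale: float = 1.0) -> RecoveryResult:
    """Default fixture at the given seed, clustered at K, scored by ARI."""
    sc = default_fixture(seed, noise_scale=noise_scale)
    frame = build_layer_frame(sc.reference_postsynapses)
    fm, hists, spreads = extract_feature_matrix(sc, frame)
    assignment = ward_cluster(fm, K)
    truth = [sc.ground_truth[c] for c in assignment.cell_ids]
    ari = adjusted_rand_score(truth, assignment.label_array())
    return RecoveryResult(
        ari=float(ari),
        assignment=assignment,
        feature_matrix=fm,
        depth_hists=hists,
        spreads=spreads,
        frame=frame,
        connectome=sc,
    )
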