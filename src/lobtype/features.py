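"""Per-cell morphology and connectivity features, and the combined matrix.

Each cell of interest is described by three feature blocks:

* connectivity — synapses onto each labeled downstream type, summed over all
  individual cells of that type (so retinotopic position drops out),
* synapse spread — sample SDs of its presynapse positions along the three
  layer-frame axes (two tangential extents + vertical diffuseness),
* innervation depth — presynapse counts in 5 um bins of relative depth over
  [-20, 50) um, 14 bins spanning the full depth of the neuropil, lightly
  smoothed along depth before clustering.

Before concatenation, each block is normalized by its total dispersion (the
sum of per-feature variances) and weighted. The default reading divides by
sqrt(total dispersion), so each block enters with unit dispersion and the
weights (5, 1, 3 for connectivity, spread, depth) directly set the relative
block influence; dividing by the dispersion itself is available via
``mode="linear"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateFeatureError, InvalidArgumentError

__all__ = [
    "DEPTH_LO",
    "DEPTH_HI",
    "DEPTH_BIN_WIDTH",
    "DEFAULT_KERNEL",
    "DEFAULT_WEIGHTS",
    "FeatureMatrix",
    "TypeProfile",
    "synapse_spread",
    "innervation_depth_hist",
    "depth_bin_edges",
    "smooth_depth_hist",
    "connectivity_vector",
    "connectivity_matrix",
    "assemble_feature_matrix",
    "type_profile",
]

DEPTH_LO = -20.0
DEPTH_HI = 50.0
DEPTH_BIN_WIDTH = 5.0
DEFAULT_KERNEL = (0.25, 0.5, 0.25)
#: block weights: (connectivity, spread, depth)
DEFAULT_WEIGHTS = (5.0, 1.0, 3.0)


def synapse_spread(points) -> np.ndarray:
    """Sample SD (n-1 divisor) of synapse positions along the three frame axes.

    Accepts an (n, 3) array or a framed DataFrame with x, y, z columns.
    A single synapse has zero spread by convention.
    """
    if isinstance(points, pd.DataFrame):
        points = points[["x", "y", "z"]].to_numpy(dtype=float)
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidArgumentError(f"expected (n, 3) framed points, got shape {pts.shape}")
    if pts.shape[0] == 0:
        raise InvalidArgumentError("cannot compute spread of an empty synapse set")
    if pts.shape[0] == 1:
        return np.zeros(3)
    return pts.std(axis=0, ddof=1)


def depth_bin_edges(lo: float = DEPTH_LO, hi: float = DEPTH_HI, width: float = DEPTH_BIN_WIDTH) -> np.ndarray:
    n_bins = _n_bins(lo, hi, width)
    return lo + width * np.arange(n_bins + 1)


def _n_bins(lo: float, hi: float, width: float) -> int:
    if not lo < hi:
        raise InvalidArgumentError(f"need lo < hi, got [{lo}, {hi})")
    if width <= 0:
        raise InvalidArgumentError("bin width must be positive")
    ratio = (hi - lo) / width
    n = round(ratio)
    if abs(ratio - n) > 1e-9:
        raise InvalidArgumentError(f"range [{lo}, {hi}) is not divisible by width {width}")
    return int(n)


def innervation_depth_hist(
    depths, lo: float = DEPTH_LO, hi: float = DEPTH_HI, width: float = DEPTH_BIN_WIDTH
) -> np.ndarray:
    """Histogram of relative depths in half-open bins [lo+i*w, lo+(i+1)*w).

    Depths outside [lo, hi) are dropped (the default range covers the whole
    neuropil, so out-of-range synapses are reconstruction strays, not layers).
    With the defaults this yields 14 integer counts.
    """
    n_bins = _n_bins(lo, hi, width)
    d = np.asarray(depths, dtype=float)
    idx = np.floor((d - lo) / width).astype(int)
    valid = (idx >= 0) & (idx < n_bins) & (d < hi)  # guard float edge: d just below hi
    return np.bincount(idx[valid], minlength=n_bins).astype(np.int64)


def smooth_depth_hist(hist, kernel: Sequence[float] = DEFAULT_KERNEL) -> np.ndarray:
    """Convolve a depth histogram with a normalized kernel, reflect boundary."""
    k = np.asarray(kernel, dtype=float)
    if k.ndim != 1 or len(k) % 2 == 0:
        raise InvalidArgumentError("kernel must be 1-D with odd length")
    if np.any(k < 0) or abs(k.sum() - 1.0) > 1e-9:
        raise InvalidArgumentError("kernel must be non-negative and sum to 1")
    h = np.asarray(hist, dtype=float)
    half = len(k) // 2
    if half == 0:
        return h.copy()
    # half-sample reflection (edge value repeated): the unique reflecting
    # boundary under which convolution with a normalized kernel conserves mass
    padded = np.pad(h, half, mode="symmetric")
    return np.convolve(padded, k, mode="valid")


def connectivity_vector(cell_id: int, edges: pd.DataFrame, labeled_types: Sequence[str]) -> np.ndarray:
    """Synapse counts from one cell onto each labeled type, summed over bodies."""
    if len(labeled_types) == 0:
        raise InvalidArgumentError("labeled_types must be non-empty")
    sub = edges[edges["source_id"] == cell_id]
    totals = sub.groupby("target_type")["weight"].sum()
    return np.array([int(totals.get(t, 0)) for t in labeled_types], dtype=np.int64)


def connectivity_matrix(
    cell_ids: Sequence[int], edges: pd.DataFrame, labeled_types: Sequence[str] | None = None
) -> pd.DataFrame:
    """Cells x labeled-types synapse count matrix.

    When ``labeled_types`` is None the column panel is the sorted union of
    labeled types downstream of at least one of the given cells.
    """
    ids = list(cell_ids)
    sub = edges[edges["source_id"].isin(ids) & (edges["target_type"] != "")]
    if labeled_types is None:
        labeled_types = sorted(sub["target_type"].unique())
    pivot = sub.pivot_table(
        index="source_id", columns="target_type", values="weight", aggfunc="sum", fill_value=0
    )
    out = pd.DataFrame(0, index=pd.Index(ids, name="cell_id"), columns=list(labeled_types), dtype=np.int64)
    shared = [t for t in labeled_types if t in pivot.columns]
    common = pivot.index.intersection(out.index)
    out.loc[common, shared] = pivot.loc[common, shared].astype(np.int64)
    return out


@dataclass
class FeatureMatrix:
    """Normalized, weighted, concatenated feature blocks over cells of interest."""

    cell_ids: list[int]
    values: pd.DataFrame                  # rows = cells, named feature columns
    block_slices: dict[str, slice]        # block name -> column slice
    block_weights: tuple[float, float, float]
    normalization_record: dict[str, float]  # block name -> raw total dispersion

    @property
    def array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def block(self, name: str) -> np.ndarray:
        return self.array[:, self.block_slices[name]]

    def save(self, path: str | Path, comments: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for c in comments:
                fh.write(f"# {c}\n")
            self.values.rename_axis("cell_id").to_csv(fh, sep="\t", float_format="%.12g")


def _total_dispersion(block: np.ndarray) -> float:
    if block.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 cells to compute dispersion")
    return float(block.var(axis=0, ddof=1).sum())


def assemble_feature_matrix(
    conn_block: pd.DataFrame,
    spread_block: pd.DataFrame,
    depth_block: pd.DataFrame,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    mode: str = "sqrt",
) -> FeatureMatrix:
    """Normalize each block by its total dispersion, weight and concatenate.

    ``mode="sqrt"`` (default) divides each block by the square root of its
    total dispersion, so the assembled block's total dispersion equals the
    squared weight; ``mode="linear"`` divides by the dispersion itself.
    """
    if mode not in ("sqrt", "linear"):
        raise InvalidArgumentError(f"unknown normalization mode {mode!r}")
    blocks = {"connectivity": conn_block, "spread": spread_block, "depth": depth_block}
    index = conn_block.index
    for name, b in blocks.items():
        if not b.index.equals(index):
            raise InvalidArgumentError(f"block '{name}' row order differs from connectivity block")
    record: dict[str, float] = {}
    scaled = []
    slices: dict[str, slice] = {}
    col = 0
    prefixes = {"connectivity": "conn", "spread": "spread", "depth": "depth"}
    for (name, b), w in zip(blocks.items(), weights):
        arr = b.to_numpy(dtype=float)
        disp = _total_dispersion(arr)
        if disp <= 0.0:
            raise DegenerateFeatureError(f"block '{name}' has zero total dispersion")
        record[name] = disp
        denom = np.sqrt(disp) if mode == "sqrt" else disp
        part = pd.DataFrame(
            arr / denom * w,
            index=index,
            columns=[f"{prefixes[name]}:{c}" for c in b.columns],
        )
        scaled.append(part)
        slices[name] = slice(col, col + part.shape[1])
        col += part.shape[1]
    values = pd.concat(scaled, axis=1)
    return FeatureMatrix(
        cell_ids=list(index),
        values=values,
        block_slices=slices,
        block_weights=tuple(weights),
        normalization_record=record,
    )


@dataclass(frozen=True)
class TypeProfile:
    """Per-type validation summary: mean depth profile and spread with SEM."""

    depth_profile: np.ndarray   # 14 reals, peak-normalized
    mean_spread: np.ndarray     # 3 values, um
    sem_spread: np.ndarray      # 3 values, um (0 with n=1)
    n_cells: int


def type_profile(framed_points_per_cell: Sequence[pd.DataFrame], **hist_kw) -> TypeProfile:
    """Mean depth histogram (peak-normalized within type) and mean spread +/- SEM.

    Used to validate the morphology features against cell types of known
    anatomy: the per-cell histograms of (post)synapse depth are averaged over
    the type's cells and scaled so the peak bin is 1.
    """
    if len(framed_points_per_cell) == 0:
        raise InvalidArgumentError("type has no cells")
    hists = np.array(
        [innervation_depth_hist(df["depth"].to_numpy(), **hist_kw) for df in framed_points_per_cell],
        dtype=float,
    )
    spreads = np.array([synapse_spread(df) for df in framed_points_per_cell])
    mean_hist = hists.mean(axis=0)
    peak = mean_hist.max()
    if peak <= 0.0:
        raise InvalidArgumentError("all-zero depth histograms; cannot peak-normalize the profile")
    n = len(framed_points_per_cell)
    sem = spreads.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(3)
    return TypeProfile(
        depth_profile=mean_hist / peak,
        mean_spread=spreads.mean(axis=0),
        sem_spread=sem,
        n_cells=n,
    )
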