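"""Reading/writing connectome exports and the inclusion filter.

Three tab-separated dialects are used throughout (header row required; empty
string for absent labels; lines starting with ``#`` are metadata comments):

* synapse table — ``cell_id, x, y, z, polarity, partner_id, partner_type,
  neuropil``; one row per synaptic site of the owning cell. Positions are in
  micrometres unless a ``# units=voxel`` comment declares raw 8 nm voxel
  coordinates (hemibrain convention), in which case they are converted on read.
* edge table — ``source_id, target_id, target_type, weight``; aggregated
  synapse counts between cells.
* cell-type table — ``cell_id, type_label``; the owning cell's label, empty
  for unlabeled fragments.

The inclusion filter reproduces the study design: keep unlabeled fragments
confined to one neuropil (the lobula) with more than ``min_sites`` and fewer
than ``max_sites`` total synaptic sites, both bounds strict.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import FormatError, InvalidArgumentError

__all__ = [
    "SYNAPSE_COLUMNS",
    "EDGE_COLUMNS",
    "VOXEL_SIZE_UM",
    "read_synapse_table",
    "write_synapse_table",
    "read_edge_table",
    "write_edge_table",
    "read_cell_types",
    "write_cell_types",
    "summarize_cells",
    "select_cells_of_interest",
]

SYNAPSE_COLUMNS = ("cell_id", "x", "y", "z", "polarity", "partner_id", "partner_type", "neuropil")
EDGE_COLUMNS = ("source_id", "target_id", "target_type", "weight")
#: hemibrain native voxel pitch, micrometres
VOXEL_SIZE_UM = 0.008


def _read_tsv(path: str | Path, required: Iterable[str]) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column '{col}'")
    return df, meta


def _numeric(df: pd.DataFrame, col: str, path, kind=float, allow_empty=False) -> pd.Series:
    raw = df[col]
    if allow_empty:
        raw = raw.replace("", "nan")
    converted = pd.to_numeric(raw, errors="coerce")
    bad = converted.isna() & (df[col] != "") if allow_empty else converted.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{Path(path).name}: unparseable value {df[col].iloc[row]!r} in column '{col}' at data row {row + 1}"
        )
    return converted.astype(kind) if kind is not float else converted.astype(float)


def read_synapse_table(path: str | Path, voxel_size_um: float = VOXEL_SIZE_UM) -> pd.DataFrame:
    """Read a synapse table; positions are returned in micrometres."""
    df, meta = _read_tsv(path, SYNAPSE_COLUMNS)
    out = pd.DataFrame()
    out["cell_id"] = _numeric(df, "cell_id", path, kind=np.int64)
    for c in ("x", "y", "z"):
        out[c] = _numeric(df, c, path)
    if meta.get("units", "um") == "voxel":
        for c in ("x", "y", "z"):
            out[c] = out[c] * voxel_size_um
    polarity = df["polarity"]
    bad = ~polarity.isin(["pre", "post"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(f"{Path(path).name}: polarity must be 'pre' or 'post' (data row {row + 1})")
    out["polarity"] = polarity.to_numpy()
    partner = _numeric(df, "partner_id", path, allow_empty=True)
    out["partner_id"] = partner.astype("Int64")
    out["partner_type"] = df["partner_type"].to_numpy()
    out["neuropil"] = df["neuropil"].to_numpy()
    if not np.all(np.isfinite(out[["x", "y", "z"]].to_numpy())):
        raise FormatError(f"{Path(path).name}: non-finite synapse position")
    return out


def write_synapse_table(synapses: pd.DataFrame, path: str | Path, comments: Iterable[str] = ()) -> None:
    """Write a synapse table in the documented dialect (positions in um)."""
    path = Path(path)
    df = synapses.loc[:, list(SYNAPSE_COLUMNS)].copy()
    df["partner_id"] = df["partner_id"].astype("Int64").astype(object)
    df.loc[df["partner_id"].isna(), "partner_id"] = ""
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_edge_table(path: str | Path) -> pd.DataFrame:
    df, _ = _read_tsv(path, EDGE_COLUMNS)
    out = pd.DataFrame()
    out["source_id"] = _numeric(df, "source_id", path, kind=np.int64)
    out["target_id"] = _numeric(df, "target_id", path, kind=np.int64)
    out["target_type"] = df["target_type"].to_numpy()
    out["weight"] = _numeric(df, "weight", path, kind=np.int64)
    return out


def write_edge_table(edges: pd.DataFrame, path: str | Path, comments: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        edges.loc[:, list(EDGE_COLUMNS)].to_csv(fh, sep="\t", index=False)


def read_cell_types(path: str | Path) -> dict[int, str]:
    """Read the cell-type table into an id -> label mapping ('' = unlabeled)."""
    df, _ = _read_tsv(path, ("cell_id", "type_label"))
    ids = _numeric(df, "cell_id", path, kind=np.int64)
    return dict(zip(ids.tolist(), df["type_label"].tolist()))


def write_cell_types(labels: Mapping[int, str], path: str | Path, comments: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("cell_id\ttype_label\n")
        for cid in sorted(labels):
            fh.write(f"{cid}\t{labels[cid]}\n")


def summarize_cells(synapses: pd.DataFrame, type_labels: Mapping[int, str] | None = None) -> pd.DataFrame:
    """Per-cell summary: polarity counts and neuropil membership.

    Returns one row per distinct cell_id with columns type_label, n_pre,
    n_post, n_total, neuropils (frozenset) and neuropil_counts (dict).
    """
    type_labels = type_labels or {}
    g = synapses.groupby("cell_id", sort=True)
    n_pre = g["polarity"].agg(lambda s: int((s == "pre").sum()))
    n_post = g["polarity"].agg(lambda s: int((s == "post").sum()))
    neuropils = g["neuropil"].agg(lambda s: frozenset(s))
    np_counts = g["neuropil"].agg(lambda s: dict(s.value_counts()))
    out = pd.DataFrame(
        {
            "cell_id": n_pre.index.to_numpy(),
            "type_label": [type_labels.get(cid, "") for cid in n_pre.index],
            "n_pre": n_pre.to_numpy(),
            "n_post": n_post.to_numpy(),
            "neuropils": neuropils.to_numpy(),
            "neuropil_counts": np_counts.to_numpy(),
        }
    )
    out["n_total"] = out["n_pre"] + out["n_post"]
    return out.reset_index(drop=True)


def select_cells_of_interest(
    cells: pd.DataFrame,
    min_sites: int = 50,
    max_sites: int = 500,
    neuropil: str = "LO",
    out_of_neuropil_tolerance: float = 0.0,
) -> set[int]:
    """Cells of interest: unlabeled, neuropil-confined, mid-sized fragments.

    A cell is selected when it has no type label, all its synapses lie in
    ``neuropil`` (up to the stated tolerance fraction), and its total site
    count lies strictly between ``min_sites`` and ``max_sites``.
    """
    if min_sites >= max_sites:
        raise InvalidArgumentError(f"min_sites ({min_sites}) must be < max_sites ({max_sites})")
    if not 0.0 <= out_of_neuropil_tolerance < 1.0:
        raise InvalidArgumentError("out_of_neuropil_tolerance must be in [0, 1)")
    selected: set[int] = set()
    for row in cells.itertuples(index=False):
        if row.type_label:
            continue
        if not (min_sites < row.n_total < max_sites):
            continue
        counts = row.neuropil_counts
        inside = counts.get(neuropil, 0)
        if inside == 0:
            continue
        if (row.n_total - inside) > out_of_neuropil_tolerance * row.n_total:
            continue
        selected.add(int(row.cell_id))
    return selected
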