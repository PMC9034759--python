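"""Synthetic connectome generator with known ground truth.

Emulates the statistical structure the typing pipeline relies on, so every
stage is testable without a connectome download:

* a reference tangential neuron whose postsynapses form a thin cloud on a
  curved parabolic surface (the stand-in for LT1's monostratified dendrites),
* populations of unlabeled columnar cells, each type with a characteristic
  depth-stratification mixture, tangential spread, per-cell synapse-count
  distribution, and a Poisson signature of synapse counts onto a panel of
  labeled downstream types,
* neuropil labels and labeled/unlabeled status, so the inclusion filter is
  exercisable.

The noise model is deliberately minimal: Gaussian tangential scatter around
a per-cell column centre, Gaussian normal scatter around the layer surface,
and Poisson connectivity counts. Everything is driven by one seeded
``numpy.random.Generator``, so identical (config, seed) gives bit-identical
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import special_ortho_group

from . import io as cio
from .exceptions import InvalidArgumentError
from .geometry import LayerFrame, quadric_surface

__all__ = [
    "TypeSpec",
    "SyntheticConnectome",
    "generate_reference_layer",
    "generate_columnar_cells",
    "default_fixture",
    "DEFAULT_COEFFS",
    "DEFAULT_TARGET_PANEL",
    "default_type_specs",
    "write_fixture",
]

#: Default layer-surface coefficients (a0..a5, um scale). These are of the
#: magnitude measured for the LT1 layer-2 surface in the hemibrain volume.
DEFAULT_COEFFS = np.array([-5.21, 4.04e-3, 4.04e-3, 3.17e-3, 7.65e-4, -1.22e-3])

#: Tangential half-widths of the synthetic neuropil (long, short axis; um).
DEFAULT_EXTENT = (60.0, 40.0)

#: Labeled downstream panel of the default fixture (projection/tangential types).
DEFAULT_TARGET_PANEL = (
    "LC4", "LC10", "LC11", "LC12", "LC15", "LC17",
    "LC25", "LPLC1", "LPLC2", "LT1", "LT87", "CT1",
)

_COI_ID0 = 10_000       # cells of interest
_REF_ID0 = 800_001      # reference tangential cells
_TARGET_ID0 = 900_000   # labeled downstream cells


@dataclass(frozen=True)
class TypeSpec:
    """Generative description of one columnar cell type.

    depth_modes is a stratification mixture: (mean depth um, SD um, weight)
    per dendritic stratum, weights summing to 1. conn_signature maps each
    downstream labeled type to the mean synapses/cell (a Poisson rate).
    """

    name: str
    n_cells: int
    depth_modes: tuple[tuple[float, float, float], ...]
    tangential_spread: tuple[float, float]
    presyn_count_range: tuple[int, int]
    conn_signature: Mapping[str, float] = field(default_factory=dict)
    labeled: bool = False

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise InvalidArgumentError(f"{self.name}: n_cells must be positive")
        w = sum(m[2] for m in self.depth_modes)
        if not self.depth_modes or abs(w - 1.0) > 1e-9:
            raise InvalidArgumentError(f"{self.name}: depth-mode weights must sum to 1 (got {w})")
        lo, hi = self.presyn_count_range
        if lo < 1 or hi < lo:
            raise InvalidArgumentError(f"{self.name}: invalid presyn_count_range {self.presyn_count_range}")
        if any(r < 0 for r in self.conn_signature.values()):
            raise InvalidArgumentError(f"{self.name}: connectivity rates must be >= 0")
        if any(s <= 0 for s in self.tangential_spread):
            raise InvalidArgumentError(f"{self.name}: tangential spreads must be positive")


@dataclass
class SyntheticConnectome:
    """A generated connectome export plus its generative ground truth."""

    synapses: pd.DataFrame
    edges: pd.DataFrame
    cell_types: dict[int, str]
    reference_postsynapses: np.ndarray
    ground_truth: dict[int, str]
    frame: LayerFrame        # the true generating frame (native -> layer)
    seed: int

    @property
    def n_synapses(self) -> int:
        return len(self.synapses)


def generate_reference_layer(
    coeffs=DEFAULT_COEFFS,
    n_points: int = 8000,
    extent: tuple[float, float] = DEFAULT_EXTENT,
    normal_noise_sd: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Thin synapse cloud on a parabolic surface, in layer-frame coordinates.

    Tangential coordinates are uniform over +/- the half-widths in ``extent``;
    the normal coordinate is the quadric surface value plus Gaussian noise.
    """
    if n_points < 6:
        raise InvalidArgumentError("n_points must be >= 6 (the quadric has 6 coefficients)")
    ex, ey = float(extent[0]), float(extent[1])
    if ex <= 0 or ey <= 0:
        raise InvalidArgumentError("extent half-widths must be positive")
    if normal_noise_sd < 0:
        raise InvalidArgumentError("normal_noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.uniform(-ex, ex, n_points)
    y = rng.uniform(-ey, ey, n_points)
    z = quadric_surface(coeffs, x, y) + rng.normal(0.0, normal_noise_sd, n_points)
    return np.column_stack([x, y, z])


def _sample_depths(rng: np.random.Generator, modes, n: int) -> np.ndarray:
    weights = np.array([m[2] for m in modes], dtype=float)
    counts = rng.multinomial(n, weights / weights.sum())
    parts = [rng.normal(m[0], m[1], k) for m, k in zip(modes, counts)]
    return rng.permutation(np.concatenate(parts)) if parts else np.empty(0)


def generate_columnar_cells(
    specs: Sequence[TypeSpec],
    frame_coeffs=DEFAULT_COEFFS,
    seed: int = 0,
    extent: tuple[float, float] = DEFAULT_EXTENT,
    neuropil: str = "LO",
    reference_type: str = "LT1",
    n_reference_cells: int = 4,
    n_reference_points: int = 8000,
    reference_noise_sd: float = 2.0,
    post_fraction: float = 0.4,
    max_total_sites: int | None = 499,
    dropout: float = 0.0,
    contaminant_fraction: float = 0.0,
    contaminant_neuropil: str = "ME",
) -> SyntheticConnectome:
    """Generate a full synthetic connectome export from type specifications.

    Cells are laid down in an internal layer frame (column centres uniform
    over the neuropil extent, Gaussian tangential scatter, depth from the
    stratification mixture mapped through the quadric surface), then rotated
    and translated by a seeded rigid transform into a "native" frame so the
    PCA stage has real work to do. Per-cell synapse counts onto each
    downstream labeled type are Poisson with the spec's rate, truncated so
    the labeled-partner count never exceeds the cell's presynapse count
    (keeps per-synapse partner fields and the edge table mutually
    consistent). Postsynapse counts are Poisson(post_fraction * n_pre),
    optionally capped so total sites stay below ``max_total_sites + 1``.
    """
    names = [s.name for s in specs]
    if not specs:
        raise InvalidArgumentError("need at least one TypeSpec")
    if len(set(names)) != len(names):
        raise InvalidArgumentError("duplicate type names in specs")
    if not 0.0 <= dropout < 1.0:
        raise InvalidArgumentError("dropout must be in [0, 1)")
    if not 0.0 <= contaminant_fraction < 1.0:
        raise InvalidArgumentError("contaminant_fraction must be in [0, 1)")

    rng = np.random.default_rng(seed)
    coeffs = np.asarray(frame_coeffs, dtype=float)

    # seeded rigid transform: layer frame -> native coordinates
    rotation = special_ortho_group.rvs(3, random_state=rng)
    translation = rng.uniform(-200.0, 200.0, 3)
    true_frame = LayerFrame(origin=translation, axes=rotation, coeffs=coeffs)

    def to_native(local: np.ndarray) -> np.ndarray:
        return local @ rotation + translation

    # downstream labeled cells (edge targets); a few bodies per type
    target_panel = sorted({t for s in specs for t in s.conn_signature})
    target_ids: dict[str, list[int]] = {}
    cell_types: dict[int, str] = {}
    for i, t in enumerate(target_panel):
        ids = [_TARGET_ID0 + 10 * i + j for j in range(3)]
        target_ids[t] = ids
        for cid in ids:
            cell_types[cid] = t

    frames: list[pd.DataFrame] = []
    edge_rows: list[tuple[int, int, str, int]] = []
    ground_truth: dict[int, str] = {}

    # reference tangential cells: thin postsynapse cloud on the surface
    ref_local = generate_reference_layer(coeffs, n_reference_points, extent, reference_noise_sd, rng)
    ref_native = to_native(ref_local)
    ref_owner = np.repeat(
        [_REF_ID0 + i for i in range(n_reference_cells)],
        np.diff(np.linspace(0, n_reference_points, n_reference_cells + 1).astype(int)),
    )
    for i in range(n_reference_cells):
        cell_types[_REF_ID0 + i] = reference_type
    frames.append(
        pd.DataFrame(
            {
                "cell_id": ref_owner,
                "x": ref_native[:, 0],
                "y": ref_native[:, 1],
                "z": ref_native[:, 2],
                "polarity": "post",
                "partner_id": pd.array([pd.NA] * n_reference_points, dtype="Int64"),
                "partner_type": "",
                "neuropil": neuropil,
            }
        )
    )

    next_id = _COI_ID0
    ex, ey = extent
    for spec in specs:
        for _ in range(spec.n_cells):
            cid = next_id
            next_id += 1
            ground_truth[cid] = spec.name
            if spec.labeled:
                cell_types[cid] = spec.name
            else:
                cell_types[cid] = ""

            lo, hi = spec.presyn_count_range
            n_pre = int(rng.integers(lo, hi + 1))
            n_post = int(rng.poisson(post_fraction * n_pre))
            if max_total_sites is not None:
                n_post = min(n_post, max(0, max_total_sites - n_pre))
            n_syn = n_pre + n_post

            centre = np.array([rng.uniform(-ex, ex), rng.uniform(-ey, ey)])
            sd_long, sd_short = spec.tangential_spread
            tx = centre[0] + rng.normal(0.0, sd_long, n_syn)
            ty = centre[1] + rng.normal(0.0, sd_short, n_syn)
            depth = _sample_depths(rng, spec.depth_modes, n_syn)
            tz = quadric_surface(coeffs, tx, ty) + depth
            native = to_native(np.column_stack([tx, ty, tz]))

            partner_id = np.full(n_syn, -1, dtype=np.int64)
            partner_type = np.array([""] * n_syn, dtype=object)
            cursor = 0
            for t in sorted(spec.conn_signature):
                k = int(rng.poisson(spec.conn_signature[t]))
                k = min(k, n_pre - cursor)  # keep partners within presynapse budget
                if k <= 0:
                    continue
                tids = rng.choice(target_ids[t], size=k)
                partner_id[cursor : cursor + k] = tids
                partner_type[cursor : cursor + k] = t
                for tid in np.unique(tids):
                    edge_rows.append((cid, int(tid), t, int(np.sum(tids == tid))))
                cursor += k

            polarity = np.array(["pre"] * n_pre + ["post"] * n_post, dtype=object)
            df = pd.DataFrame(
                {
                    "cell_id": cid,
                    "x": native[:, 0],
                    "y": native[:, 1],
                    "z": native[:, 2],
                    "polarity": polarity,
                    "partner_id": pd.array(
                        [pid if pid >= 0 else pd.NA for pid in partner_id], dtype="Int64"
                    ),
                    "partner_type": partner_type,
                    "neuropil": neuropil,
                }
            )
            if dropout > 0.0:
                keep = rng.random(n_syn) >= dropout
                df = df.loc[keep].reset_index(drop=True)
            frames.append(df)

    synapses = pd.concat(frames, ignore_index=True)
    if contaminant_fraction > 0.0:
        coi = synapses["cell_id"] >= _COI_ID0
        flip = coi & (rng.random(len(synapses)) < contaminant_fraction)
        synapses.loc[flip, "neuropil"] = contaminant_neuropil

    if dropout > 0.0:
        # recompute edges from surviving labeled presynapses
        lab = synapses[(synapses["polarity"] == "pre") & (synapses["partner_type"] != "")]
        g = lab.groupby(["cell_id", "partner_id", "partner_type"], sort=True).size()
        edges = g.reset_index()
        edges.columns = ["source_id", "target_id", "target_type", "weight"]
        edges["target_id"] = edges["target_id"].astype(np.int64)
    else:
        edges = pd.DataFrame(edge_rows, columns=list(cio.EDGE_COLUMNS))
        edges = edges.sort_values(["source_id", "target_id"], kind="stable").reset_index(drop=True)

    return SyntheticConnectome(
        synapses=synapses,
        edges=edges,
        cell_types=cell_types,
        reference_postsynapses=ref_native,
        ground_truth=ground_truth,
        frame=true_frame,
        seed=seed if isinstance(seed, int) else -1,
    )


def default_type_specs(n_cells: int = 60, noise_scale: float = 1.0) -> list[TypeSpec]:
    """Eight columnar types with pairwise-distinct stratification and wiring.

    Depth modes, tangential spreads and synapses/cell rates are loosely
    patterned on measured lobula columnar types (T3-, T2-, Tm4-, Tm9-like,
    etc.); ``noise_scale`` multiplies all scatter SDs to study how cluster
    recovery degrades as the populations blur together.
    """
    s = float(noise_scale)

    def modes(*ms):
        return tuple((mu, sd * s, w) for mu, sd, w in ms)

    common = dict(n_cells=n_cells, presyn_count_range=(60, 220))
    return [
        TypeSpec("T3", depth_modes=modes((2.5, 2.0, 1.0)), tangential_spread=(2.5 * s, 1.5 * s),
                 conn_signature={"LC17": 14.0, "LC11": 16.0, "LT1": 8.0}, **common),
        TypeSpec("T2", depth_modes=modes((-3.0, 2.5, 1.0)), tangential_spread=(4.0 * s, 2.0 * s),
                 conn_signature={"LC4": 11.5, "LC11": 3.8, "LPLC1": 2.5}, **common),
        TypeSpec("Tm4", depth_modes=modes((-6.0, 2.0, 0.4), (15.0, 2.0, 0.6)),
                 tangential_spread=(3.0 * s, 2.0 * s),
                 conn_signature={"LC4": 17.0, "LPLC1": 2.0, "LC12": 2.0}, **common),
        TypeSpec("Li-wide", depth_modes=modes((38.0, 3.0, 1.0)), tangential_spread=(12.0 * s, 10.0 * s),
                 conn_signature={"LC10": 7.6, "LC12": 5.0, "LT87": 4.0}, **common),
        TypeSpec("TmY9", depth_modes=modes((18.0, 2.0, 0.5), (28.0, 2.0, 0.5)),
                 tangential_spread=(10.0 * s, 4.0 * s),
                 conn_signature={"LC10": 3.0, "LC15": 2.7, "LPLC2": 1.5}, **common),
        TypeSpec("Tm20", depth_modes=modes((27.0, 2.0, 1.0)), tangential_spread=(2.0 * s, 2.0 * s),
                 conn_signature={"LC10": 4.0, "LC17": 2.0, "LC25": 1.0}, **common),
        TypeSpec("Tm5", depth_modes=modes((25.0, 2.5, 0.8), (10.0, 2.0, 0.2)),
                 tangential_spread=(3.0 * s, 2.0 * s),
                 conn_signature={"LC25": 12.0, "LC11": 3.0, "LC15": 2.0}, **common),
        TypeSpec("Tm9", depth_modes=modes((-15.0, 2.0, 1.0)), tangential_spread=(2.0 * s, 1.5 * s),
                 conn_signature={"CT1": 20.0}, **common),
    ]


def default_fixture(seed: int, noise_scale: float = 1.0) -> SyntheticConnectome:
    """The documented standard fixture: 8 unlabeled types x 60 cells.

    Connectivity signatures span a 12-type labeled downstream panel; the
    reference layer uses the default parabolic surface. Used throughout the
    test and acceptance suites.
    """
    return generate_columnar_cells(default_type_specs(noise_scale=noise_scale), seed=seed)


def type_specs_from_config(entries: Sequence[Mapping]) -> list[TypeSpec]:
    """Build TypeSpecs from flat config mappings (see RunConfig docs)."""
    specs = []
    for e in entries:
        specs.append(
            TypeSpec(
                name=e["name"],
                n_cells=int(e["n_cells"]),
                depth_modes=tuple(tuple(m) for m in e["depth_modes"]),
                tangential_spread=tuple(e["tangential_spread"]),
                presyn_count_range=tuple(int(v) for v in e["presyn_count_range"]),
                conn_signature=dict(e.get("conn_signature", {})),
                labeled=bool(e.get("labeled", False)),
            )
        )
    return specs


def write_fixture(sc: SyntheticConnectome, outdir: str | Path, comments: Sequence[str] = ()) -> dict[str, Path]:
    """Serialize a fixture in the TSV dialects the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "synapses": outdir / "synapses.tsv",
        "edges": outdir / "edges.tsv",
        "cell_types": outdir / "cell_types.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    cio.write_synapse_table(sc.synapses, paths["synapses"], comments=comments)
    cio.write_edge_table(sc.edges, paths["edges"], comments=comments)
    cio.write_cell_types(sc.cell_types, paths["cell_types"], comments=comments)
    with open(paths["ground_truth"], "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("cell_id\ttrue_type\n")
        for cid in sorted(sc.ground_truth):
            fh.write(f"{cid}\t{sc.ground_truth[cid]}\n")
    return paths
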