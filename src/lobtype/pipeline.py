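"""End-to-end orchestration: simulate -> frame -> features -> cluster -> project.

A run is a directory of text artifacts, each stamped with a hash of the
configuration that produced it. Stages are restartable: each one reads only
the artifacts of upstream stages, so partial re-runs reproduce the monolithic
run byte for byte. Identical (config, seed) gives identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import features as ft
from . import io as cio
from . import projection as pj
from . import synth
from .exceptions import DependencyError, InvalidArgumentError
from .geometry import LayerFrame, build_layer_frame, frame_points

__all__ = ["RunConfig", "run_pipeline", "run_stage", "STAGES"]

STAGES = ("simulate", "fit-frame", "features", "cluster", "project", "report")


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with the study's values as defaults."""

    seed: int = 0
    # input: either a simulate-spec or paths to existing exports
    simulate: bool = True
    fixture: str = "default"            # "default" or "custom" (needs type_specs)
    type_specs: list | None = None      # list of TypeSpec mappings when custom
    noise_scale: float = 1.0
    synapse_table: str | None = None    # used when simulate=False
    edge_table: str | None = None
    cell_type_table: str | None = None
    # inclusion criteria
    reference_type: str = "LT1"
    min_sites: int = 50
    max_sites: int = 500
    neuropil: str = "LO"
    out_of_neuropil_tolerance: float = 0.0
    # morphology features
    depth_lo: float = -20.0
    depth_hi: float = 50.0
    depth_bin_width: float = 5.0
    smoothing_kernel: tuple = (0.25, 0.5, 0.25)
    morphology_polarity: str = "pre"
    # feature assembly
    block_weights: tuple = (5.0, 1.0, 3.0)
    normalization_mode: str = "sqrt"
    # clustering
    K: int = 40
    embed: bool = False
    # projection inputs
    target_panel: list | None = None    # None = all labeled downstream types
    lump_threshold: float = 0.05
    target_linkage: str = "ward"

    def validate(self) -> None:
        if self.min_sites >= self.max_sites:
            raise InvalidArgumentError("min_sites must be < max_sites")
        if self.K < 1:
            raise InvalidArgumentError("K must be >= 1")
        if not 0.0 <= self.lump_threshold < 1.0:
            raise InvalidArgumentError("lump_threshold must be in [0, 1)")
        if self.morphology_polarity not in ("pre", "post"):
            raise InvalidArgumentError("morphology_polarity must be 'pre' or 'post'")
        if not self.simulate and not (self.synapse_table and self.edge_table and self.cell_type_table):
            raise InvalidArgumentError("simulate=False requires synapse_table, edge_table and cell_type_table")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for name in ("smoothing_kernel", "block_weights"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["smoothing_kernel"] = list(self.smoothing_kernel)
        d["block_weights"] = list(self.block_weights)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @property
    def config_hash(self) -> str:
        d = asdict(self)
        d["smoothing_kernel"] = list(self.smoothing_kernel)
        d["block_weights"] = list(self.block_weights)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _log(rundir: Path, stage: str, lines: Sequence[str], cfg: RunConfig | None = None) -> None:
    logdir = rundir / "log"
    logdir.mkdir(exist_ok=True)
    header = [f"config_hash={cfg.config_hash}"] if cfg is not None else []
    (logdir / f"{stage.replace('-', '_')}.log").write_text(
        "".join(f"[{stage}] {ln}\n" for ln in (*header, *lines))
    )


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(f"stage '{stage}' requires missing upstream artifact: {path.name}")
    return path


def _load_inputs(cfg: RunConfig, rundir: Path, stage: str):
    syn = cio.read_synapse_table(_need(rundir / "synapses.tsv", stage))
    edges = cio.read_edge_table(_need(rundir / "edges.tsv", stage))
    types = cio.read_cell_types(_need(rundir / "cell_types.tsv", stage))
    return syn, edges, types


def stage_simulate(cfg: RunConfig, rundir: Path) -> None:
    comments = [f"config_hash={cfg.config_hash}"]
    if cfg.simulate:
        if cfg.fixture == "default":
            sc = synth.default_fixture(cfg.seed, noise_scale=cfg.noise_scale)
        else:
            specs = synth.type_specs_from_config(cfg.type_specs or [])
            sc = synth.generate_columnar_cells(specs, seed=cfg.seed)
        synth.write_fixture(sc, rundir, comments=comments)
        lines = [
            f"generated {len(sc.ground_truth)} ground-truth cells, {sc.n_synapses} synapses",
            f"labeled downstream panel: {sorted(set(sc.cell_types.values()) - {'', cfg.reference_type})}",
        ]
    else:
        syn = cio.read_synapse_table(cfg.synapse_table)
        edges = cio.read_edge_table(cfg.edge_table)
        types = cio.read_cell_types(cfg.cell_type_table)
        cio.write_synapse_table(syn, rundir / "synapses.tsv", comments=comments)
        cio.write_edge_table(edges, rundir / "edges.tsv", comments=comments)
        cio.write_cell_types(types, rundir / "cell_types.tsv", comments=comments)
        lines = [f"imported {len(syn)} synapses, {len(edges)} edges"]
    _log(rundir, "simulate", lines, cfg)


def stage_fit_frame(cfg: RunConfig, rundir: Path) -> None:
    syn, _, types = _load_inputs(cfg, rundir, "fit-frame")
    ref_ids = [cid for cid, t in types.items() if t == cfg.reference_type]
    ref = syn[syn["cell_id"].isin(ref_ids) & (syn["polarity"] == "post")]
    if ref.empty:
        raise DependencyError(f"no postsynapses of reference type '{cfg.reference_type}' found")
    pts = ref[["x", "y", "z"]].to_numpy(dtype=float)
    frame = build_layer_frame(pts)
    frame.save(rundir / "frame.json", config_hash=cfg.config_hash)
    _log(
        rundir,
        "fit-frame",
        [
            f"reference postsynapses: {len(ref)} from {len(ref_ids)} cells",
            f"coeffs a0..a5: {np.array2string(frame.coeffs, precision=4)}",
            f"r2={frame.r2:.4f}",
        ],
        cfg,
    )


def stage_features(cfg: RunConfig, rundir: Path) -> None:
    syn, edges, types = _load_inputs(cfg, rundir, "features")
    frame = LayerFrame.load(_need(rundir / "frame.json", "features"))
    cells = cio.summarize_cells(syn, types)
    coi = sorted(
        cio.select_cells_of_interest(
            cells, cfg.min_sites, cfg.max_sites, cfg.neuropil, cfg.out_of_neuropil_tolerance
        )
    )
    if len(coi) < 2:
        raise DependencyError("fewer than 2 cells of interest survive the inclusion filter")
    hist_kw = dict(lo=cfg.depth_lo, hi=cfg.depth_hi, width=cfg.depth_bin_width)
    morph = syn[syn["cell_id"].isin(coi) & (syn["polarity"] == cfg.morphology_polarity)]
    framed = frame_points(morph[["x", "y", "z"]].to_numpy(dtype=float), frame)
    framed["cell_id"] = morph["cell_id"].to_numpy()

    n_bins = int(round((cfg.depth_hi - cfg.depth_lo) / cfg.depth_bin_width))
    spread_rows, hist_rows, smooth_rows = [], [], []
    for cid in coi:
        g = framed[framed["cell_id"] == cid]
        spread_rows.append(ft.synapse_spread(g))
        h = ft.innervation_depth_hist(g["depth"].to_numpy(), **hist_kw)
        hist_rows.append(h)
        smooth_rows.append(ft.smooth_depth_hist(h, cfg.smoothing_kernel))
    idx = pd.Index(coi, name="cell_id")
    spreads = pd.DataFrame(spread_rows, index=idx, columns=["e1", "e2", "e3"])
    hists = pd.DataFrame(hist_rows, index=idx, columns=[f"bin{i + 1:02d}" for i in range(n_bins)])
    smoothed = pd.DataFrame(smooth_rows, index=idx, columns=hists.columns)
    conn = ft.connectivity_matrix(coi, edges)
    fm = ft.assemble_feature_matrix(conn, spreads, smoothed, cfg.block_weights, cfg.normalization_mode)

    comments = [f"config_hash={cfg.config_hash}"]
    fm.save(rundir / "features.tsv", comments=comments)
    for name, df in (("spreads", spreads), ("depth_hists", hists), ("conn_counts", conn)):
        with open(rundir / f"{name}.tsv", "w") as fh:
            for c in comments:
                fh.write(f"# {c}\n")
            df.rename_axis("cell_id").to_csv(fh, sep="\t", float_format="%.12g")
    (rundir / "normalization.json").write_text(
        json.dumps(
            {
                "config_hash": cfg.config_hash,
                "mode": cfg.normalization_mode,
                "block_weights": list(cfg.block_weights),
                "total_dispersion": fm.normalization_record,
            },
            indent=1,
        )
        + "\n"
    )
    _log(
        rundir,
        "features",
        [
            f"cells summarized: {len(cells)}; cells of interest: {len(coi)}",
            f"connectivity panel: {conn.shape[1]} labeled downstream types",
            f"feature matrix: {fm.values.shape[0]} x {fm.values.shape[1]}",
        ],
        cfg,
    )


def _read_feature_matrix(rundir: Path, stage: str) -> pd.DataFrame:
    path = _need(rundir / "features.tsv", stage)
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.set_index("cell_id")


def stage_cluster(cfg: RunConfig, rundir: Path) -> None:
    fm = _read_feature_matrix(rundir, "cluster")
    K = min(cfg.K, len(fm))
    assignment = cl.ward_cluster(fm, K)
    comments = [f"config_hash={cfg.config_hash}"]
    with open(rundir / "assignment.tsv", "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("cell_id\tcluster\n")
        for cid in assignment.cell_ids:
            fh.write(f"{cid}\t{assignment.labels[cid]}\n")
    with open(rundir / "linkage.tsv", "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("child1\tchild2\theight\tsize\n")
        for row in assignment.linkage:
            fh.write(f"{int(row[0])}\t{int(row[1])}\t{row[2]:.12g}\t{int(row[3])}\n")
    newick = cl.linkage_to_newick(assignment.linkage, [str(c) for c in assignment.cell_ids])
    (rundir / "dendrogram.nwk").write_text(f"[config_hash={cfg.config_hash}]" + newick + "\n")

    lines = [f"clustered {len(fm)} cells into K={K} clusters"]
    gt_path = rundir / "ground_truth.tsv"
    if gt_path.exists():
        gt = pd.read_csv(gt_path, sep="\t", comment="#").set_index("cell_id")["true_type"]
        common = [c for c in assignment.cell_ids if c in gt.index]
        if common:
            from sklearn.metrics import adjusted_rand_score

            ari = adjusted_rand_score(gt.loc[common], [assignment.labels[c] for c in common])
            (rundir / "metrics.json").write_text(
                json.dumps({"config_hash": cfg.config_hash, "ari_vs_ground_truth": ari, "n": len(common)}, indent=1)
                + "\n"
            )
            lines.append(f"ARI vs ground truth: {ari:.4f} over {len(common)} cells")
    if cfg.embed:
        emb = cl.embed_2d(fm.to_numpy(dtype=float), seed=cfg.seed)
        with open(rundir / "umap.tsv", "w") as fh:
            for c in comments:
                fh.write(f"# {c}\n")
            pd.DataFrame(emb, index=fm.index, columns=["u1", "u2"]).to_csv(
                fh, sep="\t", float_format="%.6g"
            )
        lines.append("wrote 2-D embedding (visualization only)")
    _log(rundir, "cluster", lines, cfg)


def _read_assignment(rundir: Path, stage: str) -> dict[int, int]:
    path = _need(rundir / "assignment.tsv", stage)
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["cell_id"].astype(int), df["cluster"].astype(int)))


def stage_project(cfg: RunConfig, rundir: Path) -> None:
    _, edges, types = _load_inputs(cfg, rundir, "project")
    labels = _read_assignment(rundir, "project")
    if cfg.target_panel:
        panel = list(cfg.target_panel)
    else:
        labeled = {t for t in types.values() if t}
        panel = sorted(labeled & set(edges["target_type"].unique()))
    rc = pj.relative_input_fractions(edges, labels, panel)
    comments = [f"config_hash={cfg.config_hash}"]
    rc.save(rundir / "relative_connectivity.tsv", comments=comments)
    lumped = pj.lump_minor_clusters(rc, cfg.lump_threshold)
    lumped.save(rundir / "relative_connectivity_lumped.tsv", comments=comments)
    _, names, newick = pj.cluster_targets(rc, method=cfg.target_linkage)
    (rundir / "targets.nwk").write_text(f"[config_hash={cfg.config_hash}]" + newick + "\n")
    _log(
        rundir,
        "project",
        [
            f"target panel: {len(panel)} types ({len(rc.flagged)} flagged zero-input)",
            f"target dendrogram over {len(names)} types",
        ],
        cfg,
    )


def stage_report(cfg: RunConfig, rundir: Path) -> None:
    _, edges, _ = _load_inputs(cfg, rundir, "report")
    labels = _read_assignment(rundir, "report")
    hists = pd.read_csv(_need(rundir / "depth_hists.tsv", "report"), sep="\t", comment="#").set_index("cell_id")
    spreads = pd.read_csv(_need(rundir / "spreads.tsv", "report"), sep="\t", comment="#").set_index("cell_id")
    Zdf = pd.read_csv(_need(rundir / "linkage.tsv", "report"), sep="\t", comment="#")
    Z = Zdf.to_numpy(dtype=float)
    cell_ids = list(hists.index)
    assignment = cl.ClusterAssignment(labels=labels, linkage=Z, K=max(labels.values()), cell_ids=cell_ids)
    summaries = cl.cluster_summary(assignment, hists, spreads, edges, top_n=10)
    for s in summaries:
        fractions, dominant = cl.annotate_layers(
            s["mean_depth_hist"], lo=cfg.depth_lo, width=cfg.depth_bin_width
        )
        s["layer_fractions"] = fractions
        s["dominant_layers"] = dominant
    payload = {"config_hash": cfg.config_hash, "clusters": summaries}
    (rundir / "summaries.json").write_text(json.dumps(payload, indent=1) + "\n")
    _log(rundir, "report", [f"summarized {len(summaries)} clusters"], cfg)


_STAGE_FN = {
    "simulate": stage_simulate,
    "fit-frame": stage_fit_frame,
    "features": stage_features,
    "cluster": stage_cluster,
    "project": stage_project,
    "report": stage_report,
}


def run_stage(cfg: RunConfig, rundir: str | Path, stage: str) -> Path:
    """Run one pipeline stage against an existing run directory."""
    if stage not in _STAGE_FN:
        raise InvalidArgumentError(f"unknown stage '{stage}'; choose from {STAGES}")
    cfg.validate()
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(rundir / "config.yaml")
    _STAGE_FN[stage](cfg, rundir)
    return rundir


def run_pipeline(cfg: RunConfig, rundir: str | Path) -> Path:
    """Run every stage in order; aborts on the first failing stage."""
    cfg.validate()
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(rundir / "config.yaml")
    for stage in STAGES:
        try:
            _STAGE_FN[stage](cfg, rundir)
        except Exception as exc:
            (rundir / "INCOMPLETE").write_text(f"stage={stage}\nerror={exc}\n")
            raise
    incomplete = rundir / "INCOMPLETE"
    if incomplete.exists():
        incomplete.unlink()
    return rundir
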