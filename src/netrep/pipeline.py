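"""End-to-end pipeline driver and report emitters.

A :class:`PipelineConfig` (YAML-serializable) names the inputs — either a
synthetic landscape to generate or rasters/GeoJSON on disk — and the
stage parameters.  :func:`run_pipeline` executes
synth -> pca -> represent -> constituency -> complement, writes every
reported number as CSV (plots, when requested, are side-effects drawn
from those CSVs), and returns a manifest with config, versions, per-stage
wall time and sha256 checksums of all emitted files, so a rerun with the
same config and seed is byte-identical up to timing fields.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import gaussian_kde

from . import __version__
from .complement import best_network_map, candidate_gaps
from .constituency import (assign_constituency, classify_sites,
                           constituency_areas, site_gradient_ranges)
from .grid import CategoricalGrid, GridStack
from .io import (read_categorical_grid, read_features, read_grid,
                 write_categorical_grid, write_features, write_grid)
from .pca import fit_pca, select_components
from .represent import (RepresentativenessResult, normalization_constant,
                        site_representativeness)
from .sites import (filter_by_mask_class, network_to_features,
                    polygons_to_centroids, sample_centroids)
from .synth import (LandscapeSpec, MaskConfig, NetworkSpec, generate_fields,
                    generate_mask, generate_network)

logger = logging.getLogger(__name__)

WORKING_CLASSES = ["cropland", "grazingland", "mixed"]

DEFAULT_STAGES = ["synth", "pca", "represent", "constituency", "complement"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    out_dir: str = "netrep_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(DEFAULT_STAGES))
    # synthetic inputs (used when no paths are given)
    landscape: dict = field(default_factory=dict)
    mask: dict | None = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    sisters: list[dict] = field(default_factory=list)
    # on-disk inputs (override synthesis when set)
    paths: dict = field(default_factory=dict)
    # stage parameters
    pca: dict = field(default_factory=lambda: {"standardize": True,
                                               "threshold": 0.90})
    representativeness: dict = field(default_factory=lambda: {
        "aggregation": "max", "norm_method": "bbox_diameter",
        "tile_size": None})
    constituency: dict = field(default_factory=lambda: {
        "top_n": 3, "classes": list(WORKING_CLASSES),
        "area_quantile": 0.5, "rep_floor": 0.8, "cell_area_ha": None})
    complement: dict = field(default_factory=lambda: {
        "k_gaps": 5, "min_separation": 5.0, "restrict_sisters": True})
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _cell_area_ha(transform) -> float:
    return transform.cell_width * transform.cell_height / 1e4


def summarize_by_class(rep: RepresentativenessResult,
                       mask: CategoricalGrid,
                       grid_points: int = 281) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-mask-class statistics and density curves of network representativeness.

    Returns (stats, curves): stats has mean/median/sd/n per class (absent
    classes flagged empty); curves holds a Gaussian KDE (Silverman
    bandwidth) per class, evaluated on a grid extending slightly beyond
    [0, 1] so each curve integrates to ~1.
    """
    vals = rep.network.values
    xs = np.linspace(-0.2, 1.2, grid_points)
    stat_rows, curve_frames = [], []
    for code in sorted(mask.class_table):
        cls = mask.class_table[code]
        pick = rep.network.valid & mask.valid & (mask.codes == code)
        x = vals[pick]
        row = {"mask_class": cls, "n_cells": int(x.size), "empty": x.size == 0}
        if x.size:
            row.update(mean=float(x.mean()), median=float(np.median(x)),
                       sd=float(x.std(ddof=0)))
            if x.size > 1 and x.std() > 0:
                dens = gaussian_kde(x, bw_method="silverman")(xs)
                curve_frames.append(pd.DataFrame(
                    {"mask_class": cls, "representativeness": xs,
                     "density": dens}))
        else:
            row.update(mean=np.nan, median=np.nan, sd=np.nan)
        stat_rows.append(row)
    curves = (pd.concat(curve_frames, ignore_index=True) if curve_frames
              else pd.DataFrame(columns=["mask_class", "representativeness",
                                         "density"]))
    return pd.DataFrame(stat_rows), curves


def _load_or_synth(cfg: PipelineConfig, out: Path, manifest: dict):
    """Stage 1: obtain stack, mask, home network and sister networks."""
    paths = cfg.paths or {}
    if paths.get("stack"):
        stack_paths = sorted(Path(paths["stack"]).glob("*"))
        layers = [read_grid(p) for p in stack_paths
                  if p.suffix.lower() in (".asc", ".csv", ".txt", ".tif", ".tiff")]
        names = [p.stem for p in stack_paths
                 if p.suffix.lower() in (".asc", ".csv", ".txt", ".tif", ".tiff")]
        stack = GridStack(layers, names)
        manifest["inputs"] = {str(p): _sha256(Path(p)) for p in stack_paths}
    else:
        lspec = LandscapeSpec(seed=cfg.seed, **cfg.landscape)
        stack = generate_fields(lspec)
        manifest["landscape_spec"] = {k: (v.tolist() if isinstance(v, np.ndarray)
                                          else v)
                                      for k, v in asdict(lspec).items()}
    mask = None
    if paths.get("mask"):
        mask = read_categorical_grid(paths["mask"], paths["mask_classes"])
    elif cfg.mask is not None:
        mask = generate_mask(stack, MaskConfig(**cfg.mask))
        write_categorical_grid(out / "mask.asc", mask, out / "mask_classes.yaml")

    if paths.get("network"):
        home = polygons_to_centroids(read_features(paths["network"]),
                                     name=Path(paths["network"]).stem)
    else:
        nspec = NetworkSpec(seed=cfg.seed + 1, name="home", **cfg.network)
        home = generate_network(stack, nspec)
        write_features(out / "network_home.geojson", network_to_features(home))

    sisters = []
    for i, spath in enumerate(paths.get("sisters", [])):
        sisters.append(polygons_to_centroids(read_features(spath),
                                             name=Path(spath).stem))
    if not sisters:
        for i, skw in enumerate(cfg.sisters):
            sspec = NetworkSpec(seed=cfg.seed + 2 + i, name=f"sister_{i + 1}",
                                **skw)
            net = generate_network(stack, sspec)
            write_features(out / f"network_{net.name}.geojson",
                           network_to_features(net))
            sisters.append(net)
    return stack, mask, home, sisters


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages; write reports; return the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "numpy": np.__version__,
                      "seed": cfg.seed, "config": asdict(cfg),
                      "stage_seconds": {}, "checksums": {}}
    state: dict = {}

    def stage(name, fn):
        if name not in cfg.stages:
            return
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        manifest["stage_seconds"][name] = round(dt, 3)
        logger.info("stage %s done in %.2fs", name, dt)

    def s_synth():
        state["stack"], state["mask"], state["home"], state["sisters"] = (
            _load_or_synth(cfg, out, manifest))
        st = state["stack"]
        logger.info("inputs: stack %s x %d layers, %d jointly valid cells",
                    st.shape, len(st), int(st.joint_valid.sum()))

    def s_pca():
        fs = fit_pca(state["stack"], standardize=cfg.pca.get("standardize", True))
        fs = select_components(fs, cfg.pca.get("threshold", 0.90))
        state["fs"] = fs
        cum = np.cumsum(fs.variance_fraction)
        pd.DataFrame({
            "component": [f"pc_{k + 1}" for k in range(fs.n_components)],
            "variance_fraction": fs.variance_fraction,
            "cumulative": cum,
            "selected": np.arange(fs.n_components) < fs.n_selected,
        }).to_csv(out / "scree.csv", index=False)
        pd.DataFrame(fs.loadings,
                     index=pd.Index(fs.layer_names, name="layer"),
                     columns=[f"pc_{k + 1}" for k in range(fs.n_components)]
                     ).to_csv(out / "loadings.csv")
        logger.info("pca: selected %d/%d components", fs.n_selected,
                    fs.n_components)

    def s_represent():
        fs = state["fs"]
        home = sample_centroids(state["home"], fs)
        state["home"] = home
        rcfg = cfg.representativeness
        norm = normalization_constant(fs, rcfg.get("norm_method",
                                                   "bbox_diameter"),
                                      net=home,
                                      tile_size=rcfg.get("tile_size"))
        state["norm"] = norm
        rep = site_representativeness(home, fs, norm,
                                      aggregation=rcfg.get("aggregation", "max"),
                                      tile_size=rcfg.get("tile_size"))
        state["rep"] = rep
        write_grid(out / "network_representativeness.asc", rep.network,
                   fmt="%.6f")
        for site, g in rep.per_site.items():
            write_grid(out / f"site_rep_{site}.asc", g, fmt="%.6f")
        rows = [{"site": c.site, "centroid_id": c.centroid_id,
                 "x": c.x, "y": c.y, "row": c.cell[0], "col": c.cell[1],
                 **{f"pc_{k + 1}": float(v)
                    for k, v in enumerate(c.pc_values)}}
                for c in home.centroids]
        pd.DataFrame(rows).to_csv(out / "centroids.csv", index=False)
        if state.get("mask") is not None:
            stats, curves = summarize_by_class(rep, state["mask"])
            stats.to_csv(out / "class_summary.csv", index=False)
            curves.to_csv(out / "density_curves.csv", index=False)
        gaps = candidate_gaps(rep, state.get("mask"),
                              classes=(cfg.constituency.get("classes")
                                       if state.get("mask") is not None else None),
                              k=cfg.complement.get("k_gaps", 5),
                              min_separation=cfg.complement.get(
                                  "min_separation", 5.0))
        gaps.to_csv(out / "gaps.csv", index=False)

    def s_constituency():
        if state.get("mask") is None:
            raise ValueError("constituency requires a mask; provide one or "
                             "drop 'constituency' from stages")
        ccfg = cfg.constituency
        cr = assign_constituency(state["rep"], state["mask"],
                                 classes=ccfg.get("classes"),
                                 top_n=ccfg.get("top_n", 3))
        state["cr"] = cr
        write_categorical_grid(out / "constituency_winner.asc", cr.winner)
        pd.DataFrame({"code": list(cr.winner.class_table),
                      "site": list(cr.winner.class_table.values())}
                     ).to_csv(out / "constituency_legend.csv", index=False)
        cr.ranks_table().to_csv(out / "constituency_ranks.csv", index=False)
        cell_area = ccfg.get("cell_area_ha") or _cell_area_ha(
            state["rep"].network.transform)
        constituency_areas(cr, cell_area).to_csv(
            out / "constituency_summary.csv", index=False)
        site_gradient_ranges(state["home"], state["fs"]).to_csv(
            out / "site_gradient_ranges.csv", index=False)
        classify_sites(cr, ccfg.get("area_quantile", 0.5),
                       ccfg.get("rep_floor", 0.8)).to_csv(
            out / "site_classification.csv", index=False)

    def s_complement():
        if not state["sisters"]:
            logger.info("complement: no sister networks configured; skipped")
            return
        fs, mask = state["fs"], state.get("mask")
        classes = cfg.constituency.get("classes")
        sisters = []
        for net in state["sisters"]:
            net = sample_centroids(net, fs)
            if (mask is not None and
                    cfg.complement.get("restrict_sisters", True)):
                net = filter_by_mask_class(net, mask, classes or WORKING_CLASSES)
            if len(net):
                sisters.append(net)
        if not sisters:
            logger.warning("complement: all sister centroids filtered out")
            return
        mn = best_network_map([state["home"], *sisters], fs, state["norm"],
                              mask=mask, classes=classes,
                              tile_size=cfg.representativeness.get("tile_size"))
        state["multi"] = mn
        write_categorical_grid(out / "best_network.asc", mn.best_network)
        write_grid(out / "improvement.asc", mn.improvement, fmt="%.6f")
        mn.borrowed_sites.to_csv(out / "borrowed_sites.csv", index=False)

    stage("synth", s_synth)
    stage("pca", s_pca)
    stage("represent", s_represent)
    stage("constituency", s_constituency)
    stage("complement", s_complement)

    if cfg.plots:
        _emit_plots(out, state)

    cfg.to_yaml(out / "config.yaml")
    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["checksums"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _emit_plots(out: Path, state: dict) -> None:
    """Optional figures; every plotted number already lives in a CSV."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "rep" in state:
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(state["rep"].network.filled(np.nan), vmin=0, vmax=1,
                       cmap="viridis")
        fig.colorbar(im, ax=ax, label="network representativeness")
        ax.set_title("Network representativeness")
        fig.savefig(out / "network_representativeness.png", dpi=120)
        plt.close(fig)
    if "cr" in state:
        fig, ax = plt.subplots(figsize=(6, 5))
        codes = state["cr"].winner.codes.astype(float)
        codes[~state["cr"].winner.valid] = np.nan
        ax.imshow(codes, cmap="tab20")
        ax.set_title("Constituency (winning site)")
        fig.savefig(out / "constituency.png", dpi=120)
        plt.close(fig)
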