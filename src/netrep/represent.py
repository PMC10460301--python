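"""The representativeness surface: 1 − normalized Euclidean PC-space distance.

For a sampled centroid with score vector v and a grid cell with score
vector u, representativeness is

    r = 1 − ‖v − u‖ / D

where D is a normalization constant making the distance term lie in
[0, 1].  Two choices of D are provided:

* ``bbox_diameter`` (default): the Euclidean length of the per-component
  (max − min) range vector over all valid cells.  It depends only on the
  landscape, never on the site set, so adding sites can only raise
  representativeness and values are commensurable across networks.
* ``observed_max``: the exact maximum (centroid, cell) distance, computed
  in a second pass; faithful to "the furthest observed pair scores 0" but
  site-set dependent.

Per-site layers aggregate centroid layers cellwise (default ``max``;
``mean`` and ``sum`` available — ``sum`` can exceed 1 and is flagged).
The network layer is always the cellwise maximum over *all* centroids of
all sites, independent of the site-level aggregation choice.

All accumulation is double precision; computation is tiled over cells so
memory stays bounded at any landscape size, and results are independent
of the tile size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.spatial.distance import cdist

from .grid import Grid
from .pca import FeatureSpace
from .sites import Centroid, SiteNetwork

logger = logging.getLogger(__name__)

AGGREGATIONS = ("max", "mean", "sum")


@dataclass(frozen=True)
class NormalizationConstant:
    value: float
    method: str

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("normalization constant must be > 0")


@dataclass
class RepresentativenessResult:
    per_site: dict[str, Grid]
    network: Grid
    norm: NormalizationConstant
    aggregation: str

    @property
    def sites(self) -> list[str]:
        return list(self.per_site)

    def site_matrix(self) -> np.ndarray:
        """(n_valid, n_sites) per-site representativeness at valid cells."""
        v = self.network.valid
        return np.column_stack([g.values[v] for g in self.per_site.values()])


def _tiles(n: int, tile_size: int | None) -> Iterator[slice]:
    step = n if not tile_size else max(1, int(tile_size))
    for start in range(0, n, step):
        yield slice(start, min(start + step, n))


def normalization_constant(fs: FeatureSpace, method: str = "bbox_diameter",
                           net: SiteNetwork | None = None,
                           tile_size: int | None = None) -> NormalizationConstant:
    """Compute the distance-normalizing divisor for *fs*.

    ``observed_max`` requires the sampled network whose (centroid, cell)
    pairs define the maximum.
    """
    S = fs.score_matrix()
    if S.shape[0] < 2:
        raise ValueError("need at least 2 valid cells")
    if method == "bbox_diameter":
        span = S.max(axis=0) - S.min(axis=0)
        value = float(np.sqrt((span ** 2).sum()))
        if value == 0:
            raise ValueError("all cells identical in PC space; "
                             "representativeness undefined")
        return NormalizationConstant(value, method)
    if method == "observed_max":
        if net is None:
            raise ValueError("observed_max normalization needs a sampled network")
        C = net.pc_matrix()
        dmax = 0.0
        for sl in _tiles(S.shape[0], tile_size):
            dmax = max(dmax, float(cdist(S[sl], C).max()))
        if dmax == 0:
            raise ValueError("zero maximum distance; representativeness undefined")
        return NormalizationConstant(dmax, method)
    raise ValueError(f"unknown normalization method {method!r}")


def _rep_rows(S_tile: np.ndarray, C: np.ndarray, norm_value: float) -> np.ndarray:
    """Representativeness of every centroid (cols) at each tile cell (rows)."""
    return 1.0 - cdist(S_tile, C) / norm_value


def centroid_representativeness(c: Centroid, fs: FeatureSpace,
                                norm: NormalizationConstant,
                                tile_size: int | None = None) -> Grid:
    """Representativeness map of a single sampled centroid."""
    if c.pc_values is None:
        raise ValueError(f"centroid {c.centroid_id} not sampled")
    if c.pc_values.shape[0] != fs.n_selected:
        raise ValueError(
            f"centroid has {c.pc_values.shape[0]} PC values, feature space "
            f"selects {fs.n_selected}")
    S = fs.score_matrix()
    C = c.pc_values[None, :]
    flat = np.empty(S.shape[0])
    for sl in _tiles(S.shape[0], tile_size):
        flat[sl] = _rep_rows(S[sl], C, norm.value)[:, 0]
    return _flat_to_grid(_clip_logged(flat, f"centroid {c.centroid_id}"), fs)


def _clip_logged(r: np.ndarray, what: str) -> np.ndarray:
    n_clip = int((r < 0).sum() + (r > 1).sum())
    if n_clip:
        logger.info("representativeness: clipped %d value(s) to [0, 1] for %s",
                    n_clip, what)
    return np.clip(r, 0.0, 1.0)


def _flat_to_grid(flat: np.ndarray, fs: FeatureSpace) -> Grid:
    v = fs.valid
    out = np.full(v.shape, np.nan)
    out[v] = flat
    return Grid(out, v.copy(), fs.scores.transform, fs.scores.crs_label,
                nodata=np.nan)


def site_representativeness(net: SiteNetwork, fs: FeatureSpace,
                            norm: NormalizationConstant,
                            aggregation: str = "max",
                            tile_size: int | None = None) -> RepresentativenessResult:
    """Per-site and network representativeness layers for a sampled network."""
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
    if len(net) == 0:
        raise ValueError("empty network")
    C = net.pc_matrix()
    if C.shape[1] != fs.n_selected:
        raise ValueError("network sampled on a different feature space")
    S = fs.score_matrix()
    n_cells = S.shape[0]
    site_rows = net.site_rows()
    sites = list(site_rows)

    site_flat = {s: np.empty(n_cells) for s in sites}
    net_flat = np.empty(n_cells)
    n_clip = 0
    for sl in _tiles(n_cells, tile_size):
        R = _rep_rows(S[sl], C, norm.value)  # (tile, n_centroids)
        # clip at the centroid level so mean/sum aggregate [0,1] maps;
        # can only trigger at floating-point edges or under observed_max
        n_clip += int((R < 0).sum() + (R > 1).sum())
        np.clip(R, 0.0, 1.0, out=R)
        for s in sites:
            block = R[:, site_rows[s]]
            if aggregation == "max":
                site_flat[s][sl] = block.max(axis=1)
            elif aggregation == "mean":
                site_flat[s][sl] = block.mean(axis=1)
            else:
                site_flat[s][sl] = block.sum(axis=1)
        net_flat[sl] = R.max(axis=1)

    if n_clip:
        logger.info("site_representativeness: clipped %d centroid value(s) "
                    "to [0, 1] for network %s", n_clip, net.name)
    per_site: dict[str, Grid] = {}
    for s in sites:
        vals = site_flat[s]
        if aggregation == "sum":
            n_over = int((vals > 1).sum())
            if n_over:
                logger.warning("site %s: 'sum' aggregation produced %d cell(s) "
                               "above 1; layer is not a [0,1] index", s, n_over)
        per_site[s] = _flat_to_grid(vals, fs)
    return RepresentativenessResult(per_site=per_site,
                                    network=_flat_to_grid(net_flat, fs),
                                    norm=norm, aggregation=aggregation)
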