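"""Site networks: experimental-area centroids and their environmental samples.

A *site* is a named collection of experimental areas (plots, fields,
watersheds); each area is reduced to its area-weighted geometric centroid.
A :class:`SiteNetwork` keeps every centroid individually — rather than a
per-site mean — so the within-site environmental diversity survives into
the representativeness computation.  Centroids acquire their environmental
coordinates by sampling the principal-component score stack at the grid
cell that contains them; centroids sharing a cell share identical
environmental conditions by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import shape

from .grid import Transform

logger = logging.getLogger(__name__)


@dataclass
class Centroid:
    site: str
    centroid_id: str
    x: float
    y: float
    cell: tuple[int, int] | None = None
    pc_values: np.ndarray | None = None

    @property
    def sampled(self) -> bool:
        return self.pc_values is not None


@dataclass
class SiteNetwork:
    name: str
    centroids: list[Centroid]

    def __post_init__(self) -> None:
        if any(not c.site for c in self.centroids):
            raise ValueError("every centroid needs a non-empty site label")

    @property
    def sites(self) -> list[str]:
        """Site names in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.centroids:
            seen.setdefault(c.site, None)
        return list(seen)

    @property
    def site_index(self) -> dict[str, list[Centroid]]:
        idx: dict[str, list[Centroid]] = {}
        for c in self.centroids:
            idx.setdefault(c.site, []).append(c)
        return idx

    def __len__(self) -> int:
        return len(self.centroids)

    def pc_matrix(self) -> np.ndarray:
        """(n_centroids, k) matrix of sampled PC vectors, centroid order."""
        if any(c.pc_values is None for c in self.centroids):
            raise ValueError("network not fully sampled; run sample_centroids first")
        return np.vstack([c.pc_values for c in self.centroids])

    def site_rows(self) -> dict[str, np.ndarray]:
        """Map site -> integer row indices into :meth:`pc_matrix`."""
        rows: dict[str, list[int]] = {s: [] for s in self.sites}
        for i, c in enumerate(self.centroids):
            rows[c.site].append(i)
        return {s: np.array(ix, dtype=int) for s, ix in rows.items()}


def polygons_to_centroids(features: list[dict], name: str = "network") -> SiteNetwork:
    """Reduce GeoJSON features to one centroid per feature.

    Polygons are replaced by their area-weighted geometric centroid (which
    may fall outside the polygon); points pass through unchanged.  Missing
    ``centroid_id`` properties are assigned deterministically as
    ``<site>-<ordinal in file order>``.
    """
    centroids: list[Centroid] = []
    counters: dict[str, int] = {}
    for i, feat in enumerate(features):
        props = feat.get("properties") or {}
        site = props.get("site")
        if not site:
            raise ValueError(f"feature {i} has no 'site' property")
        geom = shape(feat["geometry"])
        if geom.is_empty:
            raise ValueError(f"feature {i} (site {site!r}) has an empty geometry")
        pt = geom.centroid
        counters[site] = counters.get(site, 0) + 1
        cid = str(props.get("centroid_id") or f"{site}-{counters[site]}")
        centroids.append(Centroid(site=str(site), centroid_id=cid, x=pt.x, y=pt.y))
    return SiteNetwork(name=name, centroids=centroids)


def network_to_features(net: SiteNetwork) -> list[dict]:
    """Serialize a network's centroids as GeoJSON point features."""
    return [
        {"type": "Feature",
         "geometry": {"type": "Point", "coordinates": [c.x, c.y]},
         "properties": {"site": c.site, "centroid_id": c.centroid_id}}
        for c in net.centroids
    ]


def sample_centroids(net: SiteNetwork, fs: "FeatureSpace") -> SiteNetwork:
    """Attach grid cell and PC score vector to every centroid.

    Cell membership follows the half-open rule (west/north edge inclusive).
    Centroids outside the grid extent raise — that indicates
    mis-registration, not data gaps.  Centroids on invalid cells are
    dropped with a logged warning and count.  Idempotent.
    """
    scores = fs.scores
    transform: Transform = scores.transform
    nrows, ncols = scores.shape
    valid = scores.joint_valid
    score_cube = np.stack([g.values for g in scores.layers], axis=-1)

    outside: list[str] = []
    dropped: list[str] = []
    kept: list[Centroid] = []
    for c in net.centroids:
        row, col = transform.world_to_cell(c.x, c.y)
        if not (0 <= row < nrows and 0 <= col < ncols):
            outside.append(f"{c.site}/{c.centroid_id} at ({c.x}, {c.y})")
            continue
        if not valid[row, col]:
            dropped.append(c.centroid_id)
            continue
        kept.append(replace(c, cell=(row, col),
                            pc_values=score_cube[row, col].copy()))
    if outside:
        raise ValueError(
            f"{len(outside)} centroid(s) outside the grid extent "
            f"(mis-registration?): {', '.join(outside[:5])}")
    if dropped:
        logger.warning("sample_centroids: dropped %d centroid(s) on invalid "
                       "cells: %s", len(dropped), ", ".join(dropped[:10]))
    return SiteNetwork(name=net.name, centroids=kept)


def filter_by_mask_class(net: SiteNetwork, mask: "CategoricalGrid",
                         classes: list[str]) -> SiteNetwork:
    """Keep only centroids whose containing cell carries one of *classes*.

    Used to restrict sister networks to working-lands locations before a
    cross-network comparison.
    """
    keep = mask.class_mask(classes)
    nrows, ncols = mask.shape
    kept = []
    for c in net.centroids:
        row, col = mask.transform.world_to_cell(c.x, c.y)
        if 0 <= row < nrows and 0 <= col < ncols and keep[row, col]:
            kept.append(c)
    logger.info("filter_by_mask_class: %s -> kept %d/%d centroids",
                net.name, len(kept), len(net.centroids))
    return SiteNetwork(name=net.name, centroids=kept)
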