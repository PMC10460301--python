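"""Constituency: the argmax regionalization of a site network.

Every masked valid cell is assigned to the site whose representativeness
layer is highest there — its best representative.  No spatial contiguity
is enforced; any coherence in the winner map emerges from the spatial
autocorrelation of the environmental drivers.  Beyond the winner, a
ranked top-N list of runner-up sites is kept per cell, and per-site
summaries (constituency area, representativeness distribution) support
the generalist / specialist / double-duty site taxonomy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .grid import CategoricalGrid, assert_coregistered
from .pca import FeatureSpace
from .represent import RepresentativenessResult
from .sites import SiteNetwork


@dataclass
class ConstituencyResult:
    winner: CategoricalGrid          # codes = site indices over the domain
    sites: list[str]                 # site order used for codes / tie-breaks
    domain: np.ndarray               # bool: cells that received an assignment
    cells: np.ndarray                # (n, 2) row, col of domain cells, C order
    rank_sites: np.ndarray           # (n, N) site indices, best first
    rank_values: np.ndarray          # (n, N) matching representativeness
    network_values: np.ndarray       # (n,) network representativeness
    mask: CategoricalGrid | None = None

    @property
    def top_n(self) -> int:
        return self.rank_sites.shape[1]

    def winner_values(self) -> np.ndarray:
        """Winning-site representativeness at each domain cell."""
        return self.rank_values[:, 0]

    def ranks_table(self) -> pd.DataFrame:
        n, N = self.rank_sites.shape
        return pd.DataFrame({
            "row": np.repeat(self.cells[:, 0], N),
            "col": np.repeat(self.cells[:, 1], N),
            "rank": np.tile(np.arange(1, N + 1), n),
            "site": np.asarray(self.sites)[self.rank_sites.ravel()],
            "representativeness": self.rank_values.ravel(),
        })


def assign_constituency(rep: RepresentativenessResult,
                        mask: CategoricalGrid | None = None,
                        classes: list[str] | None = None,
                        top_n: int = 3) -> ConstituencyResult:
    """Assign each (masked) valid cell to its best-representing site.

    Ties break deterministically to the earlier site in the network's
    site order.  With *mask* given, only cells whose class is in
    *classes* (default: every class in the mask's table) are assigned.
    """
    valid = rep.network.valid
    if mask is not None:
        assert_coregistered(rep.network, mask)
        if classes is None:
            classes = sorted(set(mask.class_table.values()))
        if not classes:
            raise ValueError("empty class selection")
        domain = valid & mask.class_mask(classes)
    else:
        if classes is not None:
            raise ValueError("classes given without a mask")
        domain = valid.copy()

    sites = rep.sites
    M_all = rep.site_matrix()                      # (n_valid, n_sites)
    sel = domain[valid]                            # domain within valid order
    M = M_all[sel]
    top_n = min(top_n, len(sites))
    # stable descending sort: ties resolve to the earlier-listed site
    order = np.argsort(-M, axis=1, kind="stable")[:, :top_n]
    rank_values = np.take_along_axis(M, order, axis=1)

    codes = np.zeros(valid.shape, dtype=np.int64)
    codes[domain] = order[:, 0]
    winner = CategoricalGrid(codes, {i: s for i, s in enumerate(sites)},
                             domain.copy(), rep.network.transform,
                             rep.network.crs_label)
    return ConstituencyResult(
        winner=winner, sites=sites, domain=domain,
        cells=np.argwhere(domain), rank_sites=order, rank_values=rank_values,
        network_values=rep.network.values[domain], mask=mask)


def iter_full_ranking(rep: RepresentativenessResult,
                      cr: ConstituencyResult) -> Iterator[tuple[tuple[int, int], list[tuple[str, float]]]]:
    """Stream ((row, col), [(site, rep), ...]) with the complete sorted site
    list per domain cell, for consumers that need more than the stored top-N."""
    M = rep.site_matrix()[cr.domain[rep.network.valid]]
    for (r, c), vals in zip(cr.cells, M):
        order = np.argsort(-vals, kind="stable")
        yield (int(r), int(c)), [(cr.sites[j], float(vals[j])) for j in order]


def _dist_stats(x: np.ndarray) -> dict[str, float]:
    if x.size == 0:
        return {k: np.nan for k in
                ("mean", "median", "p10", "p90", "min", "max")}
    return {"mean": float(x.mean()), "median": float(np.median(x)),
            "p10": float(np.quantile(x, 0.10)),
            "p90": float(np.quantile(x, 0.90)),
            "min": float(x.min()), "max": float(x.max())}


def constituency_areas(cr: ConstituencyResult, cell_area_ha: float) -> pd.DataFrame:
    """Per (site, mask class): constituency area and representativeness stats.

    Area = cell count x *cell_area_ha*.  Sites with an empty constituency
    appear with area 0 and NaN statistics (flagged ``empty``).  Without a
    mask, the single class "all" is reported.
    """
    win_idx = cr.rank_sites[:, 0]
    win_rep = cr.winner_values()
    if cr.mask is not None:
        cell_class = np.asarray(
            [cr.mask.class_table[int(c)] for c in
             cr.mask.codes[cr.domain]])
        class_names = sorted(set(cr.mask.class_table.values()))
    else:
        cell_class = np.full(win_idx.shape, "all")
        class_names = ["all"]

    rows = []
    for i, site in enumerate(cr.sites):
        in_site = win_idx == i
        for cls in class_names:
            pick = in_site & (cell_class == cls)
            n = int(pick.sum())
            rows.append({"site": site, "mask_class": cls, "n_cells": n,
                         "area_ha": n * cell_area_ha, "empty": n == 0,
                         **_dist_stats(win_rep[pick])})
    return pd.DataFrame(rows)


def site_gradient_ranges(net: SiteNetwork, fs: FeatureSpace) -> pd.DataFrame:
    """Environmental gradient sampled at each site: per-component stats of
    the centroid PC values (min, p10, median, mean, p90, max)."""
    C = net.pc_matrix()
    rows = []
    for site, idx in net.site_rows().items():
        for k in range(fs.n_selected):
            x = C[idx, k]
            st = _dist_stats(x)
            rows.append({"site": site, "component": f"pc_{k + 1}",
                         "n_centroids": len(idx), **st})
    return pd.DataFrame(rows)


def classify_sites(cr: ConstituencyResult, area_quantile: float = 0.5,
                   rep_floor: float = 0.8) -> pd.DataFrame:
    """Generalist / specialist / double-duty labels per site.

    Operationalizes a qualitative taxonomy: a *generalist* holds a large
    constituency (area at or above the *area_quantile* across sites) with
    mean representativeness at or above *rep_floor*; a *specialist* serves
    a smaller area equally well; a *double-duty* site is the best
    available representative for part of its constituency yet fits it
    poorly (10th percentile below ``rep_floor − 0.2``), signalling a
    forced fit.  Sites meeting none of these are labelled ``poor-fit``.
    Thresholds are conventions, configurable, not measured quantities.
    """
    if not (0 < area_quantile < 1) or not (0 < rep_floor < 1):
        raise ValueError("area_quantile and rep_floor must be in (0, 1)")
    win_idx = cr.rank_sites[:, 0]
    win_rep = cr.winner_values()
    areas = np.array([(win_idx == i).sum() for i in range(len(cr.sites))],
                     dtype=float)
    cut = np.quantile(areas, area_quantile)
    rows = []
    for i, site in enumerate(cr.sites):
        x = win_rep[win_idx == i]
        mean = float(x.mean()) if x.size else np.nan
        p10 = float(np.quantile(x, 0.10)) if x.size else np.nan
        if x.size and p10 < rep_floor - 0.2:
            label = "double-duty"
        elif x.size and mean >= rep_floor:
            label = "generalist" if areas[i] >= cut else "specialist"
        else:
            label = "poor-fit" if x.size else "empty"
        rows.append({"site": site, "label": label, "n_cells": int(areas[i]),
                     "mean_rep": mean, "p10_rep": p10})
    return pd.DataFrame(rows)
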