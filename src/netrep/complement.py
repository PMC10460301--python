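"""Cross-network complementarity: can borrowing sister sites help?

Given a home network and one or more sister networks all sampled on the
same feature space and normalized by one shared landscape-derived
constant (so values are commensurable), this module maps which network
best represents each cell, how much the home network would gain by
borrowing every sister centroid, and which individual sister sites do
the winning.  It also nominates candidate locations for new sites at the
spaced minima of a representativeness surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import CategoricalGrid, Grid, assert_coregistered
from .pca import FeatureSpace
from .represent import (NormalizationConstant, RepresentativenessResult,
                        site_representativeness)
from .sites import SiteNetwork


@dataclass
class MultiNetworkResult:
    best_network: CategoricalGrid    # codes = network indices, 0 = home
    networks: list[str]
    home_rep: Grid
    combined_rep: Grid
    improvement: Grid                # combined − home, >= 0 everywhere
    borrowed_sites: pd.DataFrame     # network, site, cells_won, mean_gain
    per_network: dict[str, RepresentativenessResult]


def best_network_map(networks: list[SiteNetwork], fs: FeatureSpace,
                     norm: NormalizationConstant,
                     mask: CategoricalGrid | None = None,
                     classes: list[str] | None = None,
                     tile_size: int | None = None) -> MultiNetworkResult:
    """Compare the home network (first in the list) against sister networks.

    Per cell, ``best_network`` is the argmax of the networks' network-level
    representativeness; ties resolve to the home network first, then list
    order — the conservative "no change needed" reading.  ``combined_rep``
    is the maximum over the union of all centroids, so it can only sit at
    or above ``home_rep``.  With *mask*/*classes*, the comparison domain is
    restricted (the winner map is invalid elsewhere) but every network's
    surfaces are still computed everywhere.
    """
    if len(networks) < 2:
        raise ValueError("need the home network plus at least one sister")
    names = [n.name for n in networks]
    if len(set(names)) != len(names):
        raise ValueError("network names must be unique")

    per_network = {
        n.name: site_representativeness(n, fs, norm, aggregation="max",
                                        tile_size=tile_size)
        for n in networks
    }
    valid = fs.valid
    net_stack = np.stack([per_network[n].network.values for n in names])
    # home-first tie rule: argmax of (value, home-preference) via reversed
    # scan — np.argmax returns the first maximum, and the list is already
    # ordered home first.
    best_idx = np.argmax(net_stack, axis=0)

    domain = valid.copy()
    if mask is not None:
        assert_coregistered(fs.scores[0], mask)
        if classes is None:
            classes = sorted(set(mask.class_table.values()))
        domain &= mask.class_mask(classes)

    codes = np.where(domain, best_idx, 0).astype(np.int64)
    best = CategoricalGrid(codes, {i: n for i, n in enumerate(names)},
                           domain, fs.scores.transform, fs.scores.crs_label)

    home = per_network[names[0]].network
    combined_vals = net_stack.max(axis=0)
    combined = Grid(np.where(valid, combined_vals, np.nan), valid.copy(),
                    fs.scores.transform, fs.scores.crs_label, nodata=np.nan)
    improvement = Grid(np.where(valid, combined_vals - home.values, np.nan),
                       valid.copy(), fs.scores.transform, fs.scores.crs_label,
                       nodata=np.nan)

    rows = []
    gain = improvement.values
    for j, net in enumerate(networks[1:], start=1):
        won = domain & (best_idx == j)
        if not won.any():
            continue
        rep_j = per_network[net.name]
        # attribute each won cell to the sister site that is best there
        site_mat = rep_j.site_matrix()           # (n_valid, n_sites_j)
        won_in_valid = won[valid]
        site_win = np.argmax(site_mat[won_in_valid], axis=1)
        for s_idx, site in enumerate(rep_j.sites):
            pick = site_win == s_idx
            if not pick.any():
                continue
            rows.append({
                "network": net.name, "site": site,
                "cells_won": int(pick.sum()),
                "mean_gain": float(gain[won][pick].mean()),
            })
    borrowed = pd.DataFrame(rows, columns=["network", "site", "cells_won",
                                           "mean_gain"])
    return MultiNetworkResult(best_network=best, networks=names,
                              home_rep=home, combined_rep=combined,
                              improvement=improvement,
                              borrowed_sites=borrowed,
                              per_network=per_network)


def candidate_gaps(rep: RepresentativenessResult,
                   mask: CategoricalGrid | None = None,
                   classes: list[str] | None = None,
                   k: int = 5, min_separation: float = 5.0) -> pd.DataFrame:
    """The k worst-represented (masked) cells, greedily spaced.

    Cells are scanned in ascending representativeness (row, col as
    deterministic tie-breaks) and accepted only if at least
    *min_separation* cells (Euclidean, in cell units) from every already
    accepted candidate, so the nominations are not all in one pocket.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    valid = rep.network.valid
    domain = valid.copy()
    if mask is not None:
        assert_coregistered(rep.network, mask)
        if classes is None:
            classes = sorted(set(mask.class_table.values()))
        domain &= mask.class_mask(classes)
    cells = np.argwhere(domain)
    vals = rep.network.values[domain]
    order = np.lexsort((cells[:, 1], cells[:, 0], vals))

    chosen: list[int] = []
    for i in order:
        if len(chosen) == k:
            break
        rc = cells[i]
        if all(np.hypot(*(rc - cells[j])) >= min_separation for j in chosen):
            chosen.append(i)
    t = rep.network.transform
    rows = []
    for rank, i in enumerate(chosen, start=1):
        r, c = (int(v) for v in cells[i])
        x, y = t.cell_center(r, c)
        rows.append({"rank": rank, "row": r, "col": c, "x": x, "y": y,
                     "representativeness": float(vals[i])})
    return pd.DataFrame(rows)
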