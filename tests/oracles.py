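"""Independent brute-force reference implementations.

Everything here is written as plain double loops over cells and sites,
deliberately sharing no code with the package's vectorised/tiled
implementations, so the two can cross-check each other.
"""

import math

import numpy as np


def resample_dominant(codes, valid, factor):
    """Per-block histogram argmax with lowest-code tie-break."""
    nr, nc = codes.shape
    cr, cc = nr // factor, nc // factor
    out = np.zeros((cr, cc), dtype=codes.dtype)
    out_valid = np.zeros((cr, cc), dtype=bool)
    for i in range(cr):
        for j in range(cc):
            counts = {}
            for di in range(factor):
                for dj in range(factor):
                    r, c = i * factor + di, j * factor + dj
                    if valid[r, c]:
                        counts[int(codes[r, c])] = counts.get(int(codes[r, c]), 0) + 1
            if counts:
                best = max(sorted(counts), key=lambda k: counts[k])
                # max with sorted keys picks the highest count; on count
                # ties, the lowest code must win:
                top = max(counts.values())
                best = min(k for k, v in counts.items() if v == top)
                out[i, j] = best
                out_valid[i, j] = True
    return out, out_valid


def centroid_rep_map(score_layers, valid, pc, norm):
    """Representativeness of one centroid at every valid cell."""
    nrows, ncols = valid.shape
    out = np.full((nrows, ncols), np.nan)
    for r in range(nrows):
        for c in range(ncols):
            if not valid[r, c]:
                continue
            d2 = 0.0
            for k, layer in enumerate(score_layers):
                d2 += (pc[k] - layer[r, c]) ** 2
            out[r, c] = min(1.0, max(0.0, 1.0 - math.sqrt(d2) / norm))
    return out


def network_layers(score_layers, valid, centroids_by_site, norm, agg="max"):
    """Per-site and network maps from per-centroid maps, cellwise."""
    site_maps = {}
    all_maps = []
    for site, pcs in centroids_by_site.items():
        maps = [centroid_rep_map(score_layers, valid, pc, norm) for pc in pcs]
        all_maps.extend(maps)
        stackd = np.stack(maps)
        if agg == "max":
            site_maps[site] = stackd.max(axis=0)
        elif agg == "mean":
            site_maps[site] = stackd.mean(axis=0)
        else:
            site_maps[site] = stackd.sum(axis=0)
    network = np.stack(all_maps).max(axis=0)
    return site_maps, network


def observed_max_distance(score_layers, valid, pcs):
    """Exhaustive max (centroid, cell) distance."""
    nrows, ncols = valid.shape
    dmax = 0.0
    for pc in pcs:
        for r in range(nrows):
            for c in range(ncols):
                if not valid[r, c]:
                    continue
                d2 = sum((pc[k] - layer[r, c]) ** 2
                         for k, layer in enumerate(score_layers))
                dmax = max(dmax, math.sqrt(d2))
    return dmax


def argmax_constituency(site_maps, domain, site_order):
    """Per-cell winner with first-listed tie-break, plus sorted rank lists."""
    nrows, ncols = domain.shape
    winner = np.full((nrows, ncols), -1)
    ranks = {}
    for r in range(nrows):
        for c in range(ncols):
            if not domain[r, c]:
                continue
            vals = [(site_maps[s][r, c], i) for i, s in enumerate(site_order)]
            best_v = max(v for v, _ in vals)
            best_i = min(i for v, i in vals if v == best_v)
            winner[r, c] = best_i
            ranks[(r, c)] = sorted(vals, key=lambda t: (-t[0], t[1]))
    return winner, ranks


def best_network(network_maps, domain, order):
    """Per-cell best network with first-listed (home) tie-break."""
    nrows, ncols = domain.shape
    out = np.full((nrows, ncols), -1)
    for r in range(nrows):
        for c in range(ncols):
            if not domain[r, c]:
                continue
            vals = [network_maps[n][r, c] for n in order]
            best_v = max(vals)
            out[r, c] = vals.index(best_v)
    return out


def cumulative_select(eigen_fractions, threshold):
    """Smallest k whose cumulative variance fraction reaches threshold."""
    total = 0.0
    for k, f in enumerate(eigen_fractions, start=1):
        total += f
        if total >= threshold - 1e-12:
            return k
    return len(eigen_fractions)
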