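import numpy as np
import pytest

import netrep as nr

from oracles import centroid_rep_map, network_layers, observed_max_distance


def _fs_from_scores(score_arrays, cell=1.0):
    """Build a FeatureSpace wrapper around hand-listed score layers."""
    shape = np.asarray(score_arrays[0]).shape
    valid = np.ones(shape, bool)
    t = nr.Transform(0.0, shape[0] * cell, cell, cell)
    layers = [nr.Grid(np.asarray(a, float), valid.copy(), t)
              for a in score_arrays]
    stack = nr.GridStack(layers, [f"pc_{i+1}" for i in range(len(layers))])
    k = len(layers)
    return nr.FeatureSpace(means=np.zeros(k), sds=np.ones(k),
                           loadings=np.eye(k),
                           variance_fraction=np.full(k, 1 / k),
                           n_selected=k, scores=stack,
                           layer_names=list(stack.names))


def _sampled(fs, cells_by_site):
    cents = []
    for site, cells in cells_by_site.items():
        for i, (r, c) in enumerate(cells, 1):
            x, y = fs.scores.transform.cell_center(r, c)
            pc = np.array([g.values[r, c] for g in fs.scores.layers])
            cents.append(nr.Centroid(site, f"{site}-{i}", x, y, (r, c), pc))
    return nr.SiteNetwork("net", cents)


def test_bbox_diameter_1d_range():
    fs = _fs_from_scores([[[-2.0, 0.0, 3.0]]])
    nc = nr.normalization_constant(fs)
    assert nc.value == pytest.approx(5.0)


def test_bbox_diameter_3_4_5():
    fs = _fs_from_scores([[[0.0, 3.0], [1.0, 2.0]],
                          [[0.0, 2.0], [4.0, 1.0]]])
    assert nr.normalization_constant(fs).value == pytest.approx(5.0)


def test_observed_max_matches_brute_force():
    rng = np.random.default_rng(0)
    fs = _fs_from_scores([rng.standard_normal((10, 10)) for _ in range(3)])
    net = _sampled(fs, {"A": [(0, 0)], "B": [(5, 5), (9, 2)]})
    nc = nr.normalization_constant(fs, "observed_max", net=net)
    layers = [g.values for g in fs.scores.layers]
    expected = observed_max_distance(layers, fs.valid, net.pc_matrix())
    assert nc.value == pytest.approx(expected, abs=1e-12)


def test_degenerate_featurespace_rejected():
    fs = _fs_from_scores([np.zeros((3, 3))])
    with pytest.raises(ValueError, match="undefined"):
        nr.normalization_constant(fs)


def test_own_cell_scores_one():
    rng = np.random.default_rng(1)
    fs = _fs_from_scores([rng.standard_normal((6, 6)) for _ in range(2)])
    net = _sampled(fs, {"A": [(2, 3)]})
    nc = nr.normalization_constant(fs)
    g = nr.centroid_representativeness(net.centroids[0], fs, nc)
    assert g.values[2, 3] == pytest.approx(1.0, abs=1e-15)


def test_cell_at_normalization_distance_scores_zero():
    # 1-D scores 0 and 5, bbox diameter 5: the far cell scores exactly 0
    fs = _fs_from_scores([[[0.0, 5.0]]])
    net = _sampled(fs, {"A": [(0, 0)]})
    nc = nr.normalization_constant(fs)
    g = nr.centroid_representativeness(net.centroids[0], fs, nc)
    assert g.values[0, 1] == pytest.approx(0.0, abs=1e-15)
    assert g.values[0, 0] == pytest.approx(1.0)


def test_centroid_map_matches_double_loop_oracle():
    rng = np.random.default_rng(2)
    fs = _fs_from_scores([rng.standard_normal((5, 5)) for _ in range(3)])
    net = _sampled(fs, {"A": [(4, 1)]})
    nc = nr.normalization_constant(fs)
    got = nr.centroid_representativeness(net.centroids[0], fs, nc)
    layers = [g.values for g in fs.scores.layers]
    exp = centroid_rep_map(layers, fs.valid, net.centroids[0].pc_values,
                           nc.value)
    assert np.allclose(got.values, exp, atol=1e-12, equal_nan=True)


def test_single_centroid_site_equals_its_map():
    rng = np.random.default_rng(3)
    fs = _fs_from_scores([rng.standard_normal((6, 6)) for _ in range(2)])
    net = _sampled(fs, {"A": [(1, 1)]})
    nc = nr.normalization_constant(fs)
    rep = nr.site_representativeness(net, fs, nc)
    cmap = nr.centroid_representativeness(net.centroids[0], fs, nc)
    assert np.allclose(rep.per_site["A"].values, cmap.values, equal_nan=True)
    assert np.allclose(rep.network.values, cmap.values, equal_nan=True)


@pytest.mark.parametrize("agg", ["max", "mean", "sum"])
def test_site_aggregation_matches_oracle(agg):
    rng = np.random.default_rng(4)
    fs = _fs_from_scores([rng.standard_normal((7, 7)) for _ in range(2)])
    cells = {"A": [(0, 0), (3, 3)], "B": [(6, 6)]}
    net = _sampled(fs, cells)
    nc = nr.normalization_constant(fs)
    rep = nr.site_representativeness(net, fs, nc, aggregation=agg)
    layers = [g.values for g in fs.scores.layers]
    pcs = {s: [np.array([l[r, c] for l in layers]) for r, c in cc]
           for s, cc in cells.items()}
    exp_sites, exp_net = network_layers(layers, fs.valid, pcs, nc.value, agg)
    for s in cells:
        assert np.allclose(rep.per_site[s].values, exp_sites[s], atol=1e-12)
    assert np.allclose(rep.network.values, exp_net, atol=1e-12)


def test_sum_of_identical_centroids_doubles_and_warns(caplog):
    import logging
    rng = np.random.default_rng(5)
    fs = _fs_from_scores([rng.standard_normal((4, 4)) for _ in range(2)])
    net = _sampled(fs, {"A": [(2, 2), (2, 2)]})
    nc = nr.normalization_constant(fs)
    single = nr.centroid_representativeness(net.centroids[0], fs, nc)
    with caplog.at_level(logging.WARNING, logger="netrep.represent"):
        rep = nr.site_representativeness(net, fs, nc, aggregation="sum")
    assert np.allclose(rep.per_site["A"].values, 2 * single.values)
    assert "above 1" in caplog.text
    # the network layer stays a max regardless of the site aggregation
    assert np.allclose(rep.network.values, single.values)


def test_adding_a_centroid_never_lowers_the_network(default_demo):
    d = default_demo
    fs, norm = d["fs"], d["norm"]
    base = d["rep"].network.values
    extra = d["net"].centroids[0]
    grown = nr.SiteNetwork("grown", d["net"].centroids + [
        nr.Centroid("NEW", "NEW-1", extra.x, extra.y)])
    grown = nr.sample_centroids(grown, fs)
    rep2 = nr.site_representativeness(grown, fs, norm)
    v = d["rep"].network.valid
    assert (rep2.network.values[v] >= base[v] - 1e-12).all()


def test_every_sampled_centroid_cell_scores_one(default_demo):
    d = default_demo
    for c in d["net"].centroids:
        r, cc = c.cell
        assert d["rep"].network.values[r, cc] == pytest.approx(1.0, abs=1e-12)


def test_tiling_invariance(default_demo):
    d = default_demo
    full = nr.site_representativeness(d["net"], d["fs"], d["norm"])
    for tile in (7, 64, 500):
        tiled = nr.site_representativeness(d["net"], d["fs"], d["norm"],
                                           tile_size=tile)
        assert np.array_equal(
            tiled.network.values[tiled.network.valid],
            full.network.values[full.network.valid])
        for s in full.per_site:
            assert np.allclose(tiled.per_site[s].values,
                               full.per_site[s].values,
                               atol=1e-12, equal_nan=True)


def test_dimension_mismatch_rejected():
    rng = np.random.default_rng(6)
    fs = _fs_from_scores([rng.standard_normal((4, 4)) for _ in range(2)])
    bad = nr.Centroid("A", "A-1", 0.5, 0.5, (3, 0), np.zeros(5))
    nc = nr.normalization_constant(fs)
    with pytest.raises(ValueError):
        nr.centroid_representativeness(bad, fs, nc)
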