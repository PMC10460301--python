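import numpy as np
import pandas as pd
import pytest

import netrep as nr

from oracles import argmax_constituency
from test_represent import _fs_from_scores, _sampled


def _mask_like(fs, codes=None):
    shape = fs.valid.shape
    codes = np.ones(shape, dtype=np.int64) if codes is None else codes
    table = {0: "non-working", 1: "cropland", 2: "grazingland", 3: "mixed"}
    return nr.CategoricalGrid(codes, table, fs.valid.copy(),
                              fs.scores.transform, fs.scores.crs_label)


def _rep(fs, cells_by_site, agg="max"):
    net = _sampled(fs, cells_by_site)
    nc = nr.normalization_constant(fs)
    return nr.site_representativeness(net, fs, nc, aggregation=agg), net


def test_single_site_takes_every_masked_cell():
    rng = np.random.default_rng(0)
    fs = _fs_from_scores([rng.standard_normal((5, 5)) for _ in range(2)])
    rep, _ = _rep(fs, {"A": [(2, 2)]})
    cr = nr.assign_constituency(rep, _mask_like(fs), classes=["cropland"])
    assert (cr.rank_sites[:, 0] == 0).all()
    assert cr.domain.sum() == 25


def test_tie_goes_to_earlier_listed_site():
    # two sites with identical centroids: every cell is an exact tie
    rng = np.random.default_rng(1)
    fs = _fs_from_scores([rng.standard_normal((4, 4)) for _ in range(2)])
    rep, _ = _rep(fs, {"first": [(1, 1)], "second": [(1, 1)]})
    cr = nr.assign_constituency(rep)
    assert (np.asarray(cr.sites)[cr.rank_sites[:, 0]] == "first").all()


def test_winner_map_matches_exhaustive_oracle():
    rng = np.random.default_rng(2)
    fs = _fs_from_scores([rng.standard_normal((10, 10)) for _ in range(3)])
    cells = {"A": [(0, 0), (4, 7)], "B": [(9, 9)], "C": [(5, 1), (2, 3)]}
    rep, _ = _rep(fs, cells)
    cr = nr.assign_constituency(rep, top_n=3)
    site_maps = {s: rep.per_site[s].values for s in cells}
    exp_win, exp_ranks = argmax_constituency(site_maps, fs.valid, list(cells))
    got_win = np.full(fs.valid.shape, -1)
    got_win[cr.domain] = cr.rank_sites[:, 0]
    assert np.array_equal(got_win, exp_win)
    for (rc, ranked), got_sites, got_vals in zip(
            sorted(exp_ranks.items()), cr.rank_sites, cr.rank_values):
        exp_vals = [v for v, _ in ranked]
        exp_idx = [i for _, i in ranked]
        assert list(got_sites) == exp_idx[:3]
        assert np.allclose(got_vals, exp_vals[:3], atol=1e-12)


def test_winner_representativeness_equals_network(default_demo):
    rep = default_demo["rep"]
    cr = nr.assign_constituency(rep, default_demo["mask"])
    assert np.allclose(cr.winner_values(), cr.network_values, atol=1e-12)


def test_rank_values_non_increasing(default_demo):
    cr = nr.assign_constituency(default_demo["rep"], default_demo["mask"])
    assert (np.diff(cr.rank_values, axis=1) <= 1e-15).all()


def test_dominance_of_winner(default_demo):
    rep = default_demo["rep"]
    cr = nr.assign_constituency(rep, default_demo["mask"])
    M = rep.site_matrix()[cr.domain[rep.network.valid]]
    assert (M.max(axis=1) <= cr.winner_values() + 1e-12).all()


def test_site_order_permutation_only_moves_ties():
    rng = np.random.default_rng(3)
    fs = _fs_from_scores([rng.standard_normal((8, 8)) for _ in range(2)])
    cells = {"A": [(0, 0)], "B": [(7, 7)], "C": [(3, 4)]}
    rep, _ = _rep(fs, cells)
    cr = nr.assign_constituency(rep)
    perm_cells = {"C": cells["C"], "B": cells["B"], "A": cells["A"]}
    rep2, _ = _rep(fs, perm_cells)
    cr2 = nr.assign_constituency(rep2)
    name1 = np.asarray(cr.sites)[cr.rank_sites[:, 0]]
    name2 = np.asarray(cr2.sites)[cr2.rank_sites[:, 0]]
    changed = name1 != name2
    if changed.any():
        M = rep.site_matrix()
        top2 = -np.sort(-M[changed], axis=1)[:, :2]
        assert np.allclose(top2[:, 0], top2[:, 1], atol=1e-12)


def test_empty_class_selection_rejected(default_demo):
    with pytest.raises(ValueError, match="empty"):
        nr.assign_constituency(default_demo["rep"], default_demo["mask"],
                               classes=[])


# ----------------------------------------------------------------- summaries

def test_area_arithmetic():
    rng = np.random.default_rng(4)
    fs = _fs_from_scores([rng.standard_normal((10, 10)) for _ in range(2)])
    rep, _ = _rep(fs, {"A": [(5, 5)]})
    cr = nr.assign_constituency(rep, _mask_like(fs), classes=["cropland"])
    tab = nr.constituency_areas(cr, cell_area_ha=100.0)
    row = tab[(tab.site == "A") & (tab.mask_class == "cropland")].iloc[0]
    assert row.area_ha == 10_000.0
    assert row.n_cells == 100


def test_zero_constituency_site_flagged_empty():
    rng = np.random.default_rng(5)
    fs = _fs_from_scores([rng.standard_normal((6, 6)) for _ in range(2)])
    rep, _ = _rep(fs, {"A": [(0, 0)], "twin": [(0, 0)]})  # twin always loses ties
    cr = nr.assign_constituency(rep, _mask_like(fs))
    tab = nr.constituency_areas(cr, 1.0)
    twin = tab[tab.site == "twin"]
    assert (twin.area_ha == 0).all()
    assert twin["empty"].all()
    assert twin["mean"].isna().all()


def test_areas_partition_masked_area(default_demo):
    mask = default_demo["mask"]
    cr = nr.assign_constituency(default_demo["rep"], mask,
                                classes=["cropland", "grazingland", "mixed"])
    tab = nr.constituency_areas(cr, 1.0)
    working = tab[tab.mask_class != "non-working"]
    assert int(working.n_cells.sum()) == int(cr.domain.sum())
    assert int(cr.domain.sum()) == int(
        mask.class_mask(["cropland", "grazingland", "mixed"]).sum())


# ------------------------------------------------------------ gradient ranges

def test_single_centroid_site_stats_collapse():
    rng = np.random.default_rng(6)
    fs = _fs_from_scores([rng.standard_normal((5, 5)) for _ in range(2)])
    net = _sampled(fs, {"A": [(2, 2)]})
    tab = nr.site_gradient_ranges(net, fs)
    for _, row in tab.iterrows():
        assert row["min"] == row["max"] == row["mean"] == row["median"]


def test_gradient_stats_match_direct_recomputation():
    rng = np.random.default_rng(7)
    fs = _fs_from_scores([rng.standard_normal((8, 8)) for _ in range(3)])
    cells = {"A": [(0, 0), (1, 1), (2, 2)], "B": [(7, 7), (6, 0)]}
    net = _sampled(fs, cells)
    tab = nr.site_gradient_ranges(net, fs).set_index(["site", "component"])
    C = net.pc_matrix()
    rows = net.site_rows()
    for s in cells:
        for k in range(3):
            x = C[rows[s], k]
            row = tab.loc[(s, f"pc_{k+1}")]
            assert row["mean"] == pytest.approx(x.mean())
            assert row["p90"] == pytest.approx(np.quantile(x, 0.9))
            assert row["max"] == pytest.approx(x.max())


# -------------------------------------------------------------- site taxonomy

def _fake_cr(site_cells, site_reps):
    """Construct a ConstituencyResult directly from per-site cell counts."""
    sites = list(site_cells)
    n = sum(site_cells.values())
    rank_sites = np.concatenate([
        np.full(site_cells[s], i) for i, s in enumerate(sites)])[:, None]
    rank_values = np.concatenate([
        np.asarray(site_reps[s]) for s in sites])[:, None]
    shape = (1, n)
    codes = rank_sites[:, 0].reshape(shape)
    winner = nr.CategoricalGrid(codes, {i: s for i, s in enumerate(sites)},
                                np.ones(shape, bool), nr.Transform(0, 1, 1, 1))
    return nr.ConstituencyResult(
        winner=winner, sites=sites, domain=np.ones(shape, bool),
        cells=np.argwhere(np.ones(shape, bool)), rank_sites=rank_sites,
        rank_values=rank_values, network_values=rank_values[:, 0])


def test_generalist_and_specialist_split_by_area():
    cr = _fake_cr({"big": 90, "small": 10},
                  {"big": np.full(90, 0.9), "small": np.full(10, 0.9)})
    tab = nr.classify_sites(cr).set_index("site")
    assert tab.loc["big", "label"] == "generalist"
    assert tab.loc["small", "label"] == "specialist"


def test_low_tail_marks_double_duty():
    reps = np.full(50, 0.85)
    reps[:10] = 0.4  # p10 well below floor - 0.2
    cr = _fake_cr({"A": 50, "B": 50},
                  {"A": reps, "B": np.full(50, 0.9)})
    tab = nr.classify_sites(cr, rep_floor=0.8).set_index("site")
    assert tab.loc["A", "label"] == "double-duty"


def test_identical_sites_share_a_label():
    cr = _fake_cr({"A": 30, "B": 30, "C": 30},
                  {s: np.full(30, 0.95) for s in "ABC"})
    assert nr.classify_sites(cr).label.nunique() == 1


def test_classify_threshold_validation(default_demo):
    cr = nr.assign_constituency(default_demo["rep"], default_demo["mask"])
    with pytest.raises(ValueError):
        nr.classify_sites(cr, area_quantile=1.5)
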