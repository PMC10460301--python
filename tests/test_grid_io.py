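import numpy as np
import pytest

import netrep as nr
from netrep.io import GridLoadError

from conftest import grid_from
from oracles import resample_dominant


# ---------------------------------------------------------------- containers

def test_grid_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shape"):
        nr.Grid(np.zeros((3, 3)), np.ones((3, 4), bool),
                nr.Transform(0, 3, 1, 1))


def test_transform_requires_positive_cells():
    with pytest.raises(ValueError, match="positive"):
        nr.Transform(0, 0, -1.0, 1.0)


def test_categorical_codes_must_be_in_class_table():
    codes = np.array([[0, 1], [2, 0]])
    with pytest.raises(ValueError, match="class_table"):
        nr.CategoricalGrid(codes, {0: "a", 1: "b"}, np.ones((2, 2), bool),
                           nr.Transform(0, 2, 1, 1))


# ----------------------------------------------------------------------- I/O

def test_ascii_grid_read(tmp_path):
    p = tmp_path / "g.asc"
    p.write_text("ncols 3\nnrows 3\nxllcorner 10\nyllcorner 20\n"
                 "cellsize 2\nnodata_value -9999\n"
                 "1 2 3\n4 -9999 6\n7 8 9\n")
    g = nr.read_grid(p)
    assert g.shape == (3, 3)
    assert g.n_valid == 8
    assert not g.valid[1, 1]
    assert g.values[0, 2] == 3
    assert g.transform.x_origin == 10
    assert g.transform.y_origin == 20 + 3 * 2  # yll + nrows*cellsize


def test_ascii_round_trip_bit_exact(tmp_path):
    rng = np.random.default_rng(0)
    g = grid_from(rng.standard_normal((7, 5)),
                  nodata_mask=rng.random((7, 5)) < 0.2)
    p = tmp_path / "rt.asc"
    nr.write_grid(p, g)
    back = nr.read_grid(p)
    assert np.array_equal(back.valid, g.valid)
    assert np.array_equal(back.values[back.valid], g.values[g.valid])
    assert back.transform == g.transform


def test_tiff_round_trip_float32(tmp_path):
    rng = np.random.default_rng(1)
    src = rng.standard_normal((6, 9))
    g = grid_from(src)
    p = tmp_path / "rt.tif"
    nr.write_grid(p, g)
    back = nr.read_grid(p)
    assert back.transform == g.transform
    assert np.allclose(back.values, src, rtol=1e-7)


def test_read_grid_missing_file(tmp_path):
    with pytest.raises(FileNotFoundError):
        nr.read_grid(tmp_path / "nope.asc")


def test_read_grid_rejects_nonfinite_valid_cells(tmp_path):
    p = tmp_path / "g.asc"
    p.write_text("ncols 2\nnrows 1\nxllcorner 0\nyllcorner 0\n"
                 "cellsize 1\nnodata_value -9999\n1 inf\n")
    with pytest.raises(GridLoadError, match=r"row=0, col=1"):
        nr.read_grid(p)


def test_categorical_round_trip(tmp_path):
    codes = np.array([[0, 1], [2, 3]])
    table = {0: "non-working", 1: "cropland", 2: "grazingland", 3: "mixed"}
    cat = nr.CategoricalGrid(codes, table, np.ones((2, 2), bool),
                             nr.Transform(0, 2, 1, 1))
    nr.write_categorical_grid(tmp_path / "m.asc", cat, tmp_path / "m.yaml")
    back = nr.read_categorical_grid(tmp_path / "m.asc", tmp_path / "m.yaml")
    assert np.array_equal(back.codes, codes)
    assert back.class_table == table


# ------------------------------------------------------------ coregistration

def test_coregistration_passes_for_identical_geometry():
    a, b = grid_from(np.zeros((4, 4))), grid_from(np.ones((4, 4)))
    nr.assert_coregistered(nr.GridStack([a, b]))


def test_coregistration_names_shifted_transform():
    a = grid_from(np.zeros((4, 4)))
    b = nr.Grid(np.zeros((4, 4)), np.ones((4, 4), bool),
                nr.Transform(1.0, 4.0, 1.0, 1.0))
    with pytest.raises(nr.CoregistrationError, match="transform"):
        nr.assert_coregistered(a, b)


def test_coregistration_names_shape():
    with pytest.raises(nr.CoregistrationError, match="shape"):
        nr.assert_coregistered(grid_from(np.zeros((100, 100))),
                               grid_from(np.zeros((100, 99))))


# ------------------------------------------------------------------ resample

def _cat(codes, valid=None):
    codes = np.asarray(codes)
    valid = np.ones(codes.shape, bool) if valid is None else valid
    table = {int(c): f"class_{c}" for c in np.unique(codes)}
    table.setdefault(0, "non-working")
    return nr.CategoricalGrid(codes, table, valid,
                              nr.Transform(0, codes.shape[0], 1, 1))


def test_resample_constant_grid_stays_constant():
    out = nr.dominant_type_resample(_cat(np.full((4, 4), 2)), 2)
    assert out.shape == (2, 2)
    assert (out.codes == 2).all()


def test_resample_tie_breaks_to_lowest_code():
    out = nr.dominant_type_resample(_cat([[1, 1], [3, 3]]), 2)
    assert out.codes[0, 0] == 1


def test_resample_matches_counting_oracle():
    rng = np.random.default_rng(5)
    codes = rng.integers(0, 3, size=(30, 30))
    valid = rng.random((30, 30)) > 0.1
    cat = _cat(codes, valid)
    out = nr.dominant_type_resample(cat, 3)
    exp_codes, exp_valid = resample_dominant(codes, valid, 3)
    assert np.array_equal(out.valid, exp_valid)
    assert np.array_equal(out.codes[out.valid], exp_codes[exp_valid])


def test_resample_drops_partial_blocks_and_warns(caplog):
    import logging
    with caplog.at_level(logging.WARNING, logger="netrep.grid"):
        out = nr.dominant_type_resample(_cat(np.zeros((5, 7), dtype=int)), 2)
    assert out.shape == (2, 3)
    assert "dropping" in caplog.text


def test_resample_class_set_subset_of_input():
    rng = np.random.default_rng(9)
    cat = _cat(rng.integers(0, 5, size=(12, 12)))
    out = nr.dominant_type_resample(cat, 4)
    assert set(np.unique(out.codes[out.valid])) <= set(np.unique(cat.codes))


def test_resample_rejects_bad_factor():
    with pytest.raises(ValueError):
        nr.dominant_type_resample(_cat(np.zeros((4, 4), dtype=int)), 0)
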