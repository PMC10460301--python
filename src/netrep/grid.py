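"""Gridded data containers.

A :class:`Grid` is the universal spatial carrier of the package: a 2-D array
of cell-centred values, an explicit boolean validity mask, and a north-up
affine cell geometry.  Row 0 is the northernmost row, indices are 0-based,
and a cell's value refers to its centre.  Validity is always an explicit
boolean array; downstream code never compares against a nodata sentinel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: relative tolerance for declaring two cell geometries identical
TRANSFORM_RTOL = 1e-9


class CoregistrationError(ValueError):
    """Raised when grids that must share a geometry do not."""


@dataclass(frozen=True)
class Transform:
    """North-up affine cell geometry.

    ``x_origin``/``y_origin`` locate the *outer corner* of cell (0, 0):
    the west edge of column 0 and the north edge of row 0.  ``cell_width``
    and ``cell_height`` are strictly positive map units per cell; rows
    increase southward.
    """

    x_origin: float
    y_origin: float
    cell_width: float
    cell_height: float

    def __post_init__(self) -> None:
        if self.cell_width <= 0 or self.cell_height <= 0:
            raise ValueError(
                f"cell size must be strictly positive, got "
                f"({self.cell_width}, {self.cell_height})"
            )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.x_origin + (col + 0.5) * self.cell_width
        y = self.y_origin - (row + 0.5) * self.cell_height
        return x, y

    def world_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """Map coordinates -> (row, col) under the half-open cell rule.

        A point on a shared edge belongs to the cell whose west or north
        edge it lies on (floor of the fractional index).
        """
        col = int(np.floor((x - self.x_origin) / self.cell_width))
        row = int(np.floor((self.y_origin - y) / self.cell_height))
        return row, col

    def close_to(self, other: "Transform", rtol: float = TRANSFORM_RTOL) -> bool:
        a = np.array([self.x_origin, self.y_origin, self.cell_width, self.cell_height])
        b = np.array([other.x_origin, other.y_origin, other.cell_width, other.cell_height])
        return bool(np.allclose(a, b, rtol=rtol, atol=rtol * max(1.0, np.abs(b).max())))


@dataclass
class Grid:
    """Single-band continuous raster with an explicit validity mask."""

    values: np.ndarray
    valid: np.ndarray
    transform: Transform
    crs_label: str = ""
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != self.valid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != valid shape {self.valid.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def filled(self, fill: float | None = None) -> np.ndarray:
        """Values with invalid cells replaced by *fill* (default nodata)."""
        out = self.values.copy()
        out[~self.valid] = self.nodata if fill is None else fill
        return out

    def copy(self) -> "Grid":
        return Grid(self.values.copy(), self.valid.copy(), self.transform,
                    self.crs_label, self.nodata)

    @classmethod
    def full_like(cls, template: "Grid | CategoricalGrid", fill: float = np.nan,
                  valid: np.ndarray | None = None) -> "Grid":
        shape = template.shape
        v = template.valid.copy() if valid is None else np.asarray(valid, bool)
        return cls(np.full(shape, fill, dtype=float), v, template.transform,
                   template.crs_label)


@dataclass
class CategoricalGrid:
    """Single-band categorical raster: small non-negative integer codes."""

    codes: np.ndarray
    class_table: dict[int, str]
    valid: np.ndarray
    transform: Transform
    crs_label: str = ""
    nodata_code: int = 255

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ValueError("codes must be an integer array")
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.codes.shape != self.valid.shape:
            raise ValueError("codes and valid must share a shape")
        present = set(np.unique(self.codes[self.valid]).tolist())
        missing = present - set(self.class_table)
        if missing:
            raise ValueError(f"codes {sorted(missing)} present but absent from class_table")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def class_mask(self, classes: Sequence[str]) -> np.ndarray:
        """Boolean mask of valid cells whose class name is in *classes*."""
        wanted = {c for c, name in self.class_table.items() if name in set(classes)}
        return self.valid & np.isin(self.codes, list(wanted))

    def copy(self) -> "CategoricalGrid":
        return CategoricalGrid(self.codes.copy(), dict(self.class_table),
                               self.valid.copy(), self.transform,
                               self.crs_label, self.nodata_code)


@dataclass
class GridStack:
    """Ordered list of co-registered :class:`Grid` layers."""

    layers: list[Grid]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a GridStack needs at least one layer")
        if not self.names:
            self.names = [f"layer_{i}" for i in range(len(self.layers))]
        if len(self.names) != len(self.layers):
            raise ValueError("names and layers length mismatch")
        assert_coregistered(self)

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self) -> Iterator[Grid]:
        return iter(self.layers)

    def __getitem__(self, i: int) -> Grid:
        return self.layers[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers[0].shape

    @property
    def transform(self) -> Transform:
        return self.layers[0].transform

    @property
    def crs_label(self) -> str:
        return self.layers[0].crs_label

    @property
    def joint_valid(self) -> np.ndarray:
        """AND of per-layer validity: the strictest mask."""
        v = self.layers[0].valid.copy()
        for g in self.layers[1:]:
            v &= g.valid
        return v

    def to_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_cells, n_layers) matrix of the cells selected by *mask*.

        Defaults to the joint validity mask; row order is C order over the
        grid, which every consumer in the package relies on.
        """
        m = self.joint_valid if mask is None else mask
        return np.column_stack([g.values[m] for g in self.layers])


def assert_coregistered(stack: GridStack | Grid | CategoricalGrid,
                        *others: Grid | CategoricalGrid | GridStack) -> None:
    """Check that all arguments share shape, transform and crs_label.

    Raises :class:`CoregistrationError` naming the offending pair and the
    differing field; passes silently otherwise.
    """
    flat: list[tuple[str, Grid | CategoricalGrid]] = []

    def _add(obj, label):
        if isinstance(obj, GridStack):
            for name, g in zip(obj.names, obj.layers):
                flat.append((f"{label}[{name}]", g))
        else:
            flat.append((label, obj))

    _add(stack, "arg0")
    for i, o in enumerate(others, start=1):
        _add(o, f"arg{i}")
    if not flat:
        raise ValueError("nothing to check")
    ref_label, ref = flat[0]
    for label, g in flat[1:]:
        if g.shape != ref.shape:
            raise CoregistrationError(
                f"shape mismatch between {ref_label} {ref.shape} and {label} {g.shape}")
        if not ref.transform.close_to(g.transform):
            raise CoregistrationError(
                f"transform mismatch between {ref_label} {ref.transform} "
                f"and {label} {g.transform}")
        if g.crs_label != ref.crs_label:
            raise CoregistrationError(
                f"crs mismatch between {ref_label} {ref.crs_label!r} "
                f"and {label} {g.crs_label!r}")


def dominant_type_resample(fine: CategoricalGrid, factor: int) -> CategoricalGrid:
    """Aggregate a categorical grid by majority vote within factor x factor blocks.

    Each coarse cell takes the most frequent code among its block of fine
    cells (invalid fine cells do not vote); ties break to the lowest code.
    Trailing rows/columns that do not fill a block are dropped with a
    logged warning.  A coarse cell is invalid only if its whole block is.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    nr, nc = fine.shape
    cr, cc = nr // factor, nc // factor
    if cr == 0 or cc == 0:
        raise ValueError("grid smaller than one block")
    if nr % factor or nc % factor:
        logger.warning(
            "dominant_type_resample: dropping %d trailing rows and %d trailing "
            "columns not filling a %dx%d block", nr % factor, nc % factor,
            factor, factor)
    codes = fine.codes[: cr * factor, : cc * factor]
    valid = fine.valid[: cr * factor, : cc * factor]
    blocks = codes.reshape(cr, factor, cc, factor).swapaxes(1, 2).reshape(cr, cc, -1)
    bvalid = valid.reshape(cr, factor, cc, factor).swapaxes(1, 2).reshape(cr, cc, -1)

    max_code = int(codes.max(initial=0))
    counts = np.zeros((cr, cc, max_code + 1), dtype=np.int64)
    for code in range(max_code + 1):
        counts[:, :, code] = ((blocks == code) & bvalid).sum(axis=2)
    # np.argmax returns the first maximum, i.e. the lowest code on ties
    out_codes = counts.argmax(axis=2).astype(fine.codes.dtype)
    out_valid = bvalid.any(axis=2)
    out_codes[~out_valid] = 0

    t = fine.transform
    coarse_t = Transform(t.x_origin, t.y_origin,
                         t.cell_width * factor, t.cell_height * factor)
    return CategoricalGrid(out_codes, dict(fine.class_table), out_valid,
                           coarse_t, fine.crs_label, fine.nodata_code)
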