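"""Seeded synthetic landscapes: correlated random fields, masks, networks.

The generator emulates the statistical structure the analysis assumes of
real environmental driver stacks: many continuous layers that are both
spatially autocorrelated (Gaussian random fields, spectral synthesis) and
strongly cross-correlated (one dominant shared gradient plus weaker
independent structure, as climate/soil driver sets typically show), a
four-class working-lands mask with spatially coherent patches, and site
networks of clustered experimental centroids.  Everything is a pure
function of (spec, seed).

Stream order: the landscape seed is expanded with ``np.random.SeedSequence``
into one child stream per layer (noise), in layer order; mask thresholding
is deterministic; networks carry their own seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import CategoricalGrid, Grid, GridStack, Transform
from .sites import Centroid, SiteNetwork

logger = logging.getLogger(__name__)

#: default inter-layer correlation of the shared environmental gradient.
#: The default landscape is built around one dominant gradient: every layer
#: shares it with weight sqrt(rho) plus independent local variation, so the
#: leading principal component carries ~rho of the variance and a network
#: stratified along the gradient can recover it as constituencies.
DEFAULT_CROSS_CORR = 0.92

#: default working-lands class proportions (code order: non-working,
#: cropland, grazingland, mixed), patterned after conterminous-US fractions
DEFAULT_CLASS_PROPORTIONS = {
    "non-working": 0.35,
    "cropland": 0.20,
    "grazingland": 0.43,
    "mixed": 0.02,
}

CLASS_CODES = {"non-working": 0, "cropland": 1, "grazingland": 2, "mixed": 3}
#: class order along the latent gradient, driest/poorest to wettest/richest
LATENT_CLASS_ORDER = ["non-working", "grazingland", "cropland", "mixed"]


def compound_symmetry(n_layers: int, rho: float = DEFAULT_CROSS_CORR) -> np.ndarray:
    """Equicorrelation matrix: every off-diagonal entry equals *rho*."""
    c = np.full((n_layers, n_layers), rho)
    np.fill_diagonal(c, 1.0)
    return c


@dataclass
class LandscapeSpec:
    nrows: int = 128
    ncols: int = 128
    n_layers: int = 15
    correlation_length: float = 12.0
    cross_corr: np.ndarray | None = None
    seed: int = 0
    cell_size: float = 1000.0
    crs_label: str = "synthetic"

    def __post_init__(self) -> None:
        if min(self.nrows, self.ncols, self.n_layers) < 1:
            raise ValueError("nrows, ncols, n_layers must be positive")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be > 0")
        if self.cross_corr is None:
            self.cross_corr = compound_symmetry(self.n_layers)
        self.cross_corr = np.asarray(self.cross_corr, dtype=float)
        if self.cross_corr.shape != (self.n_layers, self.n_layers):
            raise ValueError("cross_corr must be n_layers x n_layers")
        if not np.allclose(self.cross_corr, self.cross_corr.T):
            raise ValueError("cross_corr must be symmetric")
        if not np.allclose(np.diag(self.cross_corr), 1.0):
            raise ValueError("cross_corr diagonal must be all 1")
        if np.linalg.eigvalsh(self.cross_corr).min() < -1e-8:
            raise ValueError("cross_corr must be positive semi-definite")

    @property
    def transform(self) -> Transform:
        return Transform(0.0, self.nrows * self.cell_size,
                         self.cell_size, self.cell_size)


@dataclass
class MaskConfig:
    """How the categorical mask is carved from a latent layer.

    Either *proportions* (target class fractions, converted to quantile
    thresholds of the latent layer) or explicit *thresholds* (three
    strictly increasing cut points).  Classes are laid out along the
    latent gradient in :data:`LATENT_CLASS_ORDER`.
    """

    latent_layer: int = 0
    proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    thresholds: list[float] | None = None


@dataclass
class NetworkSpec:
    n_sites: int = 10
    centroids_per_site: tuple[int, int] = (5, 50)
    centroid_jitter: float = 2.0
    placement: str = "random"
    seed: int = 0
    strata_layer: int | str = "mean"
    name: str = "network"

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        lo, hi = self.centroids_per_site
        if lo < 1 or hi < lo:
            raise ValueError("centroids_per_site must be a range with lower bound >= 1")
        if self.centroid_jitter < 0:
            raise ValueError("centroid_jitter must be >= 0")
        if self.placement not in ("random", "stratified"):
            raise ValueError(f"unknown placement {self.placement!r}")


def _gaussian_field(rng: np.random.Generator, nrows: int, ncols: int,
                    length: float) -> np.ndarray:
    """One standardized Gaussian random field by spectral synthesis.

    White noise is low-pass filtered in the Fourier domain with a Gaussian
    transfer function whose e-folding scale is *length* cells, giving an
    approximately Gaussian spatial correlation function.  Boundaries are
    periodic (an accepted artifact of the FFT route).
    """
    noise = rng.standard_normal((nrows, ncols))
    ky = np.fft.fftfreq(nrows)[:, None]
    kx = np.fft.fftfreq(ncols)[None, :]
    k2 = (2 * np.pi) ** 2 * (ky ** 2 + kx ** 2)
    transfer = np.exp(-0.5 * k2 * length ** 2)
    fld = np.fft.ifft2(np.fft.fft2(noise) * transfer).real
    fld -= fld.mean()
    sd = fld.std()
    if sd == 0:  # pathological length >> grid
        return np.zeros_like(fld)
    return fld / sd


def generate_fields(spec: LandscapeSpec) -> GridStack:
    """Generate the correlated environmental layer stack for *spec*.

    Independent standardized fields are mixed through the symmetric square
    root of ``cross_corr`` (eigenvalues clipped at zero, tolerating
    near-PSD input), then re-standardized per layer, so sample inter-layer
    correlations track the target matrix.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_layers)
    raw = np.stack([
        _gaussian_field(np.random.default_rng(child), spec.nrows, spec.ncols,
                        spec.correlation_length)
        for child in children
    ])  # (n_layers, nrows, ncols)

    evals, evecs = np.linalg.eigh(spec.cross_corr)
    mix = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T
    flat = raw.reshape(spec.n_layers, -1)
    mixed = mix @ flat
    mixed -= mixed.mean(axis=1, keepdims=True)
    sd = mixed.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    mixed /= sd
    fields = mixed.reshape(spec.n_layers, spec.nrows, spec.ncols)

    valid = np.ones((spec.nrows, spec.ncols), dtype=bool)
    layers = [Grid(fields[i], valid.copy(), spec.transform, spec.crs_label)
              for i in range(spec.n_layers)]
    names = [f"env_{i + 1:02d}" for i in range(spec.n_layers)]
    return GridStack(layers, names)


def generate_mask(stack: GridStack, config: MaskConfig | None = None) -> CategoricalGrid:
    """Threshold a latent layer of *stack* into the four working-lands classes.

    The latent layer's spatial autocorrelation is what makes the classes
    form coherent patches; no explicit patch model is involved.
    """
    config = config or MaskConfig()
    latent = stack[config.latent_layer]
    valid = stack.joint_valid
    vals = latent.values[valid]

    if np.ptp(vals) == 0:
        logger.warning("generate_mask: constant latent layer; single-class mask")
        codes = np.zeros(stack.shape, dtype=np.int64)
        name = LATENT_CLASS_ORDER[0]
        codes[valid] = CLASS_CODES[name]
        return CategoricalGrid(codes, {CLASS_CODES[n]: n for n in CLASS_CODES},
                               valid.copy(), stack.transform, stack.crs_label)

    if config.thresholds is not None:
        cuts = np.asarray(config.thresholds, dtype=float)
    else:
        order = LATENT_CLASS_ORDER
        fracs = np.array([config.proportions[name] for name in order])
        fracs = fracs / fracs.sum()
        cuts = np.quantile(vals, np.cumsum(fracs)[:-1])
    if len(cuts) != len(LATENT_CLASS_ORDER) - 1 or np.any(np.diff(cuts) <= 0):
        raise ValueError(f"thresholds must be {len(LATENT_CLASS_ORDER) - 1} "
                         f"strictly increasing values, got {cuts}")

    bins = np.digitize(latent.values, cuts)  # 0..3 along the latent gradient
    code_by_bin = np.array([CLASS_CODES[name] for name in LATENT_CLASS_ORDER])
    codes = code_by_bin[bins]
    codes[~valid] = 0
    return CategoricalGrid(codes.astype(np.int64),
                           {CLASS_CODES[n]: n for n in CLASS_CODES},
                           valid.copy(), stack.transform, stack.crs_label)


def _strat_values(stack: GridStack, strata_layer: int | str) -> np.ndarray:
    if strata_layer == "mean":
        return np.mean([g.values for g in stack.layers], axis=0)
    return stack[int(strata_layer)].values


def generate_network(stack: GridStack, spec: NetworkSpec) -> SiteNetwork:
    """Place sites and their clustered centroids on valid cells of *stack*.

    ``random`` placement draws anchor cells uniformly from valid cells;
    ``stratified`` splits the designated gradient layer (default: the
    cross-layer mean, i.e. the dominant shared gradient) into ``n_sites``
    quantile strata and anchors one site on a typical cell of each stratum
    (a random cell from the stratum's inner quartile range).  Centroids are
    the anchor plus rounded Gaussian jitter, re-drawn (bounded retries)
    until they land on valid cells.  PC values are left unsampled.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    valid = stack.joint_valid
    nrows, ncols = stack.shape
    valid_rc = np.argwhere(valid)
    if len(valid_rc) < spec.n_sites:
        raise ValueError("not enough valid cells for n_sites")

    stratum_ok = None  # in stratified mode: cell -> may host this site's centroids
    if spec.placement == "random":
        picks = rng.choice(len(valid_rc), size=spec.n_sites, replace=False)
        anchors = valid_rc[picks]
    else:
        strat = _strat_values(stack, spec.strata_layer)
        vals = strat[valid]
        edges = np.quantile(vals, np.linspace(0, 1, spec.n_sites + 1))
        anchors = []
        stratum_ok = np.zeros((spec.n_sites,) + stack.shape, dtype=bool)
        for s in range(spec.n_sites):
            lo, hi = edges[s], edges[s + 1]
            in_stratum = (vals >= lo) & (vals <= hi if s == spec.n_sites - 1
                                         else vals < hi)
            # the stratum's most typical cell: gradient value nearest the
            # stratum median (deterministic given the landscape)
            med = np.median(vals[in_stratum])
            idx = np.flatnonzero(in_stratum)
            anchors.append(valid_rc[idx[np.abs(vals[idx] - med).argmin()]])
            # a stratified site samples its own stratum: jittered centroids
            # may not cross into a neighbouring stratum
            ok = np.zeros(stack.shape, dtype=bool)
            ok[tuple(valid_rc[idx].T)] = True
            stratum_ok[s] = ok
        anchors = np.array(anchors)

    centroids: list[Centroid] = []
    t = stack.transform
    for s, (ar, ac) in enumerate(anchors):
        site = f"S{s + 1:02d}"
        allowed = valid if stratum_ok is None else stratum_ok[s]
        n_cent = int(rng.integers(spec.centroids_per_site[0],
                                  spec.centroids_per_site[1] + 1))
        for j in range(n_cent):
            row, col = -1, -1
            for _attempt in range(100):
                if spec.centroid_jitter == 0:
                    row, col = int(ar), int(ac)
                else:
                    dr, dc = np.rint(
                        rng.normal(0.0, spec.centroid_jitter, size=2)).astype(int)
                    row = int(np.clip(ar + dr, 0, nrows - 1))
                    col = int(np.clip(ac + dc, 0, ncols - 1))
                if allowed[row, col]:
                    break
            else:
                raise RuntimeError(
                    f"no valid cell found near anchor of {site} after 100 tries "
                    f"(jitter={spec.centroid_jitter})")
            x, y = t.cell_center(row, col)
            centroids.append(Centroid(site=site, centroid_id=f"{site}-{j + 1}",
                                      x=x, y=y))
    return SiteNetwork(name=spec.name, centroids=centroids)
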