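"""Principal-component feature space over a raster stack.

The environmental layers are standardized (centred, and by default scaled
to unit variance — the layers carry incommensurable units, so correlation
PCA is the sensible default) over the jointly valid cells, and decomposed
by SVD.  All multivariate distances downstream are measured in the
truncated score space selected by cumulative explained variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .grid import Grid, GridStack


@dataclass
class FeatureSpace:
    """Fitted standardization + PCA and the per-cell score stack.

    ``loadings`` has one column per component (orthonormal); columns are
    sign-fixed so the largest-magnitude loading in each is positive,
    making results reproducible across linear-algebra backends.
    ``scores`` holds the leading ``n_selected`` component layers; its
    validity mask equals the input stack's joint validity.
    """

    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray
    variance_fraction: np.ndarray
    n_selected: int
    scores: GridStack
    layer_names: list[str]
    standardized: bool = True
    _full_scores: np.ndarray | None = None  # (n_valid, n_components) cache

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def valid(self) -> np.ndarray:
        return self.scores.joint_valid

    def score_matrix(self) -> np.ndarray:
        """(n_valid, n_selected) matrix of scores, C order over the grid."""
        return self.scores.to_matrix()

    def transform_points(self, values: np.ndarray) -> np.ndarray:
        """Project raw layer vectors (n, n_layers) into the selected score space."""
        z = (np.atleast_2d(values) - self.means) / self.sds
        return z @ self.loadings[:, : self.n_selected]


def fit_pca(stack: GridStack, standardize: bool = True,
            mask: np.ndarray | None = None) -> FeatureSpace:
    """Fit standardization + PCA over the (masked) valid cells of *stack*.

    *mask* restricts the cells entering the fit statistics (e.g. a
    working-lands-only fit); scores are still produced for every jointly
    valid cell.  Components come out ordered by decreasing variance.
    """
    if len(stack) < 2:
        raise ValueError("need at least 2 layers for a PCA")
    joint = stack.joint_valid
    fit_mask = joint if mask is None else (joint & mask)
    n_fit = int(fit_mask.sum())
    if n_fit < len(stack):
        raise ValueError(f"only {n_fit} valid cells for {len(stack)} layers")

    X_fit = stack.to_matrix(fit_mask)
    means = X_fit.mean(axis=0)
    if standardize:
        sds = X_fit.std(axis=0, ddof=0)
        dead = np.flatnonzero(sds == 0)
        if dead.size:
            names = [stack.names[i] for i in dead]
            raise ValueError(f"zero-variance layer(s) cannot be standardized: {names}")
    else:
        sds = np.ones_like(means)

    Zfit = (X_fit - means) / sds
    pca = PCA(n_components=len(stack), svd_solver="full")
    pca.fit(Zfit)
    loadings = pca.components_.T  # (n_layers, n_components)
    variance_fraction = pca.explained_variance_ratio_.copy()

    # deterministic sign: largest-|loading| entry of each column positive
    flip = loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])] < 0
    loadings[:, flip] *= -1.0

    Zall = (stack.to_matrix(joint) - means) / sds
    full_scores = Zall @ loadings

    layers = []
    for k in range(loadings.shape[1]):
        vals = np.zeros(stack.shape)
        vals[joint] = full_scores[:, k]
        vals[~joint] = np.nan
        layers.append(Grid(vals, joint.copy(), stack.transform, stack.crs_label,
                           nodata=np.nan))
    names = [f"pc_{k + 1}" for k in range(loadings.shape[1])]
    scores = GridStack(layers, names)

    return FeatureSpace(means=means, sds=sds, loadings=loadings,
                        variance_fraction=variance_fraction,
                        n_selected=loadings.shape[1], scores=scores,
                        layer_names=list(stack.names), standardized=standardize,
                        _full_scores=full_scores)


def select_components(fs: FeatureSpace, threshold: float) -> FeatureSpace:
    """Truncate to the smallest k whose cumulative variance >= *threshold*."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    cum = np.cumsum(fs.variance_fraction)
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    k = min(k, fs.n_components)
    scores = GridStack(fs.scores.layers[:k], fs.scores.names[:k])
    return FeatureSpace(means=fs.means, sds=fs.sds, loadings=fs.loadings,
                        variance_fraction=fs.variance_fraction, n_selected=k,
                        scores=scores, layer_names=fs.layer_names,
                        standardized=fs.standardized, _full_scores=fs._full_scores)


def reconstruct(fs: FeatureSpace) -> np.ndarray:
    """Inverse-project the *selected* scores back to standardized layer space.

    With all components retained this recovers the standardized inputs to
    numerical precision; with a truncation it is the least-squares
    approximation.  Returns (n_valid, n_layers).
    """
    S = fs.score_matrix()
    return S @ fs.loadings[:, : fs.n_selected].T
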