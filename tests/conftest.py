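import numpy as np
import pytest

import netrep as nr


@pytest.fixture(scope="session")
def small_landscape():
    """A 10x10, 5-layer landscape with a fitted 3-component feature space
    and a sampled 3-site network — shared by the oracle-equivalence tests."""
    spec = nr.LandscapeSpec(nrows=10, ncols=10, n_layers=5,
                            correlation_length=2.0,
                            cross_corr=np.eye(5), seed=7)
    stack = nr.generate_fields(spec)
    fs = nr.fit_pca(stack)
    cum = np.cumsum(fs.variance_fraction)
    fs = nr.select_components(fs, float(cum[2]))
    net = nr.generate_network(stack, nr.NetworkSpec(
        n_sites=3, centroids_per_site=(1, 3), centroid_jitter=1.5, seed=11))
    net = nr.sample_centroids(net, fs)
    return stack, fs, net


@pytest.fixture(scope="session")
def default_demo():
    """A mid-size run with every input the downstream stages need."""
    spec = nr.LandscapeSpec(nrows=48, ncols=48, n_layers=8, seed=21,
                            cross_corr=nr.compound_symmetry(8))
    stack = nr.generate_fields(spec)
    mask = nr.generate_mask(stack)
    fs = nr.select_components(nr.fit_pca(stack), 0.9)
    net = nr.generate_network(stack, nr.NetworkSpec(
        n_sites=6, centroids_per_site=(2, 6), centroid_jitter=2.0, seed=22))
    net = nr.sample_centroids(net, fs)
    norm = nr.normalization_constant(fs)
    rep = nr.site_representativeness(net, fs, norm)
    return {"stack": stack, "mask": mask, "fs": fs, "net": net,
            "norm": norm, "rep": rep}


def grid_from(values, nodata_mask=None, cell=1.0):
    values = np.asarray(values, dtype=float)
    valid = np.ones(values.shape, bool) if nodata_mask is None else ~np.asarray(nodata_mask)
    t = nr.Transform(0.0, values.shape[0] * cell, cell, cell)
    return nr.Grid(values, valid, t)
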