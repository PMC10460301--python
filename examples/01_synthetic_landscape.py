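"""Generate a synthetic landscape: correlated environmental fields, a
working-lands mask, and a clustered site network.

The fields are seeded Gaussian random fields sharing one dominant
gradient (as real climate/soil driver stacks do); the mask is carved from
the first field's quantiles, so its classes form coherent patches.
"""

import numpy as np

import netrep as nr

spec = nr.LandscapeSpec(nrows=96, ncols=96, n_layers=15, seed=7)
stack = nr.generate_fields(spec)
mask = nr.generate_mask(stack)
net = nr.generate_network(stack, nr.NetworkSpec(
    n_sites=8, centroids_per_site=(3, 12), centroid_jitter=2.0, seed=8))

corr = np.corrcoef(stack.to_matrix().T)
off = corr[~np.eye(len(corr), dtype=bool)]
print(f"{len(stack)} layers on a {stack.shape} grid, "
      f"{int(stack.joint_valid.sum())} valid cells")
print(f"inter-layer correlation: mean {off.mean():.2f} "
      f"(the shared environmental gradient)")
for code, name in sorted(mask.class_table.items()):
    frac = (mask.codes[mask.valid] == code).mean()
    print(f"  {name:12s} {100 * frac:5.1f}% of cells")
print(f"network: {len(net.sites)} sites, {len(net)} centroids "
      f"(each site a local cluster of experimental areas)")
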