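"""Cross-network complementarity: would borrowing sister sites help?

Two sister networks are placed on the same landscape; cells where a
sister's network-level representativeness beats the home network's are
exactly the cells where borrowing that sister's best site would raise
home representativeness.  The worst remaining gaps are nominated as
candidate locations for genuinely new sites.
"""

import netrep as nr

stack = nr.generate_fields(nr.LandscapeSpec(nrows=96, ncols=96,
                                            n_layers=15, seed=7))
mask = nr.generate_mask(stack)
fs = nr.select_components(nr.fit_pca(stack), 0.90)


def sampled(n_sites, seed, name):
    net = nr.generate_network(stack, nr.NetworkSpec(
        n_sites=n_sites, centroids_per_site=(2, 8), seed=seed, name=name))
    return nr.sample_centroids(net, fs)


home = sampled(8, 8, "home")
sisters = [nr.filter_by_mask_class(sampled(4, 20, "neon"), mask,
                                   ["cropland", "grazingland", "mixed"]),
           nr.filter_by_mask_class(sampled(3, 30, "lter"), mask,
                                   ["cropland", "grazingland", "mixed"])]
norm = nr.normalization_constant(fs)  # one shared constant: values comparable

mn = nr.best_network_map([home, *sisters], fs, norm, mask=mask,
                         classes=["cropland", "grazingland", "mixed"])
v = mn.best_network.valid
for i, name in enumerate(mn.networks):
    frac = (mn.best_network.codes[v] == i).mean()
    print(f"  {name:6s} best represents {100 * frac:5.1f}% of working lands")
imp = mn.improvement.values[mn.improvement.valid]
print(f"borrowing all sister centroids raises home representativeness by "
      f"{imp.mean():.4f} on average (max {imp.max():.3f})")
if len(mn.borrowed_sites):
    print(mn.borrowed_sites.round(4).to_string(index=False))

gaps = nr.candidate_gaps(mn.per_network["home"], mask,
                         classes=["cropland", "grazingland", "mixed"], k=3)
print("worst-represented spaced gap cells (candidates for new sites):")
print(gaps.round(3).to_string(index=False))
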