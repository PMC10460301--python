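# netrep

Representativeness and constituency analysis of environmental
observation site networks on gridded landscapes.

Ecological and agroecosystem research networks (flux towers, long-term
experimental sites, observatories) need to know how far their results
generalize: **how well do the environments sampled at the network's
sites represent every location in the region of interest, and which
site best represents each location?** `netrep` answers both questions
with exhaustive multivariate similarity — no clustering, no spatial
smoothing — for people designing, evaluating or growing such networks.

## The method

1. **Feature space.** A stack of co-registered environmental raster
   layers is standardized and reduced by PCA; the leading components
   reaching a cumulative explained-variance threshold (default 0.90)
   define the score space.
2. **Representativeness.** For a site centroid with score vector
   *V*ⁿ(site) and a grid cell with *V*ⁿ(cell),

   representativeness = 1 − √( Σₙ ( *V*ⁿ(site) − *V*ⁿ(cell) )² ) / *D*,

   where *D* normalizes distance into [0, 1] (default: the PC-space
   bounding-box diameter of the landscape). 1 means an identical
   environment; 0 the most dissimilar pair the landscape can hold.
   Per-site surfaces aggregate a site's centroids (default cellwise
   max); the network surface is the cellwise max over all centroids.
3. **Constituency.** Every masked cell is assigned to its
   best-representing site (pure argmax, with ranked runner-ups), giving
   an ecoregion-like partition centred on the actual sites, plus
   per-site area/distribution summaries and a
   generalist / specialist / double-duty triage.
4. **Complementarity.** Sister networks on the same landscape are
   compared under one shared normalization: best-network maps,
   improvement surfaces from borrowing sister sites, and spaced
   candidate locations for new sites at the worst remaining gaps.

A seeded synthetic landscape generator (correlated Gaussian random
fields, coherent working-lands masks, clustered site networks) makes
the whole pipeline runnable and testable with no data downloads. See
`docs/methods.md` for assumptions, defaults and design rationale.

## A worked example

```sh
python examples/03_representativeness.py
```

```
normalization constant (bbox diameter) = 17.217
network representativeness: mean 0.938, min 0.679 (every sampled centroid cell scores exactly 1)
 mask_class  n_cells  empty  mean  median    sd
non-working     3226  False 0.926   0.960 0.075
   cropland     1843  False 0.900   0.912 0.058
grazingland     3962  False 0.973   0.977 0.019
      mixed      185  False 0.754   0.751 0.028
```

On this 96×96 synthetic landscape the 8-site network leaves no cell
below 0.679, and grazinglands are its best-covered class (mean 0.973):
the sites' sampled environments sit closest, in PC space, to the
environments where that class occurs. The mask classes with lower means
are where network growth or site borrowing would pay off most;
`examples/04_constituency.py` and `examples/05_complementarity.py`
continue the same landscape into the partition and borrowing analyses.

The `netrep` command drives the same stages from a shell
(`netrep synth | pca | represent | constituency | complement | summarize | run`),
with `netrep run --config cfg.yaml` executing the full pipeline and
writing a manifest of checksums, versions and stage timings.

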