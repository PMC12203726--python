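# tadcore

Quantifying where a genomic locus sits inside the 3D structure of its
chromatin domain — on the surface, exposed to the rest of the nucleus, or
buried in the core — from any of five 3D-genome data modalities, without
imaging every cell.

Topologically associating domains (TADs) detected in bulk Hi-C correspond,
in individual cells, to variable, roughly globular single-cell domains
(scDomains). A locus near the *core* of its scDomain is isolated from loci
outside the domain, while a locus on the *surface* interacts with them
freely; this coreness correlates with regulatory activity, expression,
replication timing and the locations of non-coding variants. `tadcore`
computes a per-bin **intra-TAD ratio** that estimates coreness, classifies
bins into domain-surface and domain-core sets, and runs the downstream
enrichment and association analyses, for users working with SPRITE
multiplex clusters, bulk Hi-C, single-cell Hi-C, 3D structural models
(e.g. Dip-C), or chromatin-tracing imaging data.

## The statistic

For a genomic bin *i* in a multiplex read cluster *j* containing
*C<sub>j</sub>* distinct bins,

> r<sub>ij</sub> = N<sub>ij</sub> / (C<sub>j</sub> − 1)

where *N<sub>ij</sub>* counts cluster members in the same TAD as bin *i*.
The bin's intra-TAD ratio r<sub>i</sub> is the unweighted mean of
r<sub>ij</sub> over all clusters containing it (bins supported by fewer
than 100 clusters are dropped by default). For pairwise contact data the
ratio is intra-TAD contact weight over total contact weight of the bin; for
structural models it is the fraction of the *k* = 10 Euclidean nearest
neighbours in the same TAD (and, for diploid models, the same haplotype);
for imaging it is the fraction of imaged loci within 500 nm belonging to
the bin's scDomain.

Within each TAD *k* of *n<sub>k</sub>* bins, bins with ratio at or below
the q<sub>k</sub>-th quantile, q<sub>k</sub> = n<sub>k</sub><sup>−1/3</sup>,
are labeled **surface**, the rest **core** — the exponent follows the
surface-to-volume scaling S/V ∝ V<sup>−1/3</sup> of a sphere. Feature
enrichment on surfaces uses the fold (d/c)/(b/a) (a TAD bins, b surface
bins, c feature bins, d feature bins on surfaces) with an upper-tail
hypergeometric p-value, and a shuffled-TAD null preserving the TAD-size and
gap-size multisets provides the negative control.

Because the published data sets behind these analyses are large external
downloads, the package ships a synthetic single-cell domain generator
(`tadcore.synthetic_data`) with known per-bin ground-truth coreness, so the
whole pipeline is testable end to end offline.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr

from tadcore import SimConfig, simulate, sprite_ratio, classify, enrichment
from tadcore.stats import label_feature_bins

# generate a synthetic chromosome: 20 domains x ~50 bins of 10 kb, 500 cells
sim = simulate(SimConfig(seed=1), modalities=("sprite", "signals"))

# intra-TAD ratio from the SPRITE-like multiplex clusters
track = sprite_ratio(sim.clusters, sim.tads, sim.index, min_bin_support=100)
rho = spearmanr(track.values[track.mask], sim.tendency[track.mask])[0]
print(f"bins with ratio: {int(track.mask.sum())}/{sim.index.n_bins}")
print(f"Spearman(ratio, planted coreness) = {rho:.3f}")

# surface/core split at the per-TAD q_k = n_k^(-1/3) quantile
labels = classify(track, sim.tads, sim.index)
print(f"surface bins: {int(labels.surface_mask.sum())}, "
      f"core bins: {int(labels.core_mask.sum())}")

# enrichment of the implanted features on domain surfaces
universe = np.flatnonzero(labels.labels != -1)
surface = np.flatnonzero(labels.surface_mask)
feats = label_feature_bins(sim.features, sim.index)["feature"]
r = enrichment(feats, universe, surface)
print(f"surface enrichment fold = {r.fold:.2f}, p = {r.p_value:.2e}")
```

prints

```
bins with ratio: 958/958
Spearman(ratio, planted coreness) = 0.673
surface bins: 268, core bins: 690
surface enrichment fold = 2.41, p = 4.74e-14
```

The ratio computed from ~100,000 simulated clusters rank-correlates 0.67
with the generator's hidden per-bin coreness tendency; about 28% of bins
fall on domain surfaces (the average n<sub>k</sub><sup>−1/3</sup>); and
features implanted with threefold surface preference are recovered as
significantly surface-enriched (the 2.4 estimate is attenuated relative to
3 because classification here uses the *estimated* ratio rather than the
ground truth).

The same workflows are available from the shell:

```sh
tadcore simulate --preset default --seed 1 --out sim/
tadcore ratio sprite --clusters sim/clusters.tsv --tads sim/tads.bed \
    --chrom-sizes sim/chrom.sizes --out sim/ratio.tsv
tadcore classify --ratios sim/ratio.tsv --tads sim/tads.bed \
    --chrom-sizes sim/chrom.sizes --out sim/labels.tsv
tadcore enrich --labels sim/labels.tsv --features sim/features.bed \
    --chrom-sizes sim/chrom.sizes --out sim/enrich.tsv
```

Every command writes a JSON manifest (parameters, input checksums, seed,
version) beside its outputs, and reruns with the same seed are
byte-identical.

## Layout

| module | contents |
|---|---|
| `tadcore.genome_model` | bin index, TAD/interval/signal/ratio containers |
| `tadcore.io_formats` | BED, SPRITE clusters, COO contacts, .pairs, structure tables, imaging CSV |
| `tadcore.ratio_engine` | the five ratio pathways + cell subsampling |
| `tadcore.domain_geometry` | scDomain calling, convex hulls, co-membership, geometric coreness |
| `tadcore.surface_core` | q_k classification, boundary exclusion, shuffled-TAD null |
| `tadcore.stats` | enrichment, discretization, per-TAD correlation, rank-sum, interaction OLS |
| `tadcore.synthetic_data` | the generator and its configuration |
| `tadcore.cli` | `tadcore` command-line entry point |

See `docs/methods.md` for the generative model, parameter defaults and
numerical conventions.
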