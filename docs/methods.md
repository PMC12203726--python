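# Methods

## The coreness model

The package treats a chromatin domain in a single cell (an scDomain) as a
compact 3D point cloud of genomic bins. A bin's *coreness* is its tendency,
across cells, to occupy the interior of that cloud. Coreness is never
observed directly in sequencing data; the intra-TAD ratio estimates it
through the fraction of a bin's observed spatial neighbours that share its
TAD. The estimator only assumes that surface bins have more chance contacts
with loci outside the domain than core bins do — it does not require
domains to be strictly globular, which is why all distribution-level
guarantees in the test suite are stated on ranks (Spearman) rather than on
absolute geometry.

## Ratio pathways

All five pathways share the same conventions:

* Coordinates are 0-based half-open; fixed-size bins tile each chromosome
  (last bin may be short); a bin belongs to a TAD iff its midpoint lies in
  the TAD interval (the midpoint rule is the package's choice — partial
  overlaps are not otherwise specified — and is symmetric and
  deterministic).
* Bins outside all TADs never receive a ratio and are excluded from every
  enrichment universe, but they do count as real members of a cluster or as
  contact partners, so denominators reflect observed complex sizes.
* Missing is explicit: a ratio track stores NaN plus a support count, and
  `support == 0` iff the value is missing.

**Multiplex clusters (SPRITE).** Reads are deduplicated to unique bins per
cluster; C_j counts unique bins (the only reading that keeps
r_ij = N_ij/(C_j − 1) ≤ 1 when one bin receives several reads). Clusters
with fewer than 2 or more than 1000 bins are dropped; bins supported by
fewer than 100 clusters are set missing. r_i is the *unweighted* mean over
clusters — each cluster one vote, matching the per-cluster normalisation by
C_j − 1; a read-weighted variant was deliberately not used. Intra-
chromosomal mode partitions each cluster by chromosome first and re-derives
C_j per sub-cluster (size-1 sub-clusters carry no pair information and are
dropped). The adjacent-TAD exclusion removes members lying in the two TADs
1D-adjacent to the bin's TAD from the denominator; they are never intra, so
the numerator is unchanged, and members whose denominator reaches zero
yield no record.

**Pairwise contacts (bulk and single-cell).** Ratio = intra-TAD contact
weight over total contact weight of the bin; self-pairs are excluded, and
inter-chromosomal pairs are excluded by default (a flag includes them).
Single-cell tracks are averaged over the cells that observe each bin, with
support counting cells.

**Structural models.** For each positioned bin, its k = 10 Euclidean
nearest neighbours over all positioned bins of the model are found; the
ratio is the fraction in the same TAD, and in haplotype-aware mode also on
the same haplotype (a same-TAD neighbour on the other haplotype is *not*
intra). Ties at the k-th distance are broken by ascending bin id
(distances compared after rounding at 1e-9, so the break is deterministic);
models with fewer than k + 1 points contribute nothing and are logged.
Coarse models can be projected to a finer bin size by duplicating each
parent bin's value onto its children (e.g. 20 kb → two 10 kb bins).

**Imaging.** The neighbourhood of an imaged bin is the set of other imaged
bins within 500 nm of its coordinates in that cell; the ratio is the
fraction belonging to the bin's scDomain. Bins with missing coordinates or
empty neighbourhoods are missing.

Cell subsampling draws x cells without replacement (sorted before
averaging so equal draws average identically), averages pairwise-complete,
and reports Pearson and Spearman correlation with a reference track per
repeat; all randomness flows from one explicit seed.

## scDomain calling and geometry

The spatial insulation score at position i contrasts the w = 5 bins
upstream with the w bins downstream: median cross-window pairwise distance
divided by the median of within-window pairwise distances. Windows with
fewer than 3 positioned bins yield no score. Boundaries are local maxima of
the score whose **topographic prominence** exceeds 1.2 — prominence, rather
than an absolute score threshold, because the score fluctuates around 1
inside a homogeneous domain and an absolute cutoff over-segments; the
inter-domain peak rises several units above its surrounding valleys.
Adjacent domains whose cross-domain median distance is below 0.9 times
their pooled within-domain median are merged. This caller is a concrete
re-specification validated on synthetic geometry (a two-blob cell yields
one boundary at the junction ± 1 bin); it is *not* a bit-exact replica of
any published imaging-analysis code, and comparisons should say so.

Convex hulls use `scipy.spatial.ConvexHull` per scDomain; domains with
fewer than four positioned bins or degenerate geometry are all-vertex by
convention. Geometric coreness — the synthetic ground truth — is
1 − (distance to domain centroid)/(max such distance in the domain).

## Surface/core classification and the shuffled null

Within each TAD, the threshold is the empirical q_k = n_k^(−1/3) quantile
(linear interpolation between order statistics) of the TAD's non-missing
ratios; comparison is inclusive (≤), so ties can only enlarge the surface
set and it is never empty. n_k counts all bins of the TAD whether or not
their ratio is observed. With distinct ratios this yields exactly
round-down counts: 4 surface bins in an 8-bin TAD, 100 in a 1000-bin TAD.
Classification is invariant to strictly monotone transforms of the ratios
within a TAD. Boundary exclusion removes, per flank, the terminal bin plus
ceil(fraction · n_k) neighbours; the 10% default is read per flank (the
total-versus-per-flank reading is ambiguous and sensitivity to it should be
reported, not assumed).

The shuffled-TAD null permutes TAD lengths and gap lengths per chromosome
(the offset before the first TAD counts as a gap) and lays them down from
the chromosome start. The two length lists are permuted independently and
each gap is assigned to a distinct slot before one TAD: a fully joint
permutation of the interleaved list can place two gaps adjacently, merging
them in the resulting intervals, whereas this variant preserves the TAD-size
multiset, the gap-size multiset and the total span exactly — the
conservation law the test suite asserts over hundreds of random genomes.

## Enrichment and association statistics

Enrichment uses bins as sampling units: with a universe of a TAD bins, b
target (surface or core) bins, c feature bins and d feature-on-target bins,
fold = (d/c)/(b/a) and p = P(X ≥ d) under the hypergeometric distribution
(`scipy.stats.hypergeom.sf`); c = 0 or b = 0 reports an undefined fold. A
bin carries a feature category iff it overlaps any interval of that
category, regardless of other categories; labels on an exclusion list
(default `Low-DNase`) are dropped first. Raw p-values are the primary
readout, with Benjamini–Hochberg q-values reported side by side.

Discretization into quantile groups keeps tied values in one group
(`pandas.qcut`), warning when ties collapse groups. The per-TAD expression
analysis computes the Spearman correlation of expression with the ratio
across bins of each TAD with at least 5 jointly observed genes, then a
two-sided one-sample t-test of the correlation list against zero; in the
synthetic data each bin carries one gene, so no TSS table is needed (real
data would attach each gene's expression to its TSS bin). Group comparisons
use the two-sided Mann–Whitney U: exhaustive enumeration of all
C(n1+n2, n1) rank splits when both groups have ≤ 8 values (tie-safe, and
the route by which "identical groups → p = 1" holds exactly), the
tie-corrected normal approximation otherwise. The interaction regression is
ordinary least squares of the ratio on x1, x2 and x1·x2 over jointly
observed bins, with rank-deficient designs flagged rather than silently
pseudo-inverted.

## The synthetic-data generator

The generator's defaults are the package's standard study conditions; every
end-to-end guarantee is stated at these values.

| parameter | default | meaning |
|---|---|---|
| n_domains × bins_per_domain | 20 × 50 (sd 10) | one ~10 Mb chromosome of 10 kb bins |
| n_cells | 500 | cells / structural models |
| domain_radius_scale | 100 nm | ball radius = scale · n^(1/3) (~370 nm at 50 bins) |
| boundary_jitter | 2 bins | per-cell 1D shift of domain boundaries |
| coreness_persistence | 0.8 | weight of the persistent tendency in radial placement |
| clusters_per_cell | 200 | multiplex clusters sampled per cell |
| cluster_radius | 200 nm | capture radius around a cluster's anchor |
| contact_threshold | 300 nm | distance cut for pairwise contacts |
| expression_effect | −2 | slope of log-expression on tendency |
| noise_sd | 0.5 | expression noise |
| feature_fold | 3 | target surface enrichment of implanted features |
| imaging_missing_rate | 0.10 | per-locus detection failure in the imaging read-out |

Each bin draws a persistent tendency t ~ U(0,1). Per cell, domain
boundaries are the consensus ± Normal(0, jitter) (kept ordered, ≥ 2 bins
per domain); domain centres follow a 3D random walk stepping by the sum of
adjacent radii, so consecutive domains touch; a bin's normalised radius in
its domain ball is p·(1 − t) + (1 − p)·U(0,1) clipped to [0,1], placed in a
uniformly random direction. Clusters take the bins within `cluster_radius`
of a uniformly chosen anchor bin and subsample to a log-uniform target size
in [2, 1000]; contacts are all bin pairs within `contact_threshold`,
accumulated over cells (bulk) or kept per cell (.pairs). The 200 nm cluster
radius reflects that a multiplex complex is a compact molecular assembly
much smaller than a whole domain; with a capture ball as large as the
domain itself the per-bin signal washes out, and a soft distance-decay
capture model performed worse (co-members far from each other), so the hard
compact ball was kept. Log-expression is intercept + effect·t + Normal(0,
noise_sd). Features are drawn without replacement from TAD bins with odds
w = F(a − b)/(a − F·b) on truth-surface bins, the value that makes the
*expected* (d/c)/(b/a) equal the requested fold F; truth-surface bins are
defined by applying the same q_k classifier to the tendency track, so
implantation and recovery share one definition of "surface".

All randomness derives from one seed through named
`numpy.random.SeedSequence` children (genome, tendency, structures, sprite,
contacts, signals, features, imaging), so any single artifact regenerates
in isolation and byte-identically.

**What the generator does and does not emulate.** It reproduces the
statistical skeleton the analysis relies on: per-cell domains with jittered
boundaries, persistent radial preferences, proximity-driven cluster and
contact read-outs, negative expression dependence, fold-calibrated feature
implantation, imaging dropout. It does not model polymer physics (loop
extrusion, chain connectivity within domains), genomic-distance decay
beyond what ball geometry induces, trans-chromosomal structure (one
chromosome), coverage biases, or duplicate reads. Passing tests therefore
demonstrate correctness and sensitivity of the estimators under the stated
generative model, not performance on real libraries.

## Problem sizes and numerical notes

The acceptance checks run the default 958-bin, 500-cell simulation
(~100,000 clusters, ~440,000 aggregated contact pairs); the convex-hull
comparison uses 40 cells and the shuffled-TAD null 100 shuffles of the
bulk-contact pathway — sizes chosen so the whole suite completes in well
under a minute on one core while leaving comfortable statistical margins.
Under these conditions the SPRITE pathway rank-correlates ≈ 0.67–0.74 with
the planted tendency across seeds (contacts ≈ 0.56–0.65, structures
≈ 0.68–0.72), and the shuffled null collapses below half the real value in
every observed shuffle. Known limitations: the insulation caller's
defaults were validated on blob geometry only; the exclusion fraction's
per-flank reading and the midpoint TAD-assignment rule are package choices
flagged above; `pairs_ratio` averages cells with equal weight regardless of
per-cell coverage.
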