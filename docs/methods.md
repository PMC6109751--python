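# Methods

## Statistics

**Gene diversity.** Nei's unbiased estimator
`(n/(n-1)) (1 - sum p_i^2)` on haplotype counts (*H*<sub>d</sub>) or, for
microsatellites, per-locus allele counts averaged over loci with at least
two scored gene copies (*H*<sub>E</sub>, n = scored copies, 2 per diploid
individual). The biased (GenAlEx-style) variant is available via
`unbiased=False`. Populations with fewer than two gene copies return NaN and
are carried as masked. A monomorphic population scores exactly 0.

**Nucleotide diversity.** π = [Σ<sub>i&lt;j</sub> d<sub>ij</sub> / C(n,2)] /
L<sub>eff</sub>, where d<sub>ij</sub> counts differing sites after pairwise
deletion (sites with a gap or N in either sequence are excluded from that
pair) and L<sub>eff</sub> is the mean per-pair compared length. Averaging
the compared lengths rather than dividing each pair by its own length keeps
the estimator stable when a few pairs share very few comparable sites.

**Pairwise Φ<sub>ST</sub>/F<sub>ST</sub>.** Two-population AMOVA on a
gene-copy distance matrix: with N = n_A + n_B copies,

    SSD_total  = sum_{i<j} d_ij / N
    SSD_within = (within-A pair sum)/n_A + (within-B pair sum)/n_B
    sigma_w    = SSD_within / (N - 2)
    sigma_a    = (SSD_among - sigma_w) / n',  n' = N - (n_A^2 + n_B^2)/N
    Phi_ST     = sigma_a / (sigma_a + sigma_w)

Difference counts serve directly as squared distances (the convention of
distance-based AMOVA on haplotype data). Three distance modes are exposed:
`molecular_distance` (pairwise differences; the default for sequences),
`haplotype_identity` (0/1), and `allele_identity_multilocus` for diploid
microsatellites, where each individual contributes its two allele copies
and the distance between two copies is the number of differing loci. A
locus is used for a pair only if both populations have a scored copy there;
within a copy pair, loci missing in either copy are skipped and the
identity sum is rescaled to the shared-locus count so distances stay
comparable across copy pairs of different completeness. Degenerate input
(zero total variance) returns 0. Estimates below 0 mean "no detectable
differentiation" and are clamped to 0 before normalization; the raw value
is written to the output CSV.

**Normalization.** Each statistic is divided by its maximum within the same
species × marker, making species with different marker variability
comparable before interpolation. An all-zero statistic normalizes to all
zeros with a logged warning. Multi-marker species are normalized per marker
and their marker landscapes averaged within the species before the
cross-species average — each species casts one vote regardless of how many
markers it carries. (The alternative — averaging after pooling all marker
landscapes equally — is a one-line change in `multi_species_average`; the
one-vote rule was chosen because study-rich species would otherwise
dominate the multi-species surface.)

## Landscapes

Grids are regular, addressed from the lower-left corner, row 0 northernmost
(ESRI convention); cells are addressed by center. Two coordinate regimes:
`planar` (synthetic unit-square studies; distances and areas in grid units)
and `lonlat` (degrees; great-circle distances in km via the haversine
formula, cell areas via 111.195 km/degree with the cos-latitude
correction). Default cell sizes are configuration, not method: analyses in
this repository use 1/60 degree-equivalents on the unit square, and results
are robust to the interpolation resolution because IDW is pointwise.

Divergence values are placed at pair midpoints (arithmetic for planar,
great-circle geodesic for lon/lat); within-population values at the
collection locations. Interpolation is k-nearest-neighbor IDW with weight
d^(−2) and k = 12 ("variable search radius with 12 points": the 12th
neighbor sets the radius, however far). Coincident sample points are
pre-averaged, which both defines the surface at zero distance and makes it
invariant to duplicating the point set; a cell center within 1e−9 of a
sample point takes the sample value exactly. k is reduced with a warning
when fewer points exist. IDW output is a convex combination of neighbor
values, so normalized inputs keep landscapes in [0, 1].

Clipping masks cells whose centers fall outside the boundary polygon;
invalid polygons get one `buffer(0)` repair pass. An empty intersection
yields an all-masked landscape and a warning rather than an error.

## Hotspots

Classification uses the population standard deviation (denominator N) over
unmasked cells — the classes describe the realized raster, not a sample
from it; at raster sizes the difference from the sample SD is negligible
and the choice is recorded in the run metadata. The middle class spans
mean ± 0.5 SD and every other class is exactly 1 SD wide. Cells strictly
above mean + 1.5 SD are hotspot cells; a zero-variance landscape
degenerates to a single middle class with no hotspots (warning). Hotspot
delineation is invariant under positive affine transforms of the landscape
(mean and SD transform covariantly) but not under general monotone
transforms.

Patches are maximal connected components (8-connectivity by default, 4
available), numbered in decreasing area order with ties broken by the
northernmost-then-westernmost member cell, so labeling is deterministic.
`merge_distance` optionally unifies patches whose minimum inter-cell-center
distance is below the threshold; it defaults to 0 (off) because merging
"nearby" patches is a narrative convenience without a canonical rule. The
unified report joins patches from the three statistic layers that share at
least one cell and flags which statistics exceed threshold in each group.

## Regional correlations

The regional value of a landscape is the mean of unmasked cell values whose
centers fall in the region polygon (matching the landscape-first flow of
the analysis); averaging the raw population points instead is available via
`mode="points"`. Region longitude/latitude is the polygon centroid.
Pearson r uses pairwise-complete observations with the two-sided t test on
n − 2 df; zero-variance variables yield a missing r rather than an error.
No multiple-testing correction is applied to the headline table — a
Holm-adjusted column is emitted alongside for transparency. OLS regressions
report slope, intercept, r (identical to the Pearson r of the pair) and p.
No spatial-autocorrelation correction is applied; with strongly
autocorrelated rasters the nominal p-values overstate independence, which
is a known limitation.

## Synthetic studies

The generator produces the statistical structure the analysis assumes, not
a demographic model. Per species: two haplotype pools of `n_haplotype_pool`
sequences (length `sequence_length`, default 300), one per side of a
barrier segment. The pools share a fraction (1 − s) of haplotypes; side
backbones differ at `round(s * backbone_divergence * L)` fixed sites
(default fraction 0.10), so cross-barrier gene copies are elevated in
molecular distance by an amount controlled by the divergence strength
s ∈ [0, 1] (default 0.8). Shared haplotypes derive from an intermediate
backbone carrying half of the divergent sites: "migrant" haplotypes are
then equidistant from both side pools and do not bias within-side molecular
diversity toward one side. Each haplotype carries independent per-site
mutations at rate 0.02 against its backbone.

A population at (x, y) draws haplotype frequencies from a symmetric
Dirichlet over its side's pool with per-haplotype concentration
θ(x, y) = θ₀ + Σ peak · exp(−d²/(2σ²)); individuals are sampled
multinomially. For a symmetric Dirichlet with concentration a over P
categories the expected gene diversity is a(P−1)/(Pa+1), which maps θ to a
target *H*<sub>d</sub>: the defaults θ₀ = 0.015 (background ≈ 0.25, most
populations nearly monomorphic, with enough polymorphism that the AMOVA
within-component stays positive) and bump peak 0.7 (≈ 0.9 at the center)
give a planted anomaly that is steep in *H*<sub>d</sub> without saturating.
A bump's `radius` is defined as 2σ of its kernel, so the anomaly has
decayed to ~1% at 1.5 radii; compact bumps matter because the mean + 1.5 SD
rule flags a fixed upper tail, and wide skirts inflate the landscape SD
until the threshold climbs to the bump tops. The default footprint
(r = 0.16 on the unit square) balances the probability that each species
samples populations inside the bump against that threshold inflation.
Microsatellite species use the same scheme with integer allele pools per
locus. Region tessellations couple the species-diversity indices to a
divergence signal with weight `sd_coupling` plus independent Gaussian
noise, then rescale affinely into plausible positive ranges per index; the
signal is the supplied per-region divergence vector when given (so full
coupling with zero noise is exactly affine in the measured regional AGD,
and the correlation is exactly ±1), otherwise the true barrier-proximity
field at region centroids.

What the generator does *not* emulate: coalescent genealogies, isolation by
distance within sides, mutation models beyond random substitution,
selection, uneven sampling effort, or spatially autocorrelated sampling
noise. Passing recovery tests therefore demonstrates that the pipeline
detects the kind of structure it targets at realistic sample sizes — not
that any particular empirical system has such structure.

With the default study (5 species × 20 populations × 8 individuals, two
bumps, one barrier, 60 × 60 grid) the pipeline recovers the barrier
corridor in the divergence layer essentially always, and each planted bump
in at least one within-population-diversity layer in ≈ 93–95% of
replicates; residual failures are placement luck — occasionally a bump
falls in a sampling gap of several species simultaneously, which no
parameterization of the planted structure can exclude at 20 uniform
populations per species.

## Numerical choices

- Nodata is −9999 in ESRI ASCII output and NaN in memory; grid values are
  written with 6 decimals, which bounds the round-trip error at 5e−7.
- IDW coincidence tolerance is 1e−9 in the distance unit.
- Patch tie-breaks, class edges and all orderings are deterministic;
  rerunning any stage with the same config and seed reproduces outputs byte
  for byte (no dict-order or floating-point-reduction nondeterminism on a
  fixed platform).
- All randomness flows from explicit seeds; the generator refuses to run
  without one.

## Problem sizes

The test suite and the acceptance script run the reference study (60 × 60
grid, 20 replicates for recovery rates), a 1000 × 1000 raster for the
classification-tail check, 150 random small instances per estimator for the
enumeration oracles, and 40 seeds × 5 indices for the null-correlation
check. These sizes give a per-check Monte-Carlo error well inside the
asserted tolerances while keeping a full run in a few minutes on one CPU.
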