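# Methods

`paleomob` estimates individual-level human mobility from spatially and
temporally referenced ancient-DNA samples.  This note describes the model
behind each stage, the parameters that matter, the numerical choices made,
and what the synthetic validation does and does not establish.

## From genotypes to ancestry components

Input genotypes are alternate-allele dosages (0/1/2, `9` = missing) over a
fixed SNP panel in EIGENSTRAT format.  Pairwise genetic distance between
samples i and j is one minus the mean proportion of alleles identical by
state over their mutually non-missing loci, with the per-locus share for
diploid dosages defined as `1 − |g_i − g_j| / 2` (opposite homozygotes
share nothing; a heterozygote shares half with either homozygote).  This
diploid convention is documented here as this package's choice; allele-level
tallies would differ only in how heterozygote pairs are weighted.  Pairs
with fewer than 1,000 overlapping loci (configurable) are treated as
errors, not imputed: the upstream SNP-count filter makes such pairs
pathological, and silent imputation would distort the embedding.

Quality control keeps a sample iff it has ≥ 25,000 autosomal SNPs on the
panel, a determinable molecular sex, and — for males — an X-chromosome
contamination estimate below 0.1 (female X-contamination estimates are not
informative, so the filter applies to males only).  Close relatives and
duplicates are removed by thresholding the IBS distance at 0.245: edges
below the threshold define a graph, and exactly one sample — the one with
the most autosomal SNPs, ties broken by smallest sample identifier — is
kept per connected component.

Classical (Torgerson) multidimensional scaling turns the filtered distance
matrix into k ancestry components (default k = 2): square the distances,
double-center (`B = −½ J D² J`), take the top-k positive eigenpairs, and
scale eigenvectors by the square root of their eigenvalue.  "Ancestry
component" here means an orthogonal MDS axis, not an admixture proportion.
Eigenvector sign is fixed by making each column's largest-magnitude entry
positive, so output is reproducible across platforms.

## The spatiotemporal ancestry field

Each ancestry component is modeled as a Gaussian process over three
independent coordinates — planar easting x and northing y in meters on an
equal-area projection, and time t in calendar years (calBC negative,
calAD positive, treated as one real line without a year-zero correction;
the one-year discrepancy is far below the temporal lengthscale).  The
covariance is the separable squared-exponential

    Cov(a, b) = τ² · exp(−[(Δx)²/θ_x + (Δy)²/θ_y + (Δt)²/θ_t]) + η · δ(a, b)

with δ the Kronecker delta on *exact* coordinate equality: the nugget η
sits on the diagonal and on exact duplicates, absorbing local ancestry
heterogeneity and measurement noise.  Near-duplicate coordinates are never
fuzzily collapsed.  θ_k is the divisor of squared separation (units of
distance squared); the "lengthscale" quoted in configuration files is
√θ_k, entered in km (space) or years (time).

Each component gets its own kernel and a constant mean equal to its
training mean, so predictions revert to the data mean far from all
observations and the predictive variance saturates at τ² + η.  Fitting is
exact (dense Cholesky); a jitter of 1e−8·τ² is added only if factorization
fails, with a logged warning.  Duplicated coordinates with conflicting
values and η = 0 raise an error advising a positive nugget.  Predictive
variance is floored at zero.

All distances in the kernel are computed on planar projected coordinates.
The default projection is the European equal-area grid (ETRS89 Lambert
azimuthal equal-area on GRS80, center 52°N 10°E, false origin
4,321,000 / 3,210,000 m), implemented from the standard ellipsoidal
formulas and validated against the published EPSG worked example.  Within
the core study window the planar distance agrees with the ellipsoidal
geodesic to better than 1% for separations up to 1,000 km; distortion
grows toward the projection periphery, which is the main reason peripheral
regions should be interpreted cautiously.

### Kernel selection

Three diagnostics are provided: an empirical variogram (semivariance
`γ = ½·mean squared value difference` over space-lag × time-lag bins with
pair counts), closed-form leave-one-out cross-validation, and maximum
marginal likelihood.  The MLE optimizes log(θ_x, θ_y, θ_t, η/τ²) with τ²
profiled out in closed form (τ̂² = yᵀC⁻¹y/n for the correlation matrix C
including the scaled nugget), using analytic gradients and L-BFGS-B from
multiple starts spread over the bounded log-box (default 8; seeded, hence
reproducible).  Multi-start matters: the profiled likelihood is multimodal,
with a nugget-dominated basin competing against the smooth-field basin.
For noise-only data the two explanations are confounded — vanishing
lengthscales mimic a pure nugget — so among optima whose likelihoods are
statistically indistinguishable (likelihood-ratio criterion at 5% over the
four free parameters) the fit returns the largest nugget ratio and warns:
the conservative reading that does not claim spatial structure the
likelihood cannot support.

The LOOCV score uses the standard closed-form identities
(`e_i = α_i / (K⁻¹)_ii`) on the full factorization.  The GP mean is held
fixed at the full-data component mean: the closed-form identity holds for a
fixed-mean GP, not for per-fold re-centering, and the brute-force refit it
is tested against uses the same fixed offset.

Shipped default kernel values (800 km / 800 y lengthscales, τ² = 1,
η = 0.1) are order-of-magnitude placeholders consistent with an
anisotropic kernel reaching over multiple hundred kilometers and years;
they are configuration, not canon, and should be re-estimated per dataset.

## Similarity probability surfaces

For one sample with component values z and one past time slice, every grid
cell is scored by the Gaussian likelihood of z_c under the field's
predictive distribution N(μ_c(cell), σ_c²(cell) + η_c) per component.  The
likelihood variance includes the nugget in addition to the predictive
variance, so locally heterogeneous ancestry retains support and the
surface cannot collapse onto training locations.  Bayes normalization uses
a uniform prior over grid cells — on an equal-area projection this equals
a uniform spatial prior, and normalize-then-multiply coincides with
multiply-then-renormalize.  The product over components and the
normalization run in log-space (log-sum-exp), and the log-space result
agrees with a linear-space evaluation to 1e−9 on well-conditioned inputs.

Because the predictive sd grows toward √(τ² + η) away from data, the
surface is only peaked where the field is supported by observations, even
if the interpolated mean happens to match the sample's values in a data
void.  The retrospection time is an input, never inferred; a surface is
computed for exactly one slice per call.

The maximum-probability cell is found by argmax with a deterministic
row-major tie-break (smallest y, then smallest x); any tie at the maximum
is flagged in the output so that uninformative (e.g. spatially constant)
surfaces are not over-interpreted.

## Mobility vectors and regional series

The mobility vector points from the burial location to the
maximum-probability cell, with length in km and compass bearing
(0° = North, clockwise; undefined and reported missing for zero length).
Age uncertainty propagates by Monte-Carlo resampling (default 25 runs):
draws come from the calibrated age probability table when present,
otherwise from a normal centered on the age median with sd equal to a
quarter of the 2-sigma range, truncated to the 2-sigma bounds.  For each
resampled age a the field is sliced at a − r, where r is the retrospection
distance (default 667 y, informed by the temporal kernel lengthscale).
The per-sample summary is the component-wise mean vector (opposing runs
can cancel — by design, since systematic direction matters more than
scatter) and the standard deviation of per-run lengths.

Regional curves are moving means of vector length over all resampled runs,
anchored at the resampled sample age (not the slice time), in centered
windows of 400 y sliding by 50 y (the step is this package's choice; the
window is standard).  Run-level pooling is the default; sample-level
pooling is available by flag.  The uncertainty band is two standard errors
of the per-sample mean lengths in the window, reported as infinite when a
window holds fewer than two samples.  Windrose-style direction histograms
use equal compass bins, half-open, starting at North, excluding zero-length
vectors.

## Synthetic validation

The simulator generates samples directly in ancestry-component space:
populations occupy rectangular planar regions, their component centroids
follow piecewise-linear trajectories in time, observations add independent
Gaussian noise per component, and discrete migration events place samples
in a destination region while their ancestry is drawn around the source
population's centroid.  A separate genotype-level generator (two
populations with shifted allele frequencies, binomial(2, p) dosages)
exercises the IBS-distance and MDS stages.

The pinned **two-pop-reference** scenario fixes the validation conditions:
two adjacent 500 km × 500 km regions, temporally stable centroids
separated by four observation-noise standard deviations (noise sd 0.05) in
component space, 100 non-migrants per population spread uniformly over
2,000 years, and 20 migrants at mid-span.  The evaluation fits the field
to non-migrants (spatial lengthscale 250 km — a moderate fraction of the
region width so the two regions stay resolved; temporal lengthscale
1,000 y since centroids are stable; τ² at the between-population spread;
η at the observation-noise variance), slices at each migrant's age minus
500 y on a 25 km grid, and asks whether the maximum-similarity point falls
inside the true donor region.  Under these conditions the expected
misassignment rate for a 4-sd centroid separation is roughly Φ(−2) ≈ 2%,
and the pipeline recovers ≥ 90% of migrant origins aggregated over 20
replicates; tied maxima are flagged and never counted as recovered.

What this does *not* show: component-space simulation bypasses genotype
sampling noise, missingness structure, uneven spatial sampling, admixture
gradients, and dating error correlated with context — all present in real
archaeogenetic data.  Passing the synthetic checks establishes that the
machinery is correct, not that real-data inferences are unbiased.  In
particular, interpolation averages over coexisting ancestries in close
proximity, and the similarity search inherits that limitation.

## Problem sizes and determinism

Validation uses deliberately desk-scale problems: GP oracle checks at
n ≤ 50, kernel recovery at n = 300 over 20 replicates, origin recovery at
220 samples per replicate on an 800-cell grid.  The dense GP is the
reference implementation throughout; a local-approximation speed path is
out of scope.  Every stochastic step takes an explicit seed
(`numpy.random.default_rng`), the pipeline derives per-sample seeds from
the global seed via `SeedSequence`, and two runs with identical
configuration and seed produce byte-identical result tables.

## Known limitations

* The interpolated field smooths over rapid local turnover; individuals
  culturally isolated from their geographic neighbors produce similarity
  surfaces pointing at distant look-alike populations.
* Mean mobility vectors can cancel; the tie flag and per-run outputs are
  provided so downstream analyses can detect uninformative surfaces.
* Regions at the data or projection periphery attract center-biased
  maximum-similarity assignments.
* The EIGENSTRAT reader is the only genotype entry point; other formats
  must be converted externally.
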