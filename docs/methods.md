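# Methods

## The estimation problem

Passive acoustic sensors record male koala bellows but cannot identify
individuals, so classical capture–recapture is unavailable. The spatial
count (SC) model — spatial capture–recapture for unmarked populations —
instead exploits the spatial correlation of counts across a detector
array: an individual whose home-range centre sits between two sensors
inflates both of their counts, and the joint pattern of counts across the
array is informative about how many activity centres there are and where
they sit.

## Model

The population is represented by data augmentation: M hypothetical
individuals, each with an inclusion flag `z_i ~ Bernoulli(psi)` and a
latent activity centre `s_i ~ Uniform(S)`, where the state-space S is the
minimum rectangle envelope of the detector locations expanded by a buffer
(750 m by default; a 5×5 grid at 400 m spacing then gives a 3100 m ×
3100 m rectangle, 961 ha). Nightly counts at detector j are

    n_jk ~ Poisson(Lambda_j),
    Lambda_j = lambda0 * sum_i z_i * exp(-d(s_i, x_j)^2 / (2 sigma^2)),

a half-normal encounter rate implied by bivariate-normal space use around
the activity centre. Abundance is `N = sum_i z_i` and density `D = N/|S|`
in males per hectare. The rate is constant across nights: survey occasions
(nights) enter only as replicate counts, so the likelihood depends on the
data only through per-detector totals and per-detector effective night
counts. Sensor failures are handled as masked detector-nights excluded
from both.

A count is the number of 10-minute periods in a night with at least one
validated bellow. The model treats these as unbounded Poisson counts;
at realistic rates (well below one call-period per detector-night) the cap
of 66 ten-minute periods per night is immaterial.

## Priors

- `lambda0 ~ Uniform(0, 100)` expected call-periods per detector-night at
  distance zero.
- `psi ~ Beta(1, 1)`.
- `sigma`, three variants:
  - *uninformative*: `Uniform(0, 2000)` metres. (A uniform(0, 100) prior
    on a ~150 m movement scale would be informative in the wrong place;
    the 2000 m ceiling is far above any plausible koala value.)
  - *strong*: Gamma, moment-matched so the mean equals the sigma implied
    by a 40 ha mean male home range and the coefficient of variation is
    0.2 (mean ≈ 145.8 m, sd ≈ 29.2 m).
  - *weak*: Gamma with mean at the midpoint of the sigmas implied by a
    (min, max) home-range interval and sd equal to half that sigma range,
    i.e. the stated interval spans ±1 sd — a deliberately wide CV derived
    from the range itself.

The home-range-to-sigma conversion treats a home range of area A as the
95% contour of a circular bivariate normal: `A = pi * q * sigma^2` with
`q = chi2(2 df) quantile at 0.95 ≈ 5.99`, so `sigma = sqrt(A_m2/(pi q))`.
The quantile is an argument (`hr_quantile`) for sensitivity analyses.

## Sampler

Metropolis-within-Gibbs, one iteration being:

1. `z` — single-site Gibbs sweep from the exact Bernoulli full
   conditionals (likelihood ratios computed incrementally per detector).
2. `psi` — exact conjugate draw `Beta(a + N, b + M − N)`.
3. `s` — per-individual bivariate random-walk Metropolis; proposals
   outside S are rejected (uniform prior on S); excluded individuals
   (`z_i = 0`) have no likelihood contribution and are redrawn uniformly
   on S, which keeps the augmented pool well mixed.
4. `lambda0`, `sigma` — random-walk Metropolis on the log scale (with the
   Jacobian term), so both remain positive by construction; a sigma move
   recomputes the full kernel matrix.

Proposal scales adapt in Robbins–Monro batches of 50 iterations toward an
acceptance rate of 0.3 (within the usual 0.2–0.45 band) during a declared
adaptive phase only, and are frozen afterwards so the sampling-phase
kernel satisfies detailed balance. The per-detector rate totals are
refreshed from scratch at the top of every iteration to stop incremental
floating-point drift.

Chains are seeded explicitly (one seed per chain, derived from a single
base seed via `SeedSequence` and kept below 2^31) and whole runs are
bit-reproducible. The numerical core is numba-compiled; the per-chain
random stream is numba's own, seeded once at chain start.

Study-scale settings are M = 500 and three chains of 50,000 iterations
with 10,000 burn-in after a 1,000-iteration adaptive phase, unthinned.
The desk-scale configuration used in the tests, the analysis drivers and
the acceptance script is M = 150 with three chains of 5,000 iterations
and 1,000 burn-in — chosen as the package's standard reduced experiment
size; full settings remain one configuration object away.

Monitored draws: N, D, lambda0, sigma, psi. Every 10th retained iteration
a full (z, s) snapshot is kept for surface mapping — a storage/accuracy
compromise; the mass-conservation identity below is exact for whatever
snapshot set is retained.

### Correctness checks

- The complete-data log-likelihood is tested against a brute-force
  product of Poisson pmfs on tiny problems (|difference| < 1e-10).
- The z and psi full conditionals are tested against their closed forms.
- A Geweke-style successive-conditional test alternates data simulation
  and parameter updates on a toy configuration and compares first and
  second moments of N and sigma against forward prior sampling.
- During development the posterior for one synthetic dataset was also
  cross-checked against an independent JAGS implementation of the same
  model (rjags); the two posteriors agree within Monte-Carlo error.

### Convergence

The Gelman–Rubin potential scale reduction factor is computed per
monitored parameter in its classic between/within-chain variance form
(`sqrt((n-1)/n + B/(nW))`, unsplit, no rank-normalisation — the form whose
degenerate cases have simple closed values, e.g. identical chains give
`sqrt((n-1)/n)`). Values below 1.1 are taken as converged; zero
within-chain variance is reported as undefined (NaN). Posterior summaries
report the mean with the central 50% credible interval (25th/75th
percentiles, linear interpolation), pooled across chains.

### Known behaviour at sparse-data conditions

At the package's standard synthetic conditions (density 0.05 males/ha,
sigma 150 m, lambda0 0.3, 5×5/400 m array, 14 nights) the expected rate is
only ~0.21 counts per detector-night (~75 counts in the whole survey).
With data that weak, the unmarked-count likelihood constrains N loosely
and the flat Beta(1, 1) prior on psi pulls the posterior for N toward
M/2. The result, reproduced identically by the independent JAGS fit, is
nominal-or-better interval coverage but a posterior *mean* for density
that can exceed the generating value by 30–60% depending on the
realisation. This is a property of the model under sparse data, not of
the sampler; posterior means should be read together with their (wide)
credible intervals at such data sizes, and real surveys with near-100%
naive occupancy carry substantially more information.

If M is set below the abundance the data support, the posterior for N
piles up at the ceiling; the sampler detects and warns about this.

## Density surfaces and category overlays

Retained (z, s) snapshots are binned on a pixel grid anchored at the
state-space's lower-left corner (default pixel 100 m — well below the
400 m detector spacing, and no finer than activity-centre density is
interpretable). A pixel's value is the snapshot-mean count of included
centres in the pixel divided by the pixel area in hectares, so

    sum(pixel value × pixel area in ha) = snapshot-mean N

holds exactly and is asserted in the tests (tolerance 1e-9).

Forest-category summaries assign pixels to polygons by the
pixel-centre-in-polygon rule (no area weighting — the simplest
reproducible rule at a resolution coarser than the pixel). Each polygon
gets the mean of its pixel values; each category gets the mean over its
polygons with a standard error from the among-polygon standard deviation
(`sd/sqrt(n_polygons)`; undefined for a single polygon). Polygons
containing no pixel centre are excluded with a warning. No smoothing is
applied beyond the posterior spread of the activity centres themselves.

## BACIPS analysis

For each control/treatment pair the density difference
(control − harvested) in one period is a replicate observation. The test
statistic is the paired t on the per-pair change in differences
(after − before), df = pairs − 1 — the form matching a reported df of 2
with three pairs — with a plain two-sample t on the before and after
difference series available as an option. Zero variance in the changes
makes t undefined and is reported as NaN. Swapping control and treatment
labels flips the signs of the mean difference and t and leaves p
unchanged.

Harvest intensity is volume removed per hectare of net harvest area;
report tables round half away from zero, the unrounded value is kept.
Naive occupancy is the percentage of working (non-failed) detectors with
at least one detection; failed detectors leave the denominator.

## Synthetic survey generator

Two fidelity levels, both with explicit seeds and no global state:

- **Model-exact**: counts drawn directly from the Poisson half-normal
  model. Used for parameter recovery, where the fitted model is exactly
  the generating model.
- **Protocol**: per night each individual emits
  `Poisson(nightly_call_rate)` bellow events placed uniformly among the
  10-minute bins; a detector at distance d records an event with
  probability `g0 * exp(-d^2/(2 sigma_det^2))`; the nightly count is the
  number of bins with ≥1 recorded event (hence capped at
  `periods_per_night`); detectors listed as failed are masked entirely.

Protocol defaults emulate the survey design: 14 nights (two-week
deployments), 66 ten-minute periods (~11 h sunset–sunrise recording),
detection scale 130 m (bellows carry ~100–300 m), g0 = 0.8, and 10
bellow events per male per night — a plausible breeding-season rate;
per-detector calling-rate distributions were never published, so the
protocol defaults are realistic rather than calibrated. Nightly rates are
constant across nights (no weather covariates): the SC model pools
occasions, and validated survey nights excluded rain and wind.

What the protocol generator does *not* emulate: false positives from the
call recogniser, bellow audibility varying with weather or topography,
double-counting of one event by several sensors being correlated beyond
distance (events are detected independently per detector), and
within-night movement of individuals. Passing recovery tests on
model-exact data therefore demonstrates correct inference under the
model's own assumptions; protocol-data fits probe robustness to the
binning/capping mechanism only.

## Degenerate inputs and tie-breaks

- Arrays need ≥2 detectors; state-space rectangles must have positive
  extent; counts must be non-negative integers.
- `log Poisson(0 | 0) = 0` (a zero count at a zero rate is certain); a
  positive count at a zero rate makes the state impossible (−inf).
- All-masked count matrices are rejected by the fitting entry point but
  allowed in the update primitives (flat-likelihood behaviour is itself
  tested).
- Percentages in report tables round half away from zero.
- Raster grids extend by up to one pixel beyond the state-space when the
  extent is not a pixel multiple; centres always lie inside S, so the
  conservation identity is unaffected.

## Limitations

- Only male density is estimated (bellowing is male behaviour); sex
  ratio assumptions live outside the package.
- No open-population dynamics, trap-specific effort covariates, or
  binomial/Bernoulli encounter variants.
- Rectangular state-spaces only; the published per-site areas
  (1100–1700 ha) imply irregular envelopes that were not released, so the
  package's 961 ha regular-grid default is the reproducible stand-in.
- The density surface is indicative at pixel scale; interpret it over
  contiguous blocks, not single pixels.
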