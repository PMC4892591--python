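# Methods

This note records the models, the numerical choices and the reasoning
behind the design decisions in `dendrosync`, in the package's own words.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Chronology building

**Detrending.** Raw ring widths carry a biological age/size trend that must
be removed before climate analysis. We fit, in order, the first admissible
model of: negative exponential `G_t = a·e^(−b·t) + k` with a>0, b>0, k≥0;
a straight line constrained to non-positive slope; a stiff smoothing
spline. Admissibility is defined operationally — the optimizer must
converge, the constrained parameters must sit away from their bounds (a
negative-exponential whose amplitude or decay rate has collapsed to ~0 is a
flat line in disguise and is rejected), and the fitted values must stay
above the 0.01 mm storage resolution. The ratio `x_t/G_t` is the ring-width
index; for a multiplicative growth process this division is an exact
inverse when the fitted curve equals the true trend, which is why the
synthetic generator is multiplicative too.

**Spline parameterization.** The fallback spline is a second-difference
penalized (Whittaker) smoother, `min Σ(x−G)² + λ·Σ(Δ²G)²`, whose frequency
response is `1/(1+λ(2 sin πν)⁴)`. We solve λ from the requirement that the
gain be 0.5 at the cutoff period p (λ = (2 sin π/p)⁻⁴) and set
p = 0.67 × the site's mean segment length. Users never set λ directly; the
cutoff period is the scientific quantity. Per-core model choices of any
particular historical data set are unknowable in general, so the chain
above is applied uniformly; the chosen model is recorded on every fit for
audit.

**Robust mean.** Core indices are averaged per year with the Tukey biweight
location (c = 9, MAD about the current estimate, convergence |Δm| < 1e-6,
≤ 50 iterations; one value → itself, two → their mean, zero MAD → the
median). The chronology keeps the per-year sample depth.

**Reliability.** r̄ is the mean pairwise Pearson correlation between core
index series over their overlap, requiring ≥ 30 shared years per pair
(shorter pairs are excluded and logged); it is computed once per site, not
in running windows, because a single reliable-span cut per site is wanted.
EPS and SSS follow the standard replication algebra; chronologies are
truncated at the earliest year from which SSS ≥ 0.85 holds continuously to
the end. Mean sensitivity `MS = mean|2(x_{t+1}−x_t)/(x_{t+1}+x_t)|` is
reported per chronology.

## Network synchrony

PCA is performed on the Pearson correlation matrix (eigendecomposition,
not SVD of anomalies) over the span all chronologies cover; variance shares
are 100·λ_i/p, and every component is oriented so its mean loading is
non-negative. The running analysis uses 50-year windows advanced by 10
years, standardizing within each window; the final window keeps the last
start but extends to the period end (an 1825–2005 span therefore ends with
a 51-year "1955–2005" window) so the most recent decades are never
dropped. Extreme rings are flagged against the full-period mean ± 1.5 SD of
each chronology — one fixed yardstick per site — and counted across the
network per year.

## Climate response

The dendroclimatic year runs from May of the year before ring formation
through September of the ring year (17 monthly predictors: row t takes
months 5–12 of t−1 and 1–9 of t). Correlation functions report Pearson r
per month with two-tailed critical values `t/√(df+t²)`, df = n−2, at 95%
and 99%. Moving correlations use a fixed window (default 30 years),
assigned to the center year — the lower-middle year for even windows — with
a 95% band `tanh(atanh r ± 1.96/√(w−3))`.

**Stability test.** The question "is the wandering of the moving
correlation more than stationary noise would produce?" is answered by
Monte Carlo: fit lag-1 autocorrelations a₁, a₂ to the two series, set the
innovation cross-correlation to `r·(1−a₁a₂)/√((1−a₁²)(1−a₂²))` so the
surrogate pair reproduces the observed full-period correlation, simulate M
(default 1000) bivariate AR(1) pairs of the same length, and compare the
variance of the observed moving-correlation track with the null
distribution; `p = (1+#{null ≥ obs})/(M+1)`. The variance statistic and M
are fixed choices; the test is seeded and batched (vectorized sliding
windows), so 500-replicate calibrations run in seconds. Its size was
verified at 5% nominal under a stationary null and its power ≥ 50% against
a mid-series correlation collapse (see the test suite).

## Fuzzy partitioning

Site index vectors over a fixed interval (16 years each for the cold
1965–1980 and warm 1990–2005 winters) are z-scored per site and clustered
with fuzzy C-means: memberships `u_ij = 1/Σ_l (d_ij/d_il)^(2/(m−1))`,
centroids `c_j = Σ u_ij^m x_i / Σ u_ij^m`, Euclidean distance, fuzzifier
m = 2, tolerance 1e-5, best of 10 seeded restarts by the final objective;
memberships are computed in log space so the near-crisp limit (m → 1⁺) is
numerically stable, where hard assignments provably coincide with the best
k-means 2-partition (checked against exhaustive enumeration for p ≤ 8).
Clusters are reported in descending fuzzy-cardinality order. Summaries:
fuzzy cardinalities (they always total the number of sites), Euclidean
distance between the two centroids of the z-scored data, a fuzzy pseudo-F
(membership-weighted Calinski–Harabasz ratio; +∞ flagged when the
within-cluster dispersion vanishes), and the number of interval years whose
values differ between the hard groups (Welch t, α = 0.05). The fuzzifier,
distance, normalization and the centroid-distance scale are package
definitions — surfaced as configuration — since no canonical convention
exists for them; pseudo-F values are therefore comparable within a run
(warm vs cold), not across software.

## Nonlinearity diagnostics

**EMD/EEMD.** Sifting uses cubic-spline envelopes through the local extrema
(plateaus contribute their midpoint), with the two outermost extrema
mirrored past each end to tame boundary swings; a component is accepted
when the normalized squared change between siftings falls below 0.2 or
after 10 siftings; decomposition stops when the residual has fewer than two
extrema. Reconstruction (Σ IMFs + residual = input) is exact by
construction. EEMD averages the decompositions of an ensemble (default 100)
of copies perturbed with white noise at 0.2 × the series SD, aligning IMFs
by index and zero-padding members that produced fewer; the averaged
residual is the nonlinear trend. On 100-year linear-trend-plus-noise truth
the trend slope is recovered within ±50% in ≥ 90% of replicates.

**Growth ANN.** `GrowthANN` wraps a 2-input → h sigmoid (default 4) →
linear-output network trained by adam on squared error with standardized
inputs and target, early stopping on a 20% validation split, and the best
of 5 seeded restarts by validation score. Training is deliberately patient
(≤ 5000 epochs, 100-epoch patience, tolerance 1e-7): with ~55 annual
samples an under-trained network smooths the very curvature the diagnostic
looks for. The exposed training record is the cumulative-best loss (the
quantity early stopping tracks), which is non-increasing by construction;
the raw per-epoch adam loss is not monotone and is available on the
underlying model.

**Threshold detection.** The response surface is evaluated on a regular
temperature grid (0.1 °C) and averaged over the November–December axis; a
two-segment continuous piecewise-linear least-squares fit over all interior
grid knots gives the breakpoint and the slope ratio below/above it. A
breakpoint is reported only when the broken line improves on a single line
by more than 1% relative SSE; otherwise the profile is declared
unidentifiable (a straight profile has no threshold). The end-to-end
protocol (`estimate_threshold`) evaluates the surface between the 5th and
95th percentiles of the training predictors: sigmoid outputs saturate in
the unsampled tails, and letting the breakpoint search roam there drags the
knot toward the data-free cold edge.

## Synthetic data: what it emulates, and what it does not

The generator is multiplicative: width = (negative-exponential age trend)
× index, with index
`1 + amp_t·√f_t·σ·C_t + amp_t·√g_t·σ·G_i·D_t + √(1−f₀−g₀)·σ·S_jt + ε`,
where C is the network-wide common signal, D a two-group contrast signal
(sites alternate between groups ±1), S site noise, ε core noise. f_t and
g_t are the exact variance fractions of the common and contrast components
in year t; the idiosyncratic variance is held constant through time
(`amp_t = √((1−f₀−g₀)/(1−f_t−g_t))`, anchored at the first year), so a
rising common fraction also raises the total interannual variance — a
deliberate choice: intensifying climate forcing makes rings more extreme,
not merely more synchronous, and the extreme-ring frequency mirror depends
on it. Extreme years are ±3 SD shocks injected into the common signal.
Cores end at the final year and start staggered through the early 60% of
the span (two cores anchored at the start so truncated chronologies can
stay reliable from the first year), reproducing depth profiles that grow
toward the present.

Default study conditions: 17 sites, 1825–2005, common fraction stepping
0.3 → 0.6 in 1955 (the late-20th-century synchronization), group contrast
0.05 → 0.25 in 1990 (site responses cluster under warm winters), baseline
index SD 0.15, core noise SD 0.10, January minimum temperature coupled to
the common signal at r = 0.6, and — for the threshold study — growth
responding to January temperature at 0.10 index/°C above −7 °C but only
0.02 below it, with 0.05 observation noise over 55 years. Replicate counts
in tests and the acceptance script (100 for recovery rates, 500/200 for
stability size/power) and the 4–5 cores per site are scaled-down study
sizes chosen to keep full runs in minutes; the paper-scale networks carry
19–67 cores per site.

Climate series are a fixed highland-continental seasonal cycle plus
piecewise-linear trend segments plus AR(1) anomalies (per-variable lag-1
coefficients); coupling mixes the standardized common signal into one
month's anomalies with weight equal to the target correlation, preserving
the marginal variance. Not emulated: spatial gradients between sites,
process-based growth (no soil-moisture or phenology mechanisms), daily
climate, age-dependent noise, and missing rings. Passing recovery tests
therefore demonstrates that the estimators recover the statistical
structure they target, not that real forests behave like the generator.

## Configuration

The pipeline reads a flat YAML file whose keys mirror `PipelineConfig`
(paths, analysis and response periods, running-window length/step, extreme
threshold k, response variable and season months, MCF window, FCM intervals
and settings, EEMD/ANN settings, SSS threshold, master seed); unknown keys
are rejected. Synthetic studies read a two-section YAML (`network`,
`climate`) mirroring `NetworkSimConfig`/`ClimateSimConfig`
(`load_sim_config`); the time-varying fractions are written either as
numbers or as step mappings `{before, after, year}`, coupling as
`[variable, month, correlation]`, and trend segments as
`{variable: [[[start, end], slope], ...]}`.

## Pipeline

Stages (chronology → synchrony → climate → fcm → nonlinear) exchange data
as plain delimited text in the output directory; a stage is skipped when
its outputs exist (force to regenerate), so deleting one stage's tables
regenerates exactly that stage. Per-stage seeds derive deterministically
from the master seed (SeedSequence spawn keys); deterministic stages
reproduce bit-identically. The analysis period is clipped to the span all
truncated chronologies cover — the network overlap — before PCA, mirroring
how a common period is chosen in practice. The nonlinear stage is optional:
its failure degrades to a manifest warning. The manifest (config hash,
stage seeds, package version, warnings) is written last.

## Known limitations

- Detrending offers no signal-free or RCS variants, and no autoregressive
  (residual) chronology; variance is not stabilized for changing depth.
- r̄ is a single per-site constant; sites whose cores share no signal
  (r̄ ≤ 0) have no defined SSS and cannot be truncated automatically.
- The running PCA standardizes per window; with very short windows the
  share estimates are noisy upward (eigenvalue bias at small n/p).
- The stability test's null matches lag-1 persistence only; long-memory
  series would need a richer surrogate model.
- The pseudo-F of the fuzzy partition collapses toward 0 for maximally
  fuzzy memberships (m = 2 on structureless data); it orders partitions
  within a data set but its absolute scale is convention-dependent.
- EEMD uses fixed ensemble/noise defaults (100, 0.2); no complete-ensemble
  (CEEMDAN) variant.
- The ANN is a diagnostic, not a forecast model: no uncertainty
  quantification, no architecture search.
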