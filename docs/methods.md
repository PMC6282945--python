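# Methods

This note documents the models behind `coralprev`, the parameters that
matter, the calibration and numerical choices, and what the simulations do
and do not say about real reef surveys.

## Populations

Colony centers are points in a rectangular frame (default 1,500 × 200 m),
origin at the lower-left corner, membership half-open
([0, w) × [0, h)) so abutting sampling units partition points exactly.
The default intensity, 0.63 colonies m⁻², is derived from the reference
field survey's arithmetic: 756 colonies over 24 belt-transects of 25 × 2 m
(1,200 m²).

Three generators cover the spatial classes:

* **Random** — homogeneous Poisson: count ~ Poisson(λA), positions i.i.d.
  uniform.
* **Clustered** — Thomas process: Poisson parents (default 0.0063 m⁻²),
  Poisson(100) offspring per parent, isotropic Gaussian dispersal with
  σ = 5 m. The product of parent intensity and mean offspring equals the
  target intensity; offspring falling outside the frame are discarded (no
  toroidal wrap), which costs a few percent of realized intensity at the
  default dispersal scale — downstream stages therefore always use the
  *realized* intensity and prevalence of the generated population, not the
  nominal targets.
* **Over-dispersed** — simple sequential inhibition: uniform proposals
  accepted only if at least 0.4 m from every accepted point, until
  round(λA) points are placed. At 0.63 m⁻² the packing fraction is far below
  the jamming limit for a 0.4 m hard core (≈4.3 m⁻²), so placement succeeds
  essentially always; a cap on consecutive rejections turns pathological
  configurations into an explicit infeasibility error naming the achieved
  count. Candidate checking uses a radius-sized cell grid, so the full
  189,000-point frame generates in roughly a second.

The clustered and inhibited parameter values are package choices: the study
conditions name the three classes but not their parameters, so defaults were
fixed once at values a reef ecologist would call realistic (5 m patch scale;
just-sub-meter spacing) whose envelope class is unambiguous, and verified by
the classification machinery below.

All generators take an integer seed and spawn an isolated NumPy generator;
identical seed and parameters give bit-identical patterns.

## Spatial verification

`ripley_k` implements the standard pair-count estimator
K̂(r) = A/(n(n−1)) Σ_{i≠j} w_ij 1[d_ij ≤ r] with either no edge correction or
the translation correction w_ij = A/((W−|dx|)(H−|dy|)) (the default; "none"
is adequate when r is much smaller than the frame). Besag's centered
L(r) − r = √(K̂/π) − r is zero in expectation under CSR, positive under
clustering, negative under over-dispersion. `csr_envelope` builds the
pointwise min/max (rank-1) band of centered L over CSR simulations
conditioned on the observed count — a two-sided pointwise level of about
2/(n_sim+1), i.e. ≈5% at the default 39 simulations.

`classify_pattern` labels a pattern *clustered* (*over-dispersed*) when the
observed curve exceeds (falls below) the band on a run of three consecutive
radii **starting in the first quarter of the radii grid**, and *random*
otherwise. The small-r restriction matters: genuine clustering and hard-core
inhibition produce departures that begin at the smallest radii, whereas
chance excursions of a CSR pattern are equally likely anywhere in the grid
and, because K̂ is cumulative, persist over several radii once they occur.
Without the restriction ~8–12% of CSR patterns are mislabeled; with it, and
with 99-simulation envelopes for classification work, measured recovery is
≥98% for random and 100% for the clustered and inhibited defaults (50 × 50 m
frames, radii 0.25–5 m in 0.25 m steps). Class-recovery checks run on scaled
frames because the summary costs grow with the pair count; the generators'
spatial signatures are scale-free at these radii.

## Disease marking

*Random transmission*: i.i.d. Bernoulli(prevalence) per colony, the model of
a well-mixed water-borne agent with homogeneous susceptibility.

*Contagious transmission*: a single-pass marking in which a colony's disease
probability decreases with its nearest-neighbor distance (to a neighbor of
any disease status — this is a static spatial-risk profile, not an iterative
epidemic). Nearest-neighbor distances are cut into six strata at their
empirical 0.5, 0.7, 0.8, 0.9 and 0.99 quantiles; strata carry decreasing
weights (0.99, 0.9, 0.8, 0.7, 0.5, 0.25; boundary ties join the closer
stratum); a single constant rescales the weights so the mean per-colony
probability equals the target prevalence exactly (to <1e−12) before
sampling. If the linear solution would push probabilities above 1 they are
capped and the constant re-solved by root finding, so any target below 1
remains attainable. Raw quantile levels cannot be used as probabilities
directly: values ≥0.5 would force prevalence ≥0.5, inconsistent with a 0.162
target, hence the weight-plus-calibration construction. The marking leaves
coordinates untouched and yields the expected contagion signature (diseased
colonies have systematically shorter nearest-neighbor distances).

## Surveys

A protocol is n_stations square stations (default side 100 m) with
transects_per_station axis-aligned belt-transects each. Stations are uniform
over admissible origins, optionally rejection-resampled until all pairwise
center separations reach a minimum (with an attempt cap that turns
impossible geometry into an error — e.g. four stations pairwise ≥500 m apart
cannot fit a 1,500 × 200 m frame, where the best achievable minimum
separation is ≈477 m; virtual protocols therefore default to no separation
constraint). Transects are independent and may overlap; a no-overlap option
is deliberately absent because overlap at five transects per hectare is rare
and independence keeps the placement distribution exactly uniform.

Counting is center-in with half-open edges. Per-transect counts are pooled;
where transects overlap, a colony contributes to each transect's bookkeeping
but the pooled prevalence is computed on distinct colonies. The density
estimate is pooled count / sampled area; the prevalence estimate carries a
95% Wilson score interval; a survey that counts zero colonies is retained
with an undefined (NaN) estimate rather than raising.

## Inference

* **Wilson interval** — closed form, with exact endpoints at boundary
  counts; cross-checked against statsmodels to machine precision.
* **Count comparisons** — negative-binomial GLM on group membership
  (dispersion by ML with a moment fallback near the Poisson boundary; Wald
  test), validated by the upper-tail chi-square probability of the residual
  deviance at its degrees of freedom. The residual (not null) deviance is
  used: pairing the null deviance with residual degrees of freedom is
  internally inconsistent and the standard overdispersion check uses the
  residual quantities.
* **Prevalence comparisons** — binomial GLM with quasi-likelihood dispersion
  φ = Pearson χ²/df inflating the standard errors and a t test on residual
  df (statsmodels' `scale="X2"` option mis-estimates φ for two-column
  binomial responses, so φ is computed explicitly; group-effect p-values
  match R's `glm(..., family=quasibinomial)` to seven significant digits).
  Validity uses a half-normal-plot envelope: 19 datasets are simulated from
  the fitted model, refit, and the fit is flagged when more than 20% of the
  observed sorted |standardized deviance residuals| (leverage-standardized)
  exceed the upper envelope. The one-sided 20% rule is calibrated, not
  nominal: each order statistic has a ~1/20 chance of being the maximum
  among 20 exchangeable curves, so demanding all points inside rejects about
  half of *correct* fits, while the calibrated rule accepts 92% of correct
  binomial fits and rejected 100% of beta-binomial (ρ = 0.1) overdispersed
  fits in simulation.
* **Scenario table** — for each pattern × transmission condition, repeated
  virtual surveys are compared against a field table with both GLMs and the
  percentage of significant results among valid comparisons is reported,
  with invalid trials counted separately. Two-sided α = 0.05 throughout.

## Accuracy and power experiments

Each accuracy experiment fixes one marked population (so "true prevalence"
is that population's realized value) and repeats the survey protocol with
fresh placements — the sampling variability measured is that of the survey
design, not of the population. The tolerance can be read two ways and both
are supported: `absolute` (±0.05 on the proportion scale, the API default)
and `relative` (±5% of the true prevalence, i.e. ±0.81 points at 0.162).
The replication configuration uses the relative reading: measured
probabilities across the 10×1 / 10×2 / 25×2 / 50×2 protocols are
(≈9.5, 14, 19, 31)% under the relative margin versus (≈55, 74, 90, 98)%
under the absolute one, and only the former is compatible with reported
accuracy probabilities in the low double digits for these designs. At ~31
pooled colonies (10 × 1 protocol) the hit probability is dominated by
discreteness — for many realized counts no integer numerator lands within
±0.81 points of the target — which is why it sits near 10% rather than the
~19% a normal approximation would suggest. Note that a 48% hit rate at ~315
pooled colonies would require an effective sample of ~855 colonies; under
binomial sampling no margin reading reaches it, and the package reports ≈31%
there.

The power experiment pairs random surveys and evaluates the achieved power
of the two-sided two-proportion z test (pooled null variance, unpooled
alternative variance, no continuity correction, harmonic-mean effective n
for unequal groups; both rejection tails are kept so zero effect gives
power = α exactly). Pooled colony counts are the sample sizes — the colony,
not the transect, is the sampling unit for a binomial condition. Cliff's
delta is computed on the two surveys' per-transect prevalence values (five
values each under the single-station protocols), the only within-survey
replication available to an ordinal statistic. The fitted power-vs-|δ| trend
uses isotonic regression clamped to (0, 1) — a deliberately simple monotone
smoother standing in for a spline fit, since monotonicity is the only
structure the trend is required to have.

## What the synthetic data do and do not capture

The generator reproduces the study conditions: frame, intensity, target
prevalence, spatial classes, transmission modes, and the per-transect count
and prevalence distributions they imply. It does not model colony size or
shape (points only), imperfect detectability, diver behavior, depth or
habitat gradients (intensity is homogeneous), temporal epidemic dynamics, or
non-random transect deployment. Passing tests therefore demonstrate the
statistical properties of the survey designs under idealized conditions;
real surveys face additional biases (convenience deployment, edge effects of
colony size) that can only worsen the reported accuracy and power. The
synthetic field-table fixture (negative-binomial totals with shape 5,
binomial diseased counts) emulates the reference survey's printed summaries
in expectation; its transect-level variance is a choice, as the real
per-transect table's variance is not published.

## Numerical and degenerate-input conventions

Seeds are integers (or NumPy SeedSequences) spawning isolated generators; no
global RNG state is touched. Zero-intensity frames, zero-prevalence
markings, empty transects and zero-colony surveys are all representable
without exceptions; undefined prevalence is a flagged NaN. Radii grids must
be strictly increasing; radii beyond min(frame side)/4 produce a
warning-carrying K estimate rather than an error. Stratum-boundary ties in
the contagion marking go to the closer stratum. CSV interchange uses plain
headers (`x,y[,diseased]`, `station,transect,n_total,n_diseased`) with
coordinates at six decimal places and `#` comment headers carrying frame
dimensions, config hashes and seeds.
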