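# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of the package.

## Count models and density standardization

Segment counts at a site are treated as i.i.d. draws from one of four
families: Poisson(λ); negative binomial in mean/dispersion form NB(μ, k)
with variance μ + μ²/k (k → ∞ recovers Poisson); and their zero-inflated
mixtures ZIP(π, λ) and ZINB(π, μ, k), where π is extra probability mass at
zero representing segments where turtles are structurally absent. Counts
are pooled across survey years per site for the headline densities
(per-site-year fits feed the trend series); sites surveyed in fewer than
three years are excluded from fitting.

**Estimation.** The Poisson MLE is the sample mean (closed form). The
other families are fit by direct numerical maximization of the
observed-data log-likelihood — at these sample sizes no EM machinery is
needed — over unconstrained coordinates (logit π, log μ, log k), which
enforces π ∈ (0, 1) and μ, k > 0 by construction. Nelder–Mead with an
objective tolerance of 1e-8 is run from three starts (moment-based,
zero-heavy, and a uniform mid-range start) to avoid boundary traps at
π → 0 or k → ∞; the best of the three is kept and the data are compressed
to (unique value, multiplicity) pairs so each likelihood evaluation is
O(#distinct counts). The fitted maxima agree with an independent optimizer
(statsmodels' zero-inflated count models) to ~1e-4 in log-likelihood in
the cross-check tests. Sites where every segment count is zero are
reported as degenerate fits (mean 0, P(0) = 1, converged) rather than
optimizer failures.

**Model ranking.** AIC = 2k_params − 2 ln L̂ with k_params = 1, 2, 2, 3 for
Poisson/NB/ZIP/ZINB. Families within 3 AIC units of the best are treated
as equivalent support; density reporting uses the NB whenever it is in
that equivalence set (on NB-like data the ZINB typically matches the NB's
likelihood and pays exactly the 2-unit penalty for its unused π). PMF
tables default to the 0–22 support observed in segment data but the bound
is configurable; density uses the analytic mixture mean, not a truncated
0–22 expectation, because truncation would bias heavy-tailed sites.

**Standardization.** Relative density is 1000·E[count] (turtles per 1000
tow segments, the standard effort); spatial density divides the
per-segment mean by the site's mean segment length in km; predicted
individuals per survey multiply by the site's mean segments per survey,
and regional abundance is the plain sum over sites. The three quantities
are algebraically consistent by construction and tested as such.

## Demographics

SCL = 0.8 × observed total length. Stage bins are half-open [lower,
upper): the adult rule "≥ upper cutoff" fixes the closure direction, which
is applied uniformly, so a boundary length belongs to the larger class.
Unidentified species (a percent-scale fraction of early records) are
reassigned per site from the site's multi-year identified green:hawksbill
proportions; the default is deterministic largest-remainder apportionment
(reproducible; ties toward green, the majority species overall), with a
seeded per-turtle stochastic mode as an alternative. A segment row with
count c and one recorded mean length contributes c turtles at that length;
rows with counts but no length are excluded from demographics only (they
still count for density). Stage summaries require ≥ 20 observed turtles
per site and species.

## Trends and growth

Annual densities per site (NB fit per site-year, ×1000) are pooled by
region. A LOESS — tricube weights over the span-fraction nearest
neighbors, local polynomial fit by weighted least squares — is fit over
all site-year points and evaluated at the surveyed years. Defaults span
0.75, degree 2, the conventional choices; both are configurable since
there is no principled value for sparse biennial series. The smoothed
series is read as stochastic exponential growth: r_x = ln ŷ_{t+1} − ln ŷ_t
between consecutive surveyed years, μ = mean(r_x), σ = sample (n−1) sd.
Survey cadence is biennial/triennial, so gaps are recorded with each r_x
and a per-annum normalization r_x / gap is reported alongside the raw
values; gaps are never interpolated. Nonpositive smoothed predictions
cannot be logged; the adjacent r_x values are dropped with a warning, not
imputed.

## Driver analysis

A random forest (500 trees, mtry = 2 candidate predictors per split,
minimum node size 5, bootstrap samples of size n) regresses green-turtle
site density on habitat area, SST, chl-a and human impact. The tree
ensemble itself is scikit-learn's RandomForestRegressor; the surrounding
analysis — permutation importance, the LOOCV harness, ICE/PDP — is
implemented here to match the definitions used throughout the package:

* **Permutation importance** is 100 × (MSE with one column permuted −
  baseline MSE) / baseline MSE, averaged over 10 seeded permutation
  repeats; the across-repeat sd (the estimate's noise band) is available.
  Importance evaluated on data the model memorized carries an optimistic
  tilt; the tests therefore evaluate null (inert-predictor) importances on
  freshly generated data, where they are centered on zero.
* **LOOCV** runs one iteration per site, each trained on n−1 sites with a
  deterministic per-iteration sub-seed. "Validation RMSE" of a single
  held-out site is its absolute prediction error; a pooled out-of-fold
  adjusted r² across all iterations is reported once, because r² is
  undefined for one point. Training adjusted r² uses the standard
  (n−1)/(n−p−1) correction; it is NaN for a zero-variance response, with a
  warning.
* **ICE/PDP** are definitional: the ICE curve pins one predictor at a grid
  value and predicts per site; the PDP is the pointwise mean of the ICE
  curves (asserted as an identity in tests). Two-variable PDPs pin two
  predictors jointly.

## Synthetic-data generator

The generator is the package's ground-truth instrument, not a fixture. Its
defaults encode the study conditions: 53 sites split 8/20/14/11 across
AMSM/HIIS/MARI/PRIA (the real split is not published; HIIS is the largest
region and PRIA among the smallest), April surveys on
biennial-to-triennial calendars over 2002–2015 with HIIS ending in 2010,
10 tows of ten 220 m segments per survey, NB(k = 0.5) counts (the
published data are described qualitatively as zero-inflated and
heavy-tailed; no overdispersion value is printed, and k = 0.5 reproduces
that shape), regional density scales 93/27/127/268 turtles per 1000
segments and growth rates 0.04/0.08/0.04/0.00 yr⁻¹ matching the reported
regional magnitudes, and a 90.1/8.3/1.6 % species mix. Site means scatter
around the regional scale lognormally (sd 0.8 in log space, giving the
observed within-region patchiness); year t's mean is mean₀ ·
exp(∫growth), with piecewise-constant growth legs supported so a
rise–dip–rise history can be encoded. Lengths are drawn uniformly within a
stage's SCL bin (adult bins close at 110 cm green / 90 cm hawksbill) and
divided by 0.8, so stage classification round-trips the generator label
exactly; one stage/length is shared per segment-species record, mirroring
the field protocol of one estimated average length per record — which
means turtle-level stage proportions are cluster-weighted, and the tests
use the matching cluster-aware standard error. Covariates are drawn
uniformly within plausible ranges (SST 24–31 °C, chl-a 0.05–0.6 mg m⁻³,
impact 0–6, habitat 1–500 km²) and the density response multiplies a
Gaussian SST kernel centered at 27.5 °C by linear chl-a/impact/habitat
effects plus additive noise.

What the generator does **not** emulate: spatial autocorrelation between
neighboring segments, observer detectability (sightings are counts, not
distance-sampling detections), within-year seasonal structure, and any
correlation among covariates. Passing tests therefore demonstrate that the
estimators recover known structure under the stated sampling model, not
that real surveys satisfy that model.

## Problem sizes and numerical choices

The test and acceptance runs use scaled simulation sizes chosen to make
Monte-Carlo error small relative to the asserted tolerances: 200
replicates at n = 2000 for mean-recovery bias (±5 %), 200 NB replicates at
n = 500 for AIC selection (≥ 80 %), 50 replicates of an 8-site 11-year
region for growth recovery (±0.02 around 0.08 yr⁻¹), 40 sites for the
driver suite, and 10⁵ segments for distributional checks. Likelihood-grid
oracles use lattices whose argmax is accurate to half a step, so fitted
parameters are required to land within 1.5 steps. All randomness flows
from explicit seeds; per-site generator substreams are keyed by (seed,
region index, site index) so datasets are reproducible byte-for-byte and
adding a site never perturbs existing ones.

## Known limitations

* Counts are fit per site without covariate-dependent (regression) count
  models, and no confidence intervals are attached to point densities.
* The per-site-year trend densities are simple NB fits; sparse site-years
  can smooth to nonpositive LOESS values in low-density regions, dropping
  r_x pairs (logged).
* Permutation importance reported per LOOCV iteration is computed on that
  iteration's training data, an out-of-bag-style approximation that can be
  optimistic for overfit predictors; the global null checks use fresh data.
* Deterministic reassignment of unidentified turtles apportions site
  totals, not segment-level identities; the stochastic mode exists where
  per-turtle labels matter.
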