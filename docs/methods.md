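# Methods

`vinedev` implements a stochastic model of primary shoot development in
grapevine (*Vitis vinifera*, Riesling-type), calibrated on two observation
streams from a FACE (free-air CO2 enrichment) sampling hierarchy: phenology
ratings on the modified E-L scale and manual 3D digitizations of shoots
(apex ranks and internode lengths). This note documents the model
components, the numerical choices, and what the synthetic-data experiments
do and do not demonstrate.

## Thermal time

Development is driven by a beta-distribution-like response to hourly air
temperature with cardinal parameters (t_base, t_opt, t_upper):

    hDD(T) = 2 u^a - u^(2a),   u = (T - t_base) / (t_opt - t_base),
    a = ln 2 / ln((t_upper - t_base) / (t_opt - t_base)),

zero outside [t_base, t_upper], exactly 1 at t_opt. The daily contribution
DD is the mean of the 24 hourly values; cumulative development days (CDD)
are the running sum of DD from 1 January. Conventions: hours belong to the
civil date of their timestamp; temperatures exactly at t_base or t_upper
take the formula value (0 by continuity); partial days at series boundaries
are rejected unless explicitly dropped-and-flagged; leap years use their
actual day-of-year numbering. CDD attaches to an observation as the
end-of-day value at the observation's day of year.

## Hierarchical calibration

All Bayesian models run on in-package samplers behind one
`run_mcmc(model_spec, config)` contract (default 4 chains, 2000 warm-up +
2000 kept draws each). No probabilistic-programming framework is used:

* **Hierarchical linear models** (phenology CDD ~ stage, apex rank ~ CDD)
  are fit by blocked conjugate Gibbs sampling. Coefficients (fixed and all
  group-level effects jointly) have a multivariate-normal full conditional;
  variances are inverse-gamma. The exGaussian likelihood (response =
  Normal(location, sigma) + Exponential(mean beta), the linear predictor on
  the location so slopes stay comparable to the Gaussian fit) is handled by
  a per-observation latent exponential component with a truncated-normal
  conditional, plus two partially collapsed moves that are essential for
  mixing: a Metropolis refresh of (sigma, beta) under the marginal
  exGaussian likelihood, and a ridge move trading beta against the
  intercept at constant predictive mean. With these, all parameters of the
  full-scale phenology fit reach Rhat < 1.01 and bulk-ESS ratios > 0.1.
* **The internode model** (below) is fit by adaptive Metropolis-within-
  Gibbs: an adaptive multivariate random walk for the fixed non-linear
  coefficients (proposal covariance adapted during warm-up, Haario-style),
  vectorized per-shoot / per-level random-walk updates for group-level
  blocks (conditionally independent given the shared parameters), and
  conjugate inverse-gamma draws for every variance.
* **Generic low-dimensional specifications** fall back to the emcee
  affine-invariant ensemble, walkers grouped into pseudo-chains for Rhat.

Priors are weakly informative defaults: zero-centred normals with scale
5 x SD(response) on linear fixed effects; moderately informative normals
centred on predecessor-model magnitudes for the non-linear growth
coefficients (e.g. i2 near 10 cm, lrc near -1); inverse-gamma on variances
rather than half-normal on SDs — the conjugate choice that keeps the Gibbs
sweep exact — with scales referred to the response SD divided by the RMS of
the corresponding design column, so slope-type group effects receive priors
on their own scale. Probability of direction (pd) is
100 x max(frac > 0, frac < 0); draws at zero count toward neither side.
Model ladders are compared by PSIS-LOO (arviz, importance ratios treated as
independent draws); discrete highest-density regions (budburst days) are
computed on the empirical pmf by greedy density ordering, optimal under
counting measure, with runs merged only across value-adjacent days so that
cold-spell gaps survive.

## Phenology

Modified E-L stages 1-18 are linearized (stage 4 = budburst fixed at 4; one
unit per separated leaf from stage 7; beginning of flowering extended at
21.5); unmapped stages are a domain error, not interpolated. The model
ladder CDD ~ trt x stage + year -> ... -> CDD ~ stage (Gaussian, then
exGaussian) shares the group structure (ring, year-within-ring and plant
intercepts, per-plant slope). Budburst prediction samples the posterior
predictive at linearized stage 4 without group-level effects and maps each
CDD draw to the first day reaching it.

## Internode appearance and growth

Apex rank is linear in CDD within the calibration window (ranks <= 23;
beyond is flagged as extrapolation). The final posterior condenses to
IAR ~ N(mu, sigma), sigma combining the fixed-slope posterior SD and the
between-shoot slope SD in quadrature; sampling truncates at zero.

Internode thermal age is (r_apex - rank + 1) / IAR. Expected length is
A(R) (1 - exp(-exp(lrc) (age + s_age))) with the rank-structured asymptote:
linear with indicator shifts at ranks 2 and 7 below rank 8, a period-3 step
pattern (phytomer types) above. The likelihood is Gamma with mean mu and
shape alpha (variance mu^2 / alpha), log-link applied as log mu =
log(mean length) so coefficients stay on the natural scale; log alpha
carries additive group-level heterogeneity by rank, ring, plant and shoot
(plus year outside the final variant). Group-level deviations act on lrc,
m1, i1, m2, i2 per shoot; the age correction s_age has a deviation per
shoot-and-date and exists only to absorb measurement-timing error — it is
fixed to 0 in simulation. Non-positive asymptotes or effective ages make
the log-density -infinite, so the sampler never visits them; the two
variants with treatment or year effects place per-level values on the five
coefficients listed and share s_r2, s_r7, s_age.

## Cardinal-temperature optimization

Candidate triplets on a 1 degree grid (spacing constraints t_base <=
t_opt - 2, t_opt <= t_upper - 2) are each evaluated by rebuilding the
calendars, re-attaching CDD and refitting both REML mixed models
(statsmodels MixedLM; a singular fit falls back to fixed-effects OLS).
Objectives: the treatment-averaged normalized gap between 1/IAR and the
leaf appearance rate; the absolute year coefficients of both models; and
NRMSE (= RMSE / mean of observations — the printed magnitudes of ~0.15
fix this reading) on train and held-out data, split 80/20 with plants
(phenology) or shoots (appearance) kept whole within year x treatment
strata. Seven thresholds cut to a feasible subset; the three main
objectives are min-max normalized; every weight vector on the 0.05 simplex
lattice votes for its argmin (ties credit all minima; the lattice has 231
exact-sum triples). The refinement lays a 0.1 degree grid +-0.9 around the
coarse winner, pools both feasible sets and re-votes. Predictions for the
NRMSE terms use fixed effects only, so train and test are comparable.

## Stochastic shoot simulation

Budburst CDD draws (default 4000) map to days; days with frequency >= 1%
are retained. Per retained day, 80 shoots each draw one joint posterior
parameter set plus fresh per-shoot deviations for the five non-linear
coefficients (asymptotes floored at 0.01 cm against pathological draws) and
one appearance rate. Internode r appears once the CDD since budburst
reaches r / IAR (evaluated daily, whole ranks via floor); its age within a
day is continuous, delta-CDD - (r-1)/IAR, keeping growth smooth across
days. Residual Gamma noise is not propagated — posterior and group-level
variability are the stochastic content. The horizon is 30 CDD after
budburst, the calibration window. Shoot length is the exact sum of
internode lengths (conservation is asserted, not rounded away).

## Synthetic data

The generator emulates the sampling hierarchy (2 years x 2 CO2 treatments
x 6 rings x plants x shoots) with one latent development trajectory per
shoot shared by all three observation streams. Weather is a double
sinusoid (annual + diurnal) with AR(1) noise at daily and hourly scales;
defaults put budburst near day 105-115 and give the second season a warmer
mean — contrasting seasons are what lets the year-effect objective
identify the cardinal temperatures. Ratings: each shoot has one exGaussian
development offset (shoots running ahead create the observed right skew)
plus small per-stage jitter, thresholds made monotone (a shoot passes
stages in order); a rater records the most recently attained stage at each
rating date, and only while the shoot is on the scale — once it runs more
than one stage-gap past stage 18 no rating is emitted. Digitizations:
apex ranks are the floor of the latent line plus observation-level noise
(the appearance model's residual), never decreasing within a shoot and only
once the shoot has emerged; internode lengths are Gamma noise around the
growth curve with per-shoot coefficient deviations.

Deliberate simplifications, hence limits of what green tests show about
real vineyards: no dormancy or chilling dynamics, no management events
(trimming, thinning), no spatial or operator measurement-error structure,
no decline of the appearance rate late in the season, and rating/digitizing
schedules are fixed by design rather than weather-adaptive.

Two named conditions exist beyond the defaults. `strong_signal` shrinks
group-level variability and observation noise for planted-truth recovery
experiments; `twin_years` reuses one weather-noise realization for both
seasons (with equal climates the years are identical and year effects are
exactly zero by construction, floor-discretization artefacts included;
with contrasting climates the seasons differ only by the deterministic
climate offset). End-censored emission and the emergence rule above are not
cosmetic: unbounded end-censoring biases the fitted stage slope upward by
5-15% and pre-emergence clamping biases the appearance slope downward, in
which case no fitter could recover the planted truth.

## Known limitation: the cardinal-temperature vote is not a point estimator

Planted-truth experiments show that the weighted-sum vote recovers t_opt
and t_upper to within about 1 degree but lets t_base wander by 2-3 degrees
between noise realizations, even on study-scale bundles with tightened
noise. The mechanism: two of the three voted objectives are absolute year
effects, whose minima are *noise-cancellation* regions — triplets that
warp the two seasons' thermal time so that sampled year effects vanish —
and such regions arise far from the generating triplet. The same signature
is visible in the method's own first-stage vote tables, where rival optima
tens of degrees apart hold substantial vote counts. The procedure should
therefore be read as a heuristic selector of an internally consistent
calibration, not as a consistent estimator of physiological thresholds;
uncertainty statements about the cardinal temperatures themselves are out
of its reach. (All vote/filter mechanics are nevertheless verified against
enumeration oracles, and the objectives evaluate to ~0 at the truth on
noise-free bundles.)

## Problem sizes and tolerances

Default analysis scale mirrors the study (~2600 ratings, ~500 apex rows
after the emergence rule, ~2600 internodes). Tests and the acceptance
experiments run scaled-down bundles (the `Design.small` factor and the
dedicated recovery design) and short chains; parameter-recovery assertions
use 2-3 posterior SDs. The two-stage recovery experiment uses a reduced
coarse grid (1 degree steps over t_base 9-13, t_opt 17-21, t_upper 23-27)
and a 0.45 degree refinement — the spacing constraints and vote mechanics
are identical to the full-scale search, only the enumerated neighbourhood
is smaller. Numerical guards: Gamma densities clip means at 1e-300 before
logs; min-max normalization of a degenerate range returns zeros with a
warning; `threshold_to_doy` uses binary search on the non-decreasing CDD
series and returns None for unattained thresholds.
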