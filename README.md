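# vinedev

Stochastic modelling of grapevine primary-shoot development: non-linear
thermal time, multi-objective calibration of cardinal temperatures,
Bayesian hierarchical models for budburst phenology, internode appearance
and internode length, and a simulator that propagates posterior
uncertainty into populations of virtual shoots.

The package is aimed at vine phenology and functional-structural plant
modellers who need (i) a thermal-time clock whose cardinal temperatures
are estimated jointly from phenology ratings and shoot digitizations, and
(ii) fitted, uncertainty-carrying building blocks for stochastic shoot
growth in a virtual vineyard.

## The models

**Thermal time.** Hourly air temperature T contributes a development-day
fraction through a beta-like response with cardinal temperatures
(T_base, T_opt, T_upper):

    hDD(T) = 2u^a − u^(2a),  u = (T − T_base)/(T_opt − T_base),
    a = ln2 / ln((T_upper − T_base)/(T_opt − T_base)),

zero outside [T_base, T_upper] and exactly 1 at T_opt. Daily development
DD is the 24-hour mean; CDD(doy) = Σ DD from 1 January.

**Phenology.** Linearized modified E-L stages (budburst = stage 4 fixed at
4; one unit per separated leaf from stage 7) enter a hierarchical model
CDD ~ stage with ring / year-within-ring / plant intercepts and per-plant
slopes; the final variant uses an exponentially modified Gaussian
likelihood whose right skew captures shoots running ahead of the average.
Posterior-predictive CDD thresholds for stage 4 map back through a year's
calendar to budburst-day distributions with (possibly gapped)
highest-density intervals.

**Internode appearance.** Apex rank ~ CDD with per-shoot intercepts and
slopes; the slope is the internode appearance rate IAR (ranks/CDD), and
1/IAR must agree with the phenology slope (CDD per leaf) — the consistency
constraint at the heart of the cardinal-temperature calibration.

**Cardinal temperatures.** A two-stage grid search (1 °C coarse, 0.1 °C
refined) minimizes the rate-consistency gap and both models' year effects
subject to NRMSE feasibility cuts, with a weighted-sum vote over the 0.05
simplex lattice of objective weights.

**Internode length.** IL(R, age) = A(R)·(1 − exp(−exp(lrc)·age)) with a
rank-structured asymptote (linear with dips at ranks 2 and 7; a period-3
step pattern above rank 7), Gamma likelihood with group-structured shape,
and per-shoot deviations on the five non-linear coefficients.

**Shoot simulation.** Budburst days (≥1% posterior frequency), one
appearance rate and one growth-parameter set per shoot generate internode
growth curves and shoot-length time series over a 30-CDD horizon.

A full account of assumptions, priors, samplers and limitations is in
[docs/methods.md](docs/methods.md).

## Worked example

The analysis pipeline runs on a synthetic vineyard with known ground truth
(there is no bundled observational data):

```bash
python analysis/01_make_synthetic.py --seed 1
python analysis/02_calibrate_cardinals.py --seed 1
python analysis/03_fit_phenology.py --seed 1 --chains 2 --warmup 800 --kept 800
python analysis/04_fit_appearance.py --seed 1 --chains 2 --warmup 800 --kept 800
python analysis/05_fit_internodes.py --seed 1 --skip-ladder --chains 2 \
    --warmup 1000 --kept 800
python analysis/06_simulate_shoots.py --seed 1 --year 2018
```

Step 01 writes 2360 phenology ratings, 241 apex digitizations and 3113
internode lengths generated from the truth triplet (10.8, 19.0, 24.7) °C,
a stage slope of 1.2577 CDD per linearized stage and an appearance rate of
0.7784 ranks/CDD. Step 02 sweeps 618 candidate triplets in two stages and,
on this noisy default bundle, selects (11.0, 16.7, 26.7) °C — t_base on
target, the other two coordinates illustrating the selector's spread
discussed in [docs/methods.md](docs/methods.md) (the vote favours wherever
the two seasons' year effects cancel). Step 03 prints the model-reduction
ladder — on this run
the exGaussian refit has the lowest LOOIC (12 009.6 vs 12 122.6 for the
Gaussian final model) and a slope of 1.2564 with pd = 100% — and maps
budburst to median day-of-year 124 in the cool season and 112 in the warm
one, each with a 95% HDI a few weeks wide. Step 04 reports the appearance
rate distribution IAR ~ N(0.7762, 0.0779) ranks/CDD, reciprocal
1.288 CDD per rank. Step 05's final growth fit recovers the planted
coefficients (e.g. lrc −0.849 ± 0.060, i2 9.885 ± 0.142) and shows
group-level effects improving training RMSE (2.81 vs 2.91 cm without).
Step 06 retains 27 budburst days at ≥1% posterior frequency and simulates
80 shoots for each. Each script states what it found on stdout and writes
its tables under `results/`.

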