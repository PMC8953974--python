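"""Synthetic vineyard data with known ground truth.

Emulates the free-air CO2-enrichment (FACE) sampling hierarchy — two years,
two CO2 treatments in six rings (three per treatment), plants within rings,
shoots within plants — together with the three observation streams the
pipeline consumes:

* hourly air temperature (sinusoidal annual + diurnal cycle with
  autoregressive synoptic and hourly noise),
* phenology ratings: each shoot carries a latent CDD-at-stage line with
  exGaussian (right-skewed) thresholds; a rater records the most recently
  attained modified E-L stage at each rating date,
* shoot digitizations: a per-shoot appearance rate drawn from the IAR
  distribution gives apex ranks (floor of the latent line), and internode
  lengths are Gamma noise around the rank-structured growth curve with
  per-shoot coefficient deviations.

All three streams share one latent development trajectory per shoot, so
parameter-recovery tests can hold the generator truth against every fitted
model.  Climate defaults place budburst (~7.8 CDD under the default
cardinal triplet) near day-of-year 105–115, a realistic cool-climate
spring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from vinedev.internode_growth import GrowthParameters, _asymptote_arrays
from vinedev.phenology import STAGE_LINEARIZATION
from vinedev.thermal_time import CardinalTemperatures, DevelopmentCalendar, build_calendar

__all__ = [
    "ClimateParams",
    "Design",
    "GroundTruth",
    "SyntheticBundle",
    "generate_weather",
    "generate_phenology",
    "generate_digitization",
    "make_bundle",
]


@dataclass(frozen=True)
class ClimateParams:
    """Annual/diurnal temperature cycle with AR(1) noise at two scales."""

    mean_c: float = 12.5
    annual_amp: float = 9.5
    warmest_doy: float = 200.0
    diurnal_amp: float = 4.0
    daily_noise_sd: float = 2.0
    daily_noise_ar: float = 0.7
    hourly_noise_sd: float = 1.0
    hourly_noise_ar: float = 0.9


@dataclass(frozen=True)
class Design:
    """Counts and dates of the sampling hierarchy.

    Defaults mirror the study scale: ~2400 phenology rows (six rings, eight
    rated plants of four shoots each, nine rating dates per season), ~240
    apex rows (one digitized plant per ring, seven shoots, three dates per
    year) and ~3000 internode rows.
    """

    years: tuple = (2018, 2019)
    treatments: tuple = ("aCO2", "eCO2")
    n_rings: int = 6  # alternating treatment assignment, three rings each
    plants_per_ring: int = 8
    shoots_per_plant: int = 4
    rating_doys: dict = field(default_factory=lambda: {
        2018: tuple(range(100, 153, 6)), 2019: tuple(range(99, 152, 6))})
    digitized_plants_per_ring: int = 1
    digitized_shoots_per_plant: int = 7
    digitization_doys: dict = field(default_factory=lambda: {
        2018: (125, 140, 155), 2019: (125, 140, 155)})

    def small(self, factor: float = 0.5) -> "Design":
        """Scaled-down design for fast tests (structure preserved)."""
        return replace(
            self,
            plants_per_ring=max(2, int(self.plants_per_ring * factor)),
            shoots_per_plant=max(2, int(self.shoots_per_plant * factor)),
            digitized_shoots_per_plant=max(2, int(self.digitized_shoots_per_plant * factor)),
        )

    def ring_treatment(self, ring: int) -> str:
        return self.treatments[ring % len(self.treatments)]


@dataclass
class GroundTruth:
    """Generator truth for every pipeline stage.

    Rates are linked (1/apex_slope ~ phen_slope) as the organ-development
    synchrony assumption demands; treatment and year effects default to
    zero, the study's null finding.
    """

    cardinal: CardinalTemperatures = field(
        default_factory=lambda: CardinalTemperatures(10.8, 19.0, 24.7))
    # phenology: CDD = intercept + slope * linearized stage
    phen_intercept: float = 2.78
    phen_slope: float = 1.2577
    phen_trt_effect: float = 0.0
    phen_year_effect: float = 0.0
    exgauss_sigma: float = 2.0
    exgauss_beta: float = 2.0
    phen_noise: str = "exgaussian"  # or "gaussian"
    stage_jitter_sd: float = 0.8
    sd_ring: float = 0.4
    sd_year_ring: float = 0.4
    sd_plant: float = 0.7
    sd_plant_slope: float = 0.04
    # apex rank = intercept + iar * CDD
    apex_intercept: float = -6.9
    apex_slope: float = 0.7784
    apex_trt_effect: float = 0.0
    apex_year_effect: float = 0.0
    apex_sd_ring: float = 0.25
    apex_sd_plant: float = 0.4
    apex_sd_shoot: float = 0.6
    apex_sd_shoot_slope: float = 0.08
    apex_resid_sd: float = 0.3  # observation-level noise on the latent rank
    # internode growth
    growth: GrowthParameters = field(default_factory=lambda: GrowthParameters(
        lrc=-0.812, m1=1.655, i1=1.2795, m2=0.6104, i2=9.6989,
        s_r2=-0.482, s_r7=-0.17, s_age=-0.2))
    growth_shoot_sds: tuple = (0.15, 0.15, 0.12, 0.1, 0.8)  # lrc, m1, i1, m2, i2
    sd_sage_slope: float = 0.08
    gamma_log_shape: float = 2.1
    shape_sds: dict = field(default_factory=lambda: {
        "rank": 0.25, "ring": 0.15, "plant": 0.15, "shoot": 0.25})
    design: Design = field(default_factory=Design)
    # a cool first and a warm second season: contrasting years are what
    # identifies the cardinal temperatures through the year-effect objective
    climate_by_year: dict = field(default_factory=lambda: {
        2018: ClimateParams(mean_c=12.0), 2019: ClimateParams(mean_c=13.4)})
    climate: ClimateParams = field(default_factory=ClimateParams)

    def climate_for(self, year: int) -> ClimateParams:
        return self.climate_by_year.get(year, self.climate)

    def __post_init__(self):
        if abs(1.0 / self.apex_slope - self.phen_slope) / self.phen_slope > 0.10:
            raise ValueError("linked rates violated: 1/apex_slope must stay within "
                             "10% of phen_slope")

    @classmethod
    def strong_signal(cls, design: Design | None = None, **overrides) -> "GroundTruth":
        """Truth with shrunken noise/group variability for planted-truth
        recovery of the cardinal triplet, where the objectives at the truth
        must stand out from sampling noise."""
        base = dict(
            exgauss_sigma=0.15, exgauss_beta=0.05, stage_jitter_sd=0.1,
            sd_ring=0.05, sd_year_ring=0.01, sd_plant=0.1, sd_plant_slope=0.005,
            apex_sd_ring=0.03, apex_sd_plant=0.05, apex_sd_shoot=0.1,
            apex_sd_shoot_slope=0.005,
            # continental-spring diurnal range: afternoon peaks above the
            # upper cardinal temperature identify t_upper
            climate_by_year={2018: ClimateParams(mean_c=12.0, diurnal_amp=6.5),
                             2019: ClimateParams(mean_c=13.4, diurnal_amp=6.5)},
        )
        base.update(overrides)
        if design is not None:
            base["design"] = design
        return cls(**base)


def posterior_recovery_truth() -> GroundTruth:
    """Study-scale truth with moderate noise for posterior-recovery
    experiments: paper-sized tables, eight rating dates and four
    digitization dates per season."""
    design = Design(
        plants_per_ring=8, shoots_per_plant=4,
        rating_doys={2018: tuple(range(102, 150, 6)),
                     2019: tuple(range(100, 148, 6))},
        digitized_shoots_per_plant=7,
        digitization_doys={2018: (122, 134, 146, 158),
                           2019: (118, 130, 142, 154)},
    )
    return GroundTruth(design=design, exgauss_sigma=1.2, exgauss_beta=1.0,
                       stage_jitter_sd=0.4, sd_ring=0.2, sd_year_ring=0.2,
                       sd_plant=0.4, sd_plant_slope=0.03)


def recovery_design() -> Design:
    """Sampling layout for planted-truth cardinal recovery: dense rating
    dates, many digitized shoots, six digitization dates per season."""
    # the warm season is observed ~12 days earlier, as a field campaign
    # would: aligning each year's window with its phenology keeps the
    # on-scale censoring comparable between years; digitization extends into
    # early summer so afternoon peaks exercise the upper temperature branch
    return Design(
        plants_per_ring=3, shoots_per_plant=2,
        rating_doys={2018: tuple(range(100, 152, 2)), 2019: tuple(range(88, 140, 2))},
        digitized_shoots_per_plant=16,
        digitization_doys={2018: tuple(range(118, 179, 10)),
                           2019: tuple(range(106, 167, 10))},
    )


def generate_weather(year: int, climate: ClimateParams | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """One year of hourly temperatures (columns ``timestamp``, ``t_air_c``)."""
    climate = climate or ClimateParams()
    rng = np.random.default_rng(seed)
    ndays = pd.Timestamp(year, 12, 31).dayofyear
    doy = np.arange(1, ndays + 1)
    daily = climate.mean_c + climate.annual_amp * np.cos(
        2 * np.pi * (doy - climate.warmest_doy) / 365.25)
    syn = np.empty(ndays)
    syn[0] = rng.normal(0, climate.daily_noise_sd)
    innov_sd = climate.daily_noise_sd * np.sqrt(1 - climate.daily_noise_ar ** 2)
    for i in range(1, ndays):
        syn[i] = climate.daily_noise_ar * syn[i - 1] + rng.normal(0, innov_sd)
    hours = np.arange(24)
    diurnal = climate.diurnal_amp * np.sin(2 * np.pi * (hours - 9) / 24)
    temps = (daily + syn)[:, None] + diurnal[None, :]
    nh = ndays * 24
    noise = np.empty(nh)
    noise[0] = 0.0
    e = rng.normal(0, climate.hourly_noise_sd * np.sqrt(1 - climate.hourly_noise_ar ** 2), nh)
    for i in range(1, nh):
        noise[i] = climate.hourly_noise_ar * noise[i - 1] + e[i]
    ts = pd.date_range(f"{year}-01-01", periods=nh, freq="h")
    return pd.DataFrame({"timestamp": ts, "t_air_c": temps.ravel() + noise})


def _stage_table():
    stages = np.array(sorted(STAGE_LINEARIZATION))
    linear = np.array([STAGE_LINEARIZATION[s] for s in stages])
    return stages, linear


def generate_phenology(truth: GroundTruth, calendars: dict[int, DevelopmentCalendar],
                       seed: int = 0) -> pd.DataFrame:
    """Rating table: the most recently attained E-L stage per shoot and date."""
    d = truth.design
    rng = np.random.default_rng(seed)
    stages, linear = _stage_table()

    b_ring = rng.normal(0, truth.sd_ring, d.n_rings)
    b_plant = rng.normal(0, truth.sd_plant, (d.n_rings, d.plants_per_ring))
    b_plant_slope = rng.normal(0, truth.sd_plant_slope, (d.n_rings, d.plants_per_ring))
    rows = []
    for yi, year in enumerate(d.years):
        cal = calendars[year]
        b_yr = rng.normal(0, truth.sd_year_ring, d.n_rings)
        for ring in range(d.n_rings):
            trt = d.ring_treatment(ring)
            trt_i = float(trt != d.treatments[0])
            for plant in range(d.plants_per_ring):
                for shoot in range(d.shoots_per_plant):
                    loc = (truth.phen_intercept + b_ring[ring] + b_yr[ring]
                           + b_plant[ring, plant]
                           + truth.phen_trt_effect * trt_i
                           + truth.phen_year_effect * yi
                           + (truth.phen_slope + b_plant_slope[ring, plant]) * linear)
                    # one development offset per shoot (a shoot passes stages in
                    # order, so its thresholds move together; the exponential
                    # part makes some shoots run ahead, the observed right skew)
                    # plus small per-stage jitter; monotonicity enforced
                    shoot_off = rng.normal(0, truth.exgauss_sigma)
                    if truth.phen_noise == "exgaussian":
                        shoot_off += rng.exponential(truth.exgauss_beta)
                    jitter = rng.normal(0, truth.stage_jitter_sd, len(linear))
                    thresholds = np.maximum.accumulate(loc + shoot_off + jitter)
                    # a shoot is followed only while it is on the rating scale:
                    # before its first stage is reached, and once it has run one
                    # stage-gap past the top of the scale, no rating is recorded
                    top_gap = thresholds[-1] - thresholds[-2]
                    for doy in d.rating_doys[year]:
                        cdd = cal.cdd_at(doy)
                        reached = thresholds <= cdd
                        if not reached.any():
                            continue
                        if reached.all() and cdd > thresholds[-1] + top_gap:
                            continue
                        stage = int(stages[reached][-1])
                        rows.append((year, trt, f"r{ring + 1}", f"p{plant + 1}",
                                     f"s{shoot + 1}", doy, stage))
    return pd.DataFrame(rows, columns=["year", "trt", "ring", "plant", "shoot",
                                       "doy", "el_stage"])


def generate_digitization(truth: GroundTruth, calendars: dict[int, DevelopmentCalendar],
                          seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apex-rank and internode-length tables for the digitized shoots."""
    d = truth.design
    rng = np.random.default_rng(seed)
    g = truth.growth
    sds = np.asarray(truth.growth_shoot_sds)

    e_rank = rng.normal(0, truth.shape_sds["rank"], 40)
    e_ring = rng.normal(0, truth.shape_sds["ring"], d.n_rings)
    b_ring = rng.normal(0, truth.apex_sd_ring, d.n_rings)
    apex_rows, inter_rows = [], []
    for yi, year in enumerate(d.years):
        cal = calendars[year]
        for ring in range(d.n_rings):
            trt = d.ring_treatment(ring)
            trt_i = float(trt != d.treatments[0])
            for plant in range(d.digitized_plants_per_ring):
                b_plant = rng.normal(0, truth.apex_sd_plant)
                e_plant = rng.normal(0, truth.shape_sds["plant"])
                for shoot in range(d.digitized_shoots_per_plant):
                    b_shoot = rng.normal(0, truth.apex_sd_shoot)
                    iar_s = max(truth.apex_slope + truth.apex_trt_effect * trt_i
                                + rng.normal(0, truth.apex_sd_shoot_slope), 0.05)
                    dev = rng.normal(0, sds)
                    params_s = g.with_deviations(dev) if g.i1 + dev[2] > 0 and g.i2 + dev[4] > 0 \
                        else g
                    e_shoot = rng.normal(0, truth.shape_sds["shoot"])
                    prev_rank = 0
                    for doy in d.digitization_doys[year]:
                        cdd = cal.cdd_at(doy)
                        latent = (truth.apex_intercept + b_ring[ring] + b_plant + b_shoot
                                  + truth.apex_year_effect * yi + iar_s * cdd
                                  + rng.normal(0, truth.apex_resid_sd))
                        if latent < 1.0:  # shoot not yet emerged: nothing to digitize
                            continue
                        # ranks never retreat between successive digitizations
                        r_apex = max(int(np.floor(latent)), prev_rank, 1)
                        prev_rank = r_apex
                        apex_rows.append((year, trt, f"r{ring + 1}", f"p{plant + 1}",
                                          f"s{shoot + 1}", doy, r_apex))
                        v_sd = rng.normal(0, truth.sd_sage_slope)
                        ranks = np.arange(1, r_apex + 1)
                        ages = (r_apex - ranks + 1) / truth.apex_slope
                        A = _asymptote_arrays(ranks, params_s.m1, params_s.i1,
                                              params_s.m2, params_s.i2, g.s_r2, g.s_r7)
                        eff = np.maximum(ages + g.s_age + v_sd, 0.05)
                        mu = np.maximum(A, 0.05) * (1 - np.exp(-np.exp(params_s.lrc) * eff))
                        log_shape = (truth.gamma_log_shape + e_rank[ranks - 1]
                                     + e_ring[ring] + e_plant + e_shoot)
                        alpha = np.exp(log_shape)
                        lengths = rng.gamma(alpha, mu / alpha)
                        for r, ln in zip(ranks, lengths):
                            inter_rows.append((year, trt, f"r{ring + 1}", f"p{plant + 1}",
                                               f"s{shoot + 1}", doy, int(r),
                                               float(max(ln, 1e-3)), r_apex))
    apex = pd.DataFrame(apex_rows, columns=["year", "trt", "ring", "plant", "shoot",
                                            "doy", "r_apex"])
    inter = pd.DataFrame(inter_rows, columns=["year", "trt", "ring", "plant", "shoot",
                                              "doy", "rank", "length_cm", "r_apex"])
    return apex, inter


@dataclass
class SyntheticBundle:
    """Jointly consistent weather + ratings + digitization with their truth."""

    truth: GroundTruth
    weather: dict[int, pd.DataFrame]
    calendars: dict[int, DevelopmentCalendar]
    ratings: pd.DataFrame
    apex: pd.DataFrame
    internodes: pd.DataFrame

    def write(self, out_dir):
        """Dump the four CSVs plus a truth sidecar (JSON)."""
        import json
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for year, w in self.weather.items():
            w.to_csv(out / f"weather_{year}.csv", index=False)
        self.ratings.to_csv(out / "ratings.csv", index=False)
        self.apex.to_csv(out / "apex.csv", index=False)
        self.internodes.to_csv(out / "internodes.csv", index=False)
        t = self.truth
        sidecar = {
            "cardinal": t.cardinal.as_tuple(),
            "phen_intercept": t.phen_intercept, "phen_slope": t.phen_slope,
            "apex_intercept": t.apex_intercept, "apex_slope": t.apex_slope,
            "growth": {k: getattr(t.growth, k) for k in
                       ("lrc", "m1", "i1", "m2", "i2", "s_r2", "s_r7", "s_age")},
        }
        (out / "truth.json").write_text(json.dumps(sidecar, indent=2))


def make_bundle(truth: GroundTruth | None = None, seed: int = 0,
                twin_years: bool = False) -> SyntheticBundle:
    """Generate weather, calendars, ratings and digitizations from one truth.

    The same seed reproduces the bundle bit-exactly; a new seed changes the
    noise, never the design structure.  ``twin_years`` reuses one noise
    realization for both seasons: with equal per-year climates the years are
    identical (year effects exactly zero by construction, discretization
    artefacts included); with different per-year climates the seasons differ
    only by the deterministic climate contrast ("offset years").
    """
    truth = truth or GroundTruth()
    rng = np.random.default_rng(seed)
    weather = {}
    calendars = {}
    weather_seed = int(rng.integers(2**31))
    for year in truth.design.years:
        if not twin_years:
            weather_seed = int(rng.integers(2**31))
        w = generate_weather(year, truth.climate_for(year), seed=weather_seed)
        weather[year] = w
        calendars[year] = build_calendar(w, truth.cardinal)
    ratings = generate_phenology(truth, calendars, seed=int(rng.integers(2**31)))
    apex, internodes = generate_digitization(truth, calendars, seed=int(rng.integers(2**31)))
    return SyntheticBundle(truth=truth, weather=weather, calendars=calendars,
                           ratings=ratings, apex=apex, internodes=internodes)
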