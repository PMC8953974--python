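"""Stochastic shoot simulation: posterior uncertainty to virtual shoot populations.

The full pipeline composes into a generative model for single shoots:

1. budburst — CDD thresholds drawn from the phenology posterior predictive
   are mapped onto a year's development calendar; dates reaching at least a
   frequency floor (default 1% of 4000 draws) are retained,
2. appearance — each shoot receives a development rate from the IAR
   sampling distribution; internode r is present once the CDD accumulated
   since budburst reaches r / IAR,
3. growth — each shoot draws one joint parameter set (lrc, m1, i1, m2, i2,
   s_r2, s_r7) from the growth posterior plus fresh per-shoot group-level
   deviations for the five non-linear coefficients; every internode then
   follows its deterministic growth curve (the age correction s_age is a
   measurement-side term and is fixed to 0 here; residual Gamma noise is
   not propagated, posterior and group-level variability are).

Shoot length is the sum of internode lengths, reported per day over a
horizon of 30 CDD after budburst (the calibration window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from vinedev.apex_appearance import MAX_CALIBRATED_RANK, IARDistribution, sample_iar
from vinedev.internode_growth import GrowthPosterior, _asymptote_arrays
from vinedev.phenology import (
    BUDBURST_STAGE,
    PhenologyPosterior,
    linearize_stage,
    predict_stage_cdd,
)
from vinedev.thermal_time import DevelopmentCalendar, threshold_to_doy

__all__ = [
    "SimulationConfig",
    "BudburstDates",
    "ShootTrajectory",
    "simulate_budburst_dates",
    "simulate_shoot",
    "simulate_population",
    "weighted_mean_shoot_length",
    "population_summary",
    "length_class_frequencies",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Sampling layout of the population simulation."""

    n_budburst_draws: int = 4000
    budburst_frequency_floor: float = 0.01
    shoots_per_date: int = 80
    horizon_cdd: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.budburst_frequency_floor < 1:
            raise ValueError("frequency floor must be in (0, 1)")
        if self.n_budburst_draws < 100:
            raise ValueError("need at least 100 budburst draws")


@dataclass
class BudburstDates:
    """Day-of-year pmf of predicted budburst plus the retained dates."""

    pmf: pd.Series                  # doy -> probability (sums to 1 over attained draws)
    retained: list[tuple[int, float]]  # (doy, frequency), frequency >= floor


def simulate_budburst_dates(phen_posterior: PhenologyPosterior,
                            calendar: DevelopmentCalendar,
                            config: SimulationConfig | None = None) -> BudburstDates:
    """Map posterior-predictive budburst CDD draws to days and filter by frequency."""
    config = config or SimulationConfig()
    draws = predict_stage_cdd(phen_posterior, linearize_stage(BUDBURST_STAGE),
                              n_draws=config.n_budburst_draws, seed=config.seed)
    draws = np.clip(draws, 0.0, None)
    doys = [threshold_to_doy(calendar, c) for c in draws]
    attained = np.array([d for d in doys if d is not None])
    if attained.size < len(doys):
        warnings.warn(f"{len(doys) - attained.size} of {len(doys)} budburst draws "
                      "never attained within the calendar", UserWarning)
    support, counts = np.unique(attained, return_counts=True)
    pmf = pd.Series(counts / counts.sum(), index=support)
    retained = [(int(d), float(f)) for d, f in pmf.items()
                if f >= config.budburst_frequency_floor]
    if not retained:
        raise ValueError("no budburst date reaches the frequency floor")
    return BudburstDates(pmf=pmf, retained=retained)


@dataclass
class ShootTrajectory:
    """One simulated shoot: per-day apex rank, internode lengths, shoot length."""

    shoot_id: str
    budburst_doy: int
    iar: float
    doy: np.ndarray            # days simulated (budburst .. horizon)
    delta_cdd: np.ndarray      # CDD since budburst per day
    apex_rank: np.ndarray      # whole internodes present per day
    lengths: np.ndarray        # (n_days, max_rank) internode lengths, 0 = absent
    exceeded_calibration: bool = False

    @property
    def shoot_length(self) -> np.ndarray:
        return self.lengths.sum(axis=1)

    def length_at(self, doy: int) -> float:
        """Shoot length at a day: 0 before budburst, last value beyond horizon."""
        if doy < self.doy[0]:
            return 0.0
        i = np.searchsorted(self.doy, doy, side="right") - 1
        return float(self.shoot_length[min(i, len(self.doy) - 1)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"shoot_id": self.shoot_id, "budburst_doy": self.budburst_doy,
                             "doy": self.doy, "apex_rank": self.apex_rank,
                             "shoot_length_cm": self.shoot_length})

    def internode_frame(self) -> pd.DataFrame:
        rows = []
        for i, d in enumerate(self.doy):
            for r in range(int(self.apex_rank[i])):
                rows.append((self.shoot_id, r + 1, int(d), float(self.lengths[i, r])))
        return pd.DataFrame(rows, columns=["shoot_id", "rank", "doy", "length_cm"])


def simulate_shoot(budburst_doy: int, calendar: DevelopmentCalendar,
                   iar_dist: IARDistribution, growth_posterior: GrowthPosterior,
                   seed: int = 0, horizon_cdd: float = 30.0,
                   shoot_id: str | None = None) -> ShootTrajectory:
    """Simulate one shoot deterministically from sampled parameters.

    A posterior draw provides the coefficient set and the group-level SDs
    from which this shoot's own deviations (lrc, m1, i1, m2, i2) are drawn;
    the appearance rate comes from the IAR distribution.  Internode r
    appears once the accumulated CDD reaches r / IAR; its age within a day
    is continuous, so growth curves stay smooth across days.
    """
    rng = np.random.default_rng(seed)
    d = growth_posterior.draws
    total = d.n_chains * d.n_kept
    i = int(rng.integers(total))
    params = growth_posterior.parameter_draw(i)
    sds = growth_posterior.group_sds(i)
    dev = rng.normal(0.0, sds)
    iar = float(sample_iar(iar_dist, 1, seed=int(rng.integers(2**31)))[0])

    doys = calendar.doy[calendar.doy >= budburst_doy]
    delta = calendar.cdd_at(doys) - calendar.cdd_at(budburst_doy)
    keep = delta <= horizon_cdd
    doys, delta = doys[keep], delta[keep]

    n_days = len(doys)
    max_rank = max(int(np.floor(iar * delta.max())), 0) if n_days else 0
    lengths = np.zeros((n_days, max(max_rank, 1)))
    apex = np.floor(iar * delta).astype(int)

    lrc = params.lrc + dev[0]
    A = _asymptote_arrays(np.arange(1, max_rank + 1),
                          params.m1 + dev[1], params.i1 + dev[2],
                          params.m2 + dev[3], params.i2 + dev[4],
                          params.s_r2, params.s_r7)
    A = np.maximum(A, 1e-2)  # guard: a pathological deviation draw must not
    # produce a negative asymptote (shoot length would shrink)
    for r in range(1, max_rank + 1):
        present = delta >= r / iar
        age = delta[present] - (r - 1) / iar  # s_age fixed to 0 in simulation
        lengths[present, r - 1] = A[r - 1] * (1.0 - np.exp(-np.exp(lrc) * age))

    return ShootTrajectory(
        shoot_id=shoot_id or f"bb{budburst_doy}-{seed}",
        budburst_doy=int(budburst_doy), iar=iar, doy=doys, delta_cdd=delta,
        apex_rank=apex, lengths=lengths,
        exceeded_calibration=bool(max_rank > MAX_CALIBRATED_RANK),
    )


@dataclass
class Population:
    """Shoot trajectories grouped by retained budburst date."""

    by_date: dict[int, list[ShootTrajectory]]
    frequencies: dict[int, float]
    config: SimulationConfig

    @property
    def trajectories(self) -> list[ShootTrajectory]:
        return [t for ts in self.by_date.values() for t in ts]


def simulate_population(dates: BudburstDates, calendar: DevelopmentCalendar,
                        iar_dist: IARDistribution, growth_posterior: GrowthPosterior,
                        config: SimulationConfig | None = None) -> Population:
    """shoots_per_date trajectories for every retained budburst date."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    by_date = {}
    freqs = {}
    for doy, freq in dates.retained:
        shoots = [simulate_shoot(doy, calendar, iar_dist, growth_posterior,
                                 seed=int(rng.integers(2**31)),
                                 horizon_cdd=config.horizon_cdd,
                                 shoot_id=f"bb{doy}-s{k}")
                  for k in range(config.shoots_per_date)]
        by_date[doy] = shoots
        freqs[doy] = freq
    return Population(by_date=by_date, frequencies=freqs, config=config)


def weighted_mean_shoot_length(population: Population, doy: int) -> float:
    """Mean shoot length at a day, dates weighted by budburst frequency."""
    num = den = 0.0
    for bb, shoots in population.by_date.items():
        f = population.frequencies[bb]
        num += f * np.mean([t.length_at(doy) for t in shoots])
        den += f
    if den == 0:
        raise ValueError("population has no retained dates")
    return num / den


def population_summary(population: Population,
                       quantiles=(0.05, 0.25, 0.5, 0.75, 0.95)) -> pd.DataFrame:
    """Per-day shoot-length quantiles pooled over all trajectories."""
    doys = sorted({int(d) for t in population.trajectories for d in t.doy})
    rows = []
    for d in doys:
        lengths = [t.length_at(d) for t in population.trajectories
                   if d >= t.budburst_doy]
        row = {"doy": d, "n": len(lengths),
               "weighted_mean": weighted_mean_shoot_length(population, d)}
        for q in quantiles:
            row[f"q{int(q * 100)}"] = float(np.quantile(lengths, q))
        rows.append(row)
    return pd.DataFrame(rows)


def normalized_lengths(population: Population) -> np.ndarray:
    """Max shoot length over max thermal age, one value per trajectory."""
    norm = []
    for t in population.trajectories:
        max_age = t.delta_cdd.max() if len(t.delta_cdd) else np.nan
        if max_age and max_age > 0:
            norm.append(t.shoot_length.max() / max_age)
    return np.asarray(norm)


def length_class_frequencies(population: Population,
                             thresholds: tuple[float, float] | None = None) -> pd.Series:
    """Short/medium/long class shares of normalized shoot length.

    Class boundaries are the terciles of a reference set — pass the
    thresholds derived from observations to compare a simulation against
    them; without thresholds the population's own terciles are used (and
    stored in ``.attrs['thresholds']``).
    """
    norm = normalized_lengths(population)
    if thresholds is None:
        lo, hi = np.quantile(norm, [1 / 3, 2 / 3])
    else:
        lo, hi = thresholds
    labels = np.where(norm <= lo, "short", np.where(norm <= hi, "medium", "long"))
    out = pd.Series(labels).value_counts(normalize=True).reindex(
        ["short", "medium", "long"]).fillna(0.0)
    out.attrs["thresholds"] = (float(lo), float(hi))
    return out
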