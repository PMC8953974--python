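"""Cardinal-temperature estimation by two-stage multi-objective grid search.

The three cardinal temperatures of the thermal-time response are not fit by
a classical optimizer: a coarse 1 °C grid over (t_base, t_opt, t_upper)
triplets (with spacing constraints t_base <= t_opt - 2 and
t_opt <= t_upper - 2) is evaluated against five objectives, a refined
0.1 °C grid is laid around the coarse winner, and the final triplet is the
one most frequently optimal under a weighted-sum sweep over a simplex
lattice of weights.

For each candidate triplet the development calendars are rebuilt, CDD is
re-attached to the phenology ratings and shoot digitizations, and the two
REML mixed models (CDD ~ stage, apex rank ~ CDD) are refit.  The objectives
are: the treatment-averaged normalized gap between the two organ
development rates (the reciprocal internode appearance rate should equal
the leaf appearance rate), the absolute year effects of both models (CDD
requirements are assumed year-independent), and train/test NRMSEs used as
feasibility constraints — thresholds cut the grid down to a feasible
subset, min-max normalization puts the three main objectives on [0, 1], and
every weight vector on the 0.05 simplex lattice votes for its argmin.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vinedev.apex_appearance import fit_apex_reml
from vinedev.inference_core import error_metrics
from vinedev.phenology import fit_phenology_reml
from vinedev.thermal_time import (
    CardinalTemperatures,
    DevelopmentCalendar,
    hourly_development,
    validate_hourly_series,
)

__all__ = [
    "GridSpec",
    "ObjectiveSet",
    "Thresholds",
    "WeatherCache",
    "generate_grid",
    "delta_odr",
    "evaluate_triplet",
    "threshold_filter",
    "minmax_normalize",
    "weight_lattice",
    "pareto_select",
    "run_two_stage",
    "OptimizationConfig",
    "TwoStageResult",
    "coarse_grid_paper",
    "refined_grid_around",
]


@dataclass(frozen=True)
class GridSpec:
    """Ordered candidate values per cardinal temperature (°C)."""

    t_base_values: tuple
    t_opt_values: tuple
    t_upper_values: tuple
    min_gap: float = 2.0  # t_base <= t_opt - gap and t_opt <= t_upper - gap

    def __post_init__(self):
        for vals in (self.t_base_values, self.t_opt_values, self.t_upper_values):
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0 or np.any(np.diff(arr) <= 0):
                raise ValueError("grid values must be non-empty and strictly increasing")


def generate_grid(spec: GridSpec) -> list[CardinalTemperatures]:
    """All constraint-satisfying triplets, exactly once, lexicographic order."""
    out = []
    for tb, to, tu in itertools.product(spec.t_base_values, spec.t_opt_values,
                                        spec.t_upper_values):
        if tb <= to - spec.min_gap and to <= tu - spec.min_gap:
            out.append(CardinalTemperatures(float(tb), float(to), float(tu)))
    if not out:
        raise ValueError("grid specification admits no triplet under the "
                         "spacing constraints")
    return out


def coarse_grid_paper() -> GridSpec:
    """The full coarse search space: 1 °C steps, t_base -60..15,
    t_opt 10..35, t_upper 15..55."""
    return GridSpec(tuple(range(-60, 16)), tuple(range(10, 36)), tuple(range(15, 56)))


def refined_grid_around(center: CardinalTemperatures, step: float = 0.1,
                        halfwidth: float = 0.9) -> GridSpec:
    """Refinement grid spanning center +/- halfwidth at the given step."""
    def rng(c):
        n = int(round(halfwidth / step))
        return tuple(round(c + k * step, 6) for k in range(-n, n + 1))

    return GridSpec(rng(center.t_base), rng(center.t_opt), rng(center.t_upper))


def delta_odr(lar_a: float, lar_e: float, iar_a: float, iar_e: float) -> float:
    """Treatment-averaged normalized gap between organ development rates.

    For each treatment: |1/IAR - LAR| / ((1/IAR + LAR)/2); averaged over the
    two treatments.  Zero exactly when the reciprocal appearance rate equals
    the leaf appearance rate in both treatments.
    """
    vals = []
    for lar, iar in ((lar_a, iar_a), (lar_e, iar_e)):
        if lar <= 0 or iar <= 0:
            raise ValueError("rates must be positive")
        r = 1.0 / iar
        vals.append(abs(r - lar) / ((r + lar) / 2.0))
    return float(np.mean(vals))


@dataclass
class ObjectiveSet:
    """The five objectives (plus the rates behind them) for one triplet."""

    delta_odr: float
    e_year_phen: float
    e_year_apex: float
    nrmse_train_phen: float
    nrmse_test_phen: float
    nrmse_train_apex: float
    nrmse_test_apex: float
    lar: dict
    iar: dict


@dataclass(frozen=True)
class Thresholds:
    """Feasibility cuts applied before Pareto selection."""

    delta_odr: float = 0.05
    e_year_phen: float = 0.05
    e_year_apex: float = 0.05
    nrmse_train_phen: float = 0.20
    nrmse_train_apex: float = 0.20
    nrmse_gap_phen: float = 0.05
    nrmse_gap_apex: float = 0.05

    def violation(self, o: ObjectiveSet) -> float:
        """Largest condition/threshold ratio; < 1 exactly when feasible."""
        return max(
            o.delta_odr / self.delta_odr,
            o.e_year_phen / self.e_year_phen,
            o.e_year_apex / self.e_year_apex,
            o.nrmse_train_phen / self.nrmse_train_phen,
            o.nrmse_train_apex / self.nrmse_train_apex,
            abs(o.nrmse_train_phen - o.nrmse_test_phen) / self.nrmse_gap_phen,
            abs(o.nrmse_train_apex - o.nrmse_test_apex) / self.nrmse_gap_apex,
        )

    def passes(self, o: ObjectiveSet) -> bool:
        return (o.delta_odr < self.delta_odr
                and o.e_year_phen < self.e_year_phen
                and o.e_year_apex < self.e_year_apex
                and o.nrmse_train_phen < self.nrmse_train_phen
                and o.nrmse_train_apex < self.nrmse_train_apex
                and abs(o.nrmse_train_phen - o.nrmse_test_phen) < self.nrmse_gap_phen
                and abs(o.nrmse_train_apex - o.nrmse_test_apex) < self.nrmse_gap_apex)


class WeatherCache:
    """Hourly series packed into (days x 24) arrays for fast calendar rebuilds.

    The grid search rebuilds the development calendar thousands of times;
    validation and timestamp handling happen once here.
    """

    def __init__(self, weather: dict[int, pd.DataFrame], doy0: int = 1):
        self.doy0 = doy0
        self._temps = {}
        self._doys = {}
        for year, df in weather.items():
            df = validate_hourly_series(df)
            ts = df["timestamp"]
            df = df[(ts.dt.year == year) & (ts.dt.dayofyear >= doy0)]
            doys = np.sort(df["timestamp"].dt.dayofyear.unique())
            order = np.argsort(df["timestamp"].to_numpy(), kind="stable")
            temps = df["t_air_c"].to_numpy(dtype=float)[order].reshape(len(doys), 24)
            self._temps[int(year)] = temps
            self._doys[int(year)] = doys

    def calendars(self, ct: CardinalTemperatures) -> dict[int, DevelopmentCalendar]:
        out = {}
        for year, temps in self._temps.items():
            dd = hourly_development(temps, ct).mean(axis=1)
            out[year] = DevelopmentCalendar(year=year, doy0=self.doy0,
                                            doy=self._doys[year], dd=dd)
        return out


def _attach(df: pd.DataFrame, calendars: dict[int, DevelopmentCalendar]) -> pd.DataFrame:
    from vinedev.phenology import attach_cdd

    return attach_cdd(df, calendars)


def evaluate_triplet(ct: CardinalTemperatures, phen_train: pd.DataFrame,
                     phen_test: pd.DataFrame, apex_train: pd.DataFrame,
                     apex_test: pd.DataFrame, weather: WeatherCache) -> ObjectiveSet | None:
    """Objectives for one candidate triplet; None when a mixed model fails.

    Pure function of its inputs: calendars are rebuilt under ``ct``, CDD is
    re-attached from raw doys, both REML models are refit on training data
    and predictions (fixed effects only, so train and test are comparable)
    feed the NRMSE terms.
    """
    try:
        cals = weather.calendars(ct)
        ptr, pte = _attach(phen_train, cals), _attach(phen_test, cals)
        atr, ate = _attach(apex_train, cals), _attach(apex_test, cals)
        fit_p = fit_phenology_reml(ptr)
        fit_a = fit_apex_reml(atr)
        trts = sorted(ptr["trt"].unique())
        lar = {t: fit_p.slope_by_trt[t] for t in trts}
        iar = {t: fit_a.slope_by_trt[t] for t in trts}
        return ObjectiveSet(
            delta_odr=delta_odr(lar[trts[0]], lar[trts[-1]], iar[trts[0]], iar[trts[-1]]),
            e_year_phen=abs(fit_p.year_effect),
            e_year_apex=abs(fit_a.year_effect),
            nrmse_train_phen=error_metrics(ptr["cdd"], fit_p.predict(ptr), "nrmse"),
            nrmse_test_phen=error_metrics(pte["cdd"], fit_p.predict(pte), "nrmse"),
            nrmse_train_apex=error_metrics(atr["r_apex"], fit_a.predict(atr), "nrmse"),
            nrmse_test_apex=error_metrics(ate["r_apex"], fit_a.predict(ate), "nrmse"),
            lar=lar, iar=iar,
        )
    except (np.linalg.LinAlgError, ValueError, KeyError):
        return None


def threshold_filter(results: dict, thresholds: Thresholds | None = None) -> dict:
    """Triplets meeting all seven feasibility conditions."""
    if not results:
        raise ValueError("no evaluated triplets to filter")
    thresholds = thresholds or Thresholds()
    return {k: v for k, v in results.items() if v is not None and thresholds.passes(v)}


def minmax_normalize(values) -> np.ndarray:
    """Affine map onto [0, 1]; a degenerate range maps to all zeros (warned)."""
    import warnings

    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        warnings.warn("degenerate range in min-max normalization: all values equal",
                      UserWarning)
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def weight_lattice(step: float = 0.05) -> np.ndarray:
    """All (w1, w2, w3) on the simplex lattice with exact unit sum."""
    n = int(round(1.0 / step))
    out = [(i / n, j / n, (n - i - j) / n)
           for i in range(n + 1) for j in range(n + 1 - i)]
    return np.asarray(out)


def pareto_select(feasible: dict, weight_step: float = 0.05):
    """Count, per triplet, the weight vectors whose weighted sum it minimizes.

    The three main objectives are min-max normalized within the feasible
    subset; ties credit every tied minimum.  Returns (counts, winner), the
    winner being the most frequent optimum (deterministic tie-break on the
    triplet values).
    """
    if not feasible:
        raise ValueError("empty feasible subset: relax the grid or thresholds")
    keys = sorted(feasible, key=lambda ct: ct.as_tuple())
    obj = np.column_stack([
        [feasible[k].delta_odr for k in keys],
        minmax_normalize([feasible[k].e_year_phen for k in keys]),
        minmax_normalize([feasible[k].e_year_apex for k in keys]),
    ])
    counts = {k: 0 for k in keys}
    for w in weight_lattice(weight_step):
        f = obj @ w
        fmin = f.min()
        for i in np.flatnonzero(np.isclose(f, fmin, rtol=0, atol=1e-12)):
            counts[keys[i]] += 1
    winner = max(keys, key=lambda k: (counts[k], tuple(-x for x in k.as_tuple())))
    return counts, winner


@dataclass
class OptimizationConfig:
    coarse: GridSpec
    refine_step: float = 0.1
    refine_halfwidth: float = 0.9
    thresholds: Thresholds = field(default_factory=Thresholds)
    weight_step: float = 0.05


@dataclass
class TwoStageResult:
    coarse_winner: CardinalTemperatures
    winner: CardinalTemperatures
    coarse_counts: dict
    final_counts: dict
    audit: pd.DataFrame


def _audit_frame(results: dict, feasible: dict, counts: dict) -> pd.DataFrame:
    rows = []
    for ct, o in results.items():
        row = {"t_base": ct.t_base, "t_opt": ct.t_opt, "t_upper": ct.t_upper}
        if o is None:
            row.update({"feasible": False, "pareto_count": 0})
        else:
            row.update({
                "delta_odr": o.delta_odr, "e_year_phen": o.e_year_phen,
                "e_year_apex": o.e_year_apex,
                "nrmse_train_phen": o.nrmse_train_phen,
                "nrmse_test_phen": o.nrmse_test_phen,
                "nrmse_train_apex": o.nrmse_train_apex,
                "nrmse_test_apex": o.nrmse_test_apex,
                "feasible": ct in feasible,
                "pareto_count": counts.get(ct, 0),
            })
        rows.append(row)
    return pd.DataFrame(rows)


def run_two_stage(phen_train: pd.DataFrame, phen_test: pd.DataFrame,
                  apex_train: pd.DataFrame, apex_test: pd.DataFrame,
                  weather: WeatherCache, config: OptimizationConfig,
                  progress: bool = False) -> TwoStageResult:
    """Coarse grid -> Pareto winner -> refined grid -> combined Pareto winner.

    The final selection pools the feasible sets of both stages (the refined
    stage only adds triplets not already evaluated), re-normalizes and
    re-runs the weighted-sum vote; the audit frame records every triplet.
    """
    def sweep(grid):
        res = {}
        for i, ct in enumerate(grid):
            res[ct] = evaluate_triplet(ct, phen_train, phen_test,
                                       apex_train, apex_test, weather)
            if progress and (i + 1) % 50 == 0:
                print(f"  evaluated {i + 1}/{len(grid)} triplets")
        return res

    coarse_grid = generate_grid(config.coarse)
    results = sweep(coarse_grid)
    feas1 = {k: v for k, v in results.items()
             if v is not None and config.thresholds.passes(v)}
    if feas1:
        counts1, winner1 = pareto_select(feas1, config.weight_step)
    else:
        # the feasibility bands (year effects < 0.05) can be narrower than
        # the coarse step and thread between grid points: relax by refining
        # around the least-violating triplet instead of giving up
        counts1 = {}
        winner1 = min((k for k, v in results.items() if v is not None),
                      key=lambda k: config.thresholds.violation(results[k]))

    refined_spec = refined_grid_around(winner1, config.refine_step, config.refine_halfwidth)
    refined_grid = [ct for ct in generate_grid(refined_spec) if ct not in results]
    results2 = sweep(refined_grid)
    results.update(results2)
    feas_all = threshold_filter(results, config.thresholds)
    counts2, winner2 = pareto_select(feas_all, config.weight_step)

    audit = _audit_frame(results, feas_all, counts2)
    return TwoStageResult(coarse_winner=winner1, winner=winner2,
                          coarse_counts=counts1, final_counts=counts2, audit=audit)
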