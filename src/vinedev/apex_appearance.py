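"""Internode appearance: the apex-rank ~ CDD model and the IAR distribution.

The highest internode rank present on a shoot (the apex rank) grows
linearly with cumulative development days over the calibration window
(maximum observed rank 23).  The slope of that line is the internode
appearance rate, IAR, in ranks per CDD; its reciprocal is the thermal time
needed for one new internode and links this model to the phenology slope
(leaf appearance rate, CDD per leaf).

For the shoot simulator the posterior is condensed into a single Gaussian
sampling distribution N(mu, sigma) for per-shoot appearance rates, where
sigma combines the posterior uncertainty of the fixed slope with the
between-shoot slope variability in quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from vinedev.inference_core import (
    HierarchicalLinearModel,
    MCMCConfig,
    PosteriorSamples,
    run_mcmc,
)
from vinedev.phenology import RemlFit, _mixedlm_fit
from vinedev.thermal_time import DevelopmentCalendar

__all__ = [
    "MAX_CALIBRATED_RANK",
    "IARDistribution",
    "fit_apex_reml",
    "fit_apex_bayes",
    "extract_iar",
    "sample_iar",
    "predict_apex_trajectory",
    "read_digitization_csv",
]

#: highest apex rank in the calibration domain; beyond it predictions extrapolate
MAX_CALIBRATED_RANK = 23

APEX_VARIANTS = ("full", "rm-interaction", "rm-year", "rm-trt", "add-year-GE", "final")


def read_digitization_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"year", "trt", "ring", "plant", "shoot", "doy", "r_apex"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"digitization file lacks columns {sorted(missing)}")
    return df


def fit_apex_reml(observations: pd.DataFrame) -> RemlFit:
    """REML fit of r_apex ~ CDD x trt + year with ring/plant/shoot terms.

    The per-treatment CDD slope is the IAR (ranks/CDD) handed to the
    cardinal-temperature optimizer, together with the raw year coefficient.
    """
    df = observations.copy()
    df["plant_id"] = df["ring"].astype(str) + "/" + df["plant"].astype(str)
    df["shoot_id"] = df["plant_id"] + "/" + df["shoot"].astype(str) + "@" + df["year"].astype(str)
    trts = sorted(df["trt"].unique())
    years = sorted(df["year"].unique())
    df["trt_i"] = (df["trt"] != trts[0]).astype(float)
    df["year_i"] = (df["year"] != years[0]).astype(float)

    vc = {"plant": "0 + C(plant_id)",
          "shoot": "0 + C(shoot_id)",
          "shootslope": "0 + C(shoot_id):cdd"}
    res = _mixedlm_fit("r_apex ~ cdd * trt_i + year_i", df, "ring", vc, "1")

    p = res.params
    slope = float(p["cdd"])
    inter = float(p.get("cdd:trt_i", 0.0))
    return RemlFit(
        intercept=float(p["Intercept"]),
        slope_by_trt={trts[0]: slope, trts[-1]: slope + inter},
        year_effect=float(p.get("year_i", 0.0)),
        trt_effect=float(p.get("trt_i", 0.0)),
        params=p,
        converged=bool(getattr(res, "converged", True)),
        predictor="cdd",
    )


def _design_apex(df: pd.DataFrame, variant: str):
    trts = tuple(sorted(df["trt"].unique()))
    years = tuple(sorted(df["year"].unique()))
    cdd = df["cdd"].to_numpy(dtype=float)
    trt_i = (df["trt"] != trts[0]).to_numpy(dtype=float)
    year_i = (df["year"] != years[0]).to_numpy(dtype=float)

    cols = {"intercept": np.ones(len(df)), "cdd": cdd}
    if variant == "full":
        cols.update({"trt": trt_i, "cdd:trt": cdd * trt_i, "year": year_i})
    elif variant == "rm-interaction":
        cols.update({"trt": trt_i, "year": year_i})
    elif variant == "rm-year":
        cols.update({"trt": trt_i})
    elif variant == "rm-trt":
        cols.update({"year": year_i})
    elif variant in ("add-year-GE", "final"):
        pass
    else:
        raise ValueError(f"unknown variant {variant!r}; choose from {APEX_VARIANTS}")

    def dummies(key):
        codes, _ = pd.factorize(key, sort=True)
        return np.eye(codes.max() + 1)[codes]

    ring = df["ring"].astype(str)
    plant = ring + "/" + df["plant"].astype(str)
    shoot = plant + "/" + df["shoot"].astype(str) + "@" + df["year"].astype(str)
    Z_shoot = dummies(shoot)
    res = [("ring", dummies(ring)), ("plant", dummies(plant)), ("shoot", Z_shoot),
           ("shoot_slope", Z_shoot * cdd[:, None])]
    if variant == "add-year-GE":
        res.append(("year", dummies(df["year"].astype(str))))
    X = np.column_stack(list(cols.values()))
    return X, list(cols), res, trts, years


def fit_apex_bayes(observations: pd.DataFrame, variant: str = "final",
                   config: MCMCConfig | None = None,
                   require_convergence: bool = False) -> PosteriorSamples:
    """Gibbs fit of one apex-model ladder variant (Gaussian likelihood)."""
    X, names, res, _, _ = _design_apex(observations, variant)
    model = HierarchicalLinearModel(observations["r_apex"].to_numpy(dtype=float),
                                    X, names, res)
    draws = run_mcmc(model, config)
    if require_convergence and not draws.converged:
        raise RuntimeError("apex posterior failed convergence diagnostics "
                           f"(max Rhat {draws.diagnostics['rhat'].max():.3f})")
    return draws


@dataclass(frozen=True)
class IARDistribution:
    """Gaussian sampling distribution for per-shoot appearance rates."""

    mu: float     # ranks per CDD
    sigma: float  # ranks per CDD

    def __post_init__(self):
        if self.mu <= 0 or self.sigma < 0:
            raise ValueError("IAR distribution needs mu > 0 and sigma >= 0")
        if self.mu - 3 * self.sigma <= 0:
            raise ValueError("IAR distribution too wide: mu - 3 sigma must stay positive")

    @property
    def reciprocal(self) -> float:
        """CDD needed per new internode, 1/mu."""
        return 1.0 / self.mu


def extract_iar(posterior: PosteriorSamples) -> IARDistribution:
    """Condense the final-variant posterior into the IAR sampling distribution.

    mu is the posterior mean of the fixed CDD slope; sigma combines the
    posterior SD of that slope with the (posterior mean) between-shoot slope
    SD in quadrature — the paper-reported total variability.
    """
    if "cdd" not in posterior.names():
        raise KeyError("posterior lacks the fixed CDD slope")
    if "sd_shoot_slope" not in posterior.names():
        raise KeyError("posterior lacks the group-level shoot slope SD "
                       "(structure error: refit with the shoot-slope term)")
    slope = posterior.draws("cdd")
    sd_group = float(posterior.draws("sd_shoot_slope").mean())
    sigma = float(np.sqrt(slope.std() ** 2 + sd_group ** 2))
    return IARDistribution(mu=float(slope.mean()), sigma=sigma)


def sample_iar(dist: IARDistribution, n: int, seed: int = 0) -> np.ndarray:
    """n per-shoot rates, Gaussian truncated at zero, reproducible by seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if dist.sigma == 0:
        return np.full(n, dist.mu)
    draws = rng.normal(dist.mu, dist.sigma, size=n)
    while True:  # mu - 3 sigma > 0 makes redraws essentially never needed
        bad = draws <= 0
        if not bad.any():
            return draws
        draws[bad] = rng.normal(dist.mu, dist.sigma, size=bad.sum())


def predict_apex_trajectory(iar: float, budburst_doy: int,
                            calendar: DevelopmentCalendar,
                            sigma: float | None = None) -> pd.DataFrame:
    """Expected apex rank per day: iar x CDD accumulated since budburst.

    With ``sigma`` the iar +/- sigma band is added.  Days where the central
    trajectory exceeds the calibration maximum rank are flagged
    ``extrapolated``.
    """
    doys = calendar.doy[calendar.doy >= budburst_doy]
    delta = calendar.cdd_at(doys) - calendar.cdd_at(budburst_doy)
    out = pd.DataFrame({"doy": doys, "rank_mean": iar * delta})
    if sigma is not None:
        out["rank_lo"] = (iar - sigma) * delta
        out["rank_hi"] = (iar + sigma) * delta
    out["extrapolated"] = out["rank_mean"] > MAX_CALIBRATED_RANK
    return out
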