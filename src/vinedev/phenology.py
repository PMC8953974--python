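"""Budburst phenology: stage linearization and the CDD ~ stage models.

Grapevine growth stages on the modified E-L scale are first linearized so
that accumulated thermal time (CDD) is approximately linear in stage: from
stage 7 upward each separated leaf counts one stage, budburst (stage 4) is
fixed at 4, and pre-budburst stages are drawn closer together.  On the
linearized scale a hierarchical linear model relates the CDD observed at a
rating date to the attained stage, with group-level intercepts for ring,
year-within-ring and plant and a group-level slope per plant.

The model exists in two forms: a frequentist REML fit (statsmodels MixedLM)
used inside the cardinal-temperature optimizer, where thousands of refits
must stay cheap, and Bayesian variants (Gaussian and exponentially modified
Gaussian likelihoods) fit by Gibbs sampling for budburst prediction, where
the posterior also carries the variability needed by the shoot simulator.
The exGaussian location is modelled by the linear predictor, so its slope
remains comparable to the Gaussian fit; the exponential component captures
the right skew of ratings that include shoots ahead of the average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from vinedev.inference_core import (
    HierarchicalLinearModel,
    MCMCConfig,
    PosteriorSamples,
    hdi,
    run_mcmc,
)
from vinedev.thermal_time import DevelopmentCalendar, threshold_to_doy

__all__ = [
    "STAGE_LINEARIZATION",
    "BEGIN_FLOWERING_LINEAR",
    "BUDBURST_STAGE",
    "linearize_stage",
    "attach_cdd",
    "fit_phenology_reml",
    "fit_phenology_bayes",
    "predict_stage_cdd",
    "predict_stage_calendar",
    "PhenologyPosterior",
    "RemlFit",
    "read_ratings_csv",
]

# modified E-L stage -> linearized value; strictly increasing, budburst fixed at 4
STAGE_LINEARIZATION: dict[int, float] = {
    1: 2.00, 2: 3.75, 3: 3.875, 4: 4.00, 5: 5.00,
    7: 6.50, 9: 8.50, 11: 9.50, 12: 10.50, 13: 11.50,
    14: 12.50, 15: 13.50, 16: 15.50, 17: 17.50, 18: 19.50,
}
#: linearized value assigned to "beginning of flowering" (about 16 leaves separated)
BEGIN_FLOWERING_LINEAR = 21.5
BUDBURST_STAGE = 4


class UnmappedStageError(KeyError):
    """E-L stage outside the linearization table (e.g. 6, 8, 10)."""


def linearize_stage(el_stage: int) -> float:
    """Linearized value of a modified E-L stage (lookup, no interpolation)."""
    try:
        return STAGE_LINEARIZATION[int(el_stage)]
    except (KeyError, ValueError) as exc:
        raise UnmappedStageError(
            f"E-L stage {el_stage!r} has no linearized value; "
            f"mapped stages are {sorted(STAGE_LINEARIZATION)}") from exc


def attach_cdd(observations: pd.DataFrame,
               calendars: dict[int, DevelopmentCalendar]) -> pd.DataFrame:
    """Add ``el_linear`` and ``cdd`` columns (end-of-day CDD at the rating doy)."""
    df = observations.copy()
    if "el_stage" in df.columns:
        df["el_linear"] = df["el_stage"].map(linearize_stage)
    cdd = np.empty(len(df))
    for year, g in df.groupby("year"):
        cdd[df.index.get_indexer(g.index)] = calendars[int(year)].cdd_at(g["doy"].to_numpy())
    df["cdd"] = cdd
    return df


def read_ratings_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"year", "trt", "ring", "plant", "shoot", "doy", "el_stage"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"ratings file lacks columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# REML (frequentist) fit for the optimizer


@dataclass
class RemlFit:
    """Point estimates of the CDD ~ stage mixed model.

    ``slope_by_trt`` is the leaf appearance rate LAR in CDD per linearized
    stage (~ CDD per leaf) per treatment; ``year_effect`` the raw
    second-year fixed-effect coefficient in CDD.
    """

    intercept: float
    slope_by_trt: dict[str, float]
    year_effect: float
    trt_effect: float
    params: pd.Series
    converged: bool
    predictor: str = "el_linear"

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Fixed-effects-only prediction (group effects left out)."""
        years = sorted(df["year"].unique())
        base_year = years[0]
        year_ind = (df["year"] != base_year).to_numpy(dtype=float)
        trts = sorted(df["trt"].unique())
        trt_ind = (df["trt"] != trts[0]).to_numpy(dtype=float)
        x = df[self.predictor].to_numpy(dtype=float)
        slope_a = self.slope_by_trt[trts[0]]
        slope_b = self.slope_by_trt[trts[-1]]
        return (self.intercept + self.trt_effect * trt_ind
                + self.year_effect * year_ind
                + x * np.where(trt_ind > 0, slope_b, slope_a))


def _mixedlm_fit(formula, data, groups, vc_formula, re_formula):
    """REML fit; degenerate data (zero residual variance) falls back to the
    fixed-effects ordinary-least-squares solution, which is then exact."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, data, groups=data[groups],
                                re_formula=re_formula, vc_formula=vc_formula)
            return model.fit(reml=True, method="lbfgs", maxiter=200)
        except (np.linalg.LinAlgError, ValueError):
            warnings.warn("mixed model singular (variance at boundary); "
                          "falling back to fixed-effects OLS", UserWarning)
            return smf.ols(formula, data).fit()


def fit_phenology_reml(observations: pd.DataFrame) -> RemlFit:
    """REML fit of CDD ~ trt x el_linear + year with the nested group terms.

    A variance component converging at the boundary is reported as a
    warning by the backend, not a failure.
    """
    df = observations.copy()
    df["plant_id"] = (df["ring"].astype(str) + "/" + df["plant"].astype(str))
    df["year_ring"] = df["year"].astype(str) + ":" + df["ring"].astype(str)
    trts = sorted(df["trt"].unique())
    years = sorted(df["year"].unique())
    df["trt_i"] = (df["trt"] != trts[0]).astype(float)
    df["year_i"] = (df["year"] != years[0]).astype(float)

    vc = {"yearring": "0 + C(year_ring)",
          "plant": "0 + C(plant_id)",
          "plantslope": "0 + C(plant_id):el_linear"}
    res = _mixedlm_fit("cdd ~ trt_i * el_linear + year_i", df, "ring", vc, "1")

    p = res.params
    slope = float(p["el_linear"])
    inter = float(p.get("trt_i:el_linear", 0.0))
    fit = RemlFit(
        intercept=float(p["Intercept"]),
        slope_by_trt={trts[0]: slope, trts[-1]: slope + inter},
        year_effect=float(p.get("year_i", 0.0)),
        trt_effect=float(p.get("trt_i", 0.0)),
        params=p,
        converged=bool(getattr(res, "converged", True)),
    )
    return fit


# ---------------------------------------------------------------------------
# Bayesian variants

PHENOLOGY_VARIANTS = ("full", "no-interaction", "no-year", "final", "final-exgaussian")


@dataclass
class PhenologyPosterior:
    """Posterior of a CDD ~ stage variant; the currency for budburst prediction."""

    variant: str
    likelihood: str
    draws: PosteriorSamples
    trt_levels: tuple
    year_levels: tuple

    @property
    def intercept(self) -> np.ndarray:
        return self.draws.draws("intercept")

    @property
    def slope(self) -> np.ndarray:
        return self.draws.draws("el_linear")


def _design_phenology(df: pd.DataFrame, variant: str):
    trts = tuple(sorted(df["trt"].unique()))
    years = tuple(sorted(df["year"].unique()))
    el = df["el_linear"].to_numpy(dtype=float)
    trt_i = (df["trt"] != trts[0]).to_numpy(dtype=float)
    year_i = (df["year"] != years[0]).to_numpy(dtype=float)
    one = np.ones(len(df))

    cols = {"intercept": one, "el_linear": el}
    if variant == "full":
        cols["trt"] = trt_i
        cols["trt:el_linear"] = trt_i * el
        cols["year"] = year_i
    elif variant == "no-interaction":
        cols["trt"] = trt_i
        cols["year"] = year_i
    elif variant == "no-year":
        cols["trt"] = trt_i
    elif variant in ("final", "final-exgaussian"):
        pass
    else:
        raise ValueError(f"unknown variant {variant!r}; choose from {PHENOLOGY_VARIANTS}")

    X = np.column_stack(list(cols.values()))
    names = list(cols)

    def dummies(key):
        codes, _ = pd.factorize(key, sort=True)
        return np.eye(codes.max() + 1)[codes]

    ring = df["ring"].astype(str)
    plant = ring + "/" + df["plant"].astype(str)
    yearring = df["year"].astype(str) + ":" + ring
    Z_ring = dummies(ring)
    Z_yearring = dummies(yearring)
    Z_plant = dummies(plant)
    Z_plant_slope = Z_plant * el[:, None]
    res = [("ring", Z_ring), ("year_ring", Z_yearring),
           ("plant", Z_plant), ("plant_slope", Z_plant_slope)]
    return X, names, res, trts, years


def fit_phenology_bayes(observations: pd.DataFrame, variant: str = "final-exgaussian",
                        config: MCMCConfig | None = None,
                        require_convergence: bool = False) -> PhenologyPosterior:
    """Gibbs fit of one model-ladder variant.

    All variants share the group-level structure (ring, year-within-ring and
    plant intercepts, plant slope); the ladder removes fixed effects only.
    ``final-exgaussian`` swaps the Gaussian likelihood for an exGaussian one.
    """
    X, names, res, trts, years = _design_phenology(observations, variant)
    likelihood = "exgaussian" if variant == "final-exgaussian" else "gaussian"
    model = HierarchicalLinearModel(observations["cdd"].to_numpy(dtype=float),
                                    X, names, res, likelihood=likelihood)
    draws = run_mcmc(model, config)
    if require_convergence and not draws.converged:
        raise RuntimeError("phenology posterior failed convergence diagnostics "
                           f"(max Rhat {draws.diagnostics['rhat'].max():.3f})")
    return PhenologyPosterior(variant=variant, likelihood=likelihood, draws=draws,
                              trt_levels=trts, year_levels=years)


def pointwise_loglik(posterior: PhenologyPosterior, observations: pd.DataFrame,
                     max_draws: int = 500, seed: int = 0) -> np.ndarray:
    """Draws x observations log-likelihood matrix for PSIS-LOO comparison.

    Group-level effects are marginalized out in the Gaussian sense by adding
    their sampled deviations is not required here: the ladder comparison uses
    the fixed-effect predictive density, identical in structure across
    variants.
    """
    from scipy import stats as st

    X, names, _, _, _ = _design_phenology(observations, posterior.variant)
    rng = np.random.default_rng(seed)
    ps = posterior.draws
    total = ps.n_chains * ps.n_kept
    idx = rng.choice(total, size=min(max_draws, total), replace=False)
    beta = np.column_stack([ps.draws(n)[idx] for n in names])
    sigma = ps.draws("sigma")[idx]
    y = observations["cdd"].to_numpy(dtype=float)
    loc = beta @ X.T  # (draws, n)
    if posterior.likelihood == "exgaussian":
        beta_exg = ps.draws("beta_exg")[idx]
        K = beta_exg[:, None] / sigma[:, None]  # scipy's K = (mean of exp part)/sigma
        return st.exponnorm.logpdf(y[None, :], K, loc=loc, scale=sigma[:, None])
    return st.norm.logpdf(y[None, :], loc=loc, scale=sigma[:, None])


def predict_stage_cdd(posterior: PhenologyPosterior, el_linear: float,
                      n_draws: int = 4000, seed: int = 0,
                      include_noise: bool = True) -> np.ndarray:
    """Posterior-predictive CDD thresholds for one linearized stage.

    Group-level effects are not included (predictions target a new, average
    shoot); the likelihood noise is sampled unless ``include_noise`` is off.
    """
    rng = np.random.default_rng(seed)
    ps = posterior.draws
    total = ps.n_chains * ps.n_kept
    idx = rng.choice(total, size=n_draws, replace=n_draws > total)
    # further fixed effects (full/no-year variants) evaluate at reference levels
    loc = ps.draws("intercept")[idx] + ps.draws("el_linear")[idx] * el_linear
    if not include_noise:
        return loc
    sigma = ps.draws("sigma")[idx]
    out = loc + rng.standard_normal(n_draws) * sigma
    if posterior.likelihood == "exgaussian":
        out = out + rng.exponential(ps.draws("beta_exg")[idx])
    return out


@dataclass
class CalendarPrediction:
    """Budburst (or any stage) prediction mapped onto one year's calendar."""

    pmf: pd.Series  # doy -> probability, over attained draws
    median_doy: int
    hdi50: list[tuple]
    hdi95: list[tuple]
    unattained_fraction: float


def predict_stage_calendar(posterior: PhenologyPosterior, el_linear: float,
                           calendar: DevelopmentCalendar, n_draws: int = 4000,
                           seed: int = 0) -> CalendarPrediction:
    """Map CDD threshold draws to days of year via the accumulation calendar.

    The day-of-year distribution may have gaps (cold spells accumulate no
    development), which the discrete highest-density intervals preserve.
    """
    cdd_draws = predict_stage_cdd(posterior, el_linear, n_draws, seed)
    cdd_draws = np.clip(cdd_draws, 0.0, None)
    doys = np.array([threshold_to_doy(calendar, c) or -1 for c in cdd_draws])
    attained = doys[doys > 0]
    frac_missing = 1.0 - attained.size / doys.size
    if frac_missing > 0.05:
        warnings.warn(f"{100 * frac_missing:.1f}% of draws never reach the threshold "
                      "within the calendar", UserWarning)
    if attained.size == 0:
        raise ValueError("no draw attains the threshold within the calendar")
    support, counts = np.unique(attained, return_counts=True)
    pmf = pd.Series(counts / counts.sum(), index=support)
    return CalendarPrediction(
        pmf=pmf,
        median_doy=int(np.median(attained)),
        hdi50=hdi(attained, 0.5, discrete=True),
        hdi95=hdi(attained, 0.95, discrete=True),
        unattained_fraction=frac_missing,
    )
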