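"""Internode length: rank-structured asymptotic growth under a Gamma likelihood.

An internode of rank R grows towards a rank-specific asymptote A(R) along a
saturating curve in its thermal age (CDD since its appearance):

    IL(R, age) = A(R) * (1 - exp(-exp(lrc) * (age + s_age)))

For ranks <= 7 the asymptote is linear in rank with indicator shifts at
ranks 2 and 7 (mimicking the observed Gompertz-like dip); above rank 7 it
follows a period-3 step pattern tied to the three morphologically distinct
phytomer types:

    A(R) = m1 * ((R-1) + 1[R=2] s_r2 + 1[R=7] s_r7) + i1      (R <= 7)
    A(R) = ((R+1) mod 3) * m2 + i2                            (R >  7)

The thermal age is inferred from the apex rank at digitization via the
appearance rate: age = (r_apex - R + 1) / IAR, and s_age is a global
measurement-timing correction (with a group-level deviation per
shoot-and-date) that is fixed to zero in forward simulation.

The Bayesian fit uses a Gamma likelihood whose mean is the growth curve
(variance mu^2 / shape), with group-level deviations per shoot on the five
non-linear coefficients and group-level heterogeneity of the log shape
parameter by rank, ring, plant and shoot.  Sampling is blocked adaptive
Metropolis-within-Gibbs: random-walk updates for the non-conjugate blocks
(vectorized across shoots / levels, which are conditionally independent)
and conjugate inverse-gamma draws for all variance parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from vinedev.inference_core import MCMCConfig, PosteriorSamples, run_mcmc

__all__ = [
    "GrowthParameters",
    "GrowthPosterior",
    "compute_cdd_age",
    "asymptote",
    "mean_length",
    "time_to_fraction",
    "attach_cdd_age",
    "fit_internode_bayes",
    "predict_lengths",
    "internode_pointwise_loglik",
]

INTERNODE_VARIANTS = ("fixed-trt", "fixed-year", "no-fixed", "final")
COEF_NAMES = ("lrc", "m1", "i1", "m2", "i2")


@dataclass(frozen=True)
class GrowthParameters:
    """The non-linear coefficient set of the internode growth curve."""

    lrc: float
    m1: float
    i1: float
    m2: float
    i2: float
    s_r2: float = 0.0
    s_r7: float = 0.0
    s_age: float = 0.0

    def __post_init__(self):
        if self.i1 <= 0 or self.i2 <= 0:
            raise ValueError("asymptote intercepts i1 and i2 must be positive")

    def with_deviations(self, dev: np.ndarray) -> "GrowthParameters":
        """Shift (lrc, m1, i1, m2, i2) by a per-shoot deviation vector."""
        return replace(self, lrc=self.lrc + dev[0], m1=self.m1 + dev[1],
                       i1=self.i1 + dev[2], m2=self.m2 + dev[3], i2=self.i2 + dev[4])


def compute_cdd_age(r_apex, rank, iar: float):
    """Thermal age of an internode: (r_apex - rank + 1) / IAR."""
    r_apex = np.asarray(r_apex)
    rank = np.asarray(rank)
    if iar <= 0:
        raise ValueError("iar must be positive")
    if np.any(rank < 1) or np.any(rank > r_apex):
        raise ValueError("ranks must satisfy 1 <= rank <= r_apex")
    out = (r_apex - rank + 1) / iar
    return float(out) if out.ndim == 0 else out


def _asymptote_arrays(rank, m1, i1, m2, i2, s_r2, s_r7):
    rank = np.asarray(rank)
    g = m1 * ((rank - 1) + (rank == 2) * s_r2 + (rank == 7) * s_r7) + i1
    step = ((rank + 1) % 3) * m2 + i2
    return np.where(rank <= 7, g, step)


def asymptote(rank, params: GrowthParameters):
    """Asymptotic internode length (cm) for a rank or array of ranks."""
    rank = np.asarray(rank)
    if np.any(rank < 1):
        raise ValueError("rank must be >= 1")
    out = _asymptote_arrays(rank, params.m1, params.i1, params.m2, params.i2,
                            params.s_r2, params.s_r7)
    return float(out) if out.ndim == 0 else out


def mean_length(rank, cdd_age, params: GrowthParameters):
    """Expected internode length at a given rank and thermal age."""
    eff = np.asarray(cdd_age, dtype=float) + params.s_age
    if np.any(eff <= 0):
        raise ValueError("effective age cdd_age + s_age must be positive")
    out = asymptote(rank, params) * (1.0 - np.exp(-math.exp(params.lrc) * eff))
    return float(out) if np.ndim(out) == 0 else out


def time_to_fraction(fraction: float, lrc: float) -> float:
    """CDD needed to reach a fraction of the asymptote: -ln(1-q)/exp(lrc).

    Independent of rank because growth speed is shared across ranks.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    return -math.log(1.0 - fraction) / math.exp(lrc)


def attach_cdd_age(observations: pd.DataFrame, iar: float) -> pd.DataFrame:
    """Add the ``cdd_age`` column derived from apex rank and the IAR."""
    df = observations.copy()
    df["cdd_age"] = compute_cdd_age(df["r_apex"].to_numpy(), df["rank"].to_numpy(), iar)
    return df


# ---------------------------------------------------------------------------
# Bayesian calibration


def _factorize(key) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(key, sort=True)
    return codes, len(uniques)


@dataclass
class _Priors:
    centers: dict = field(default_factory=lambda: {
        "lrc": -1.0, "m1": 1.5, "i1": 1.3, "m2": 0.6, "i2": 10.0,
        "s_r2": 0.0, "s_r7": 0.0, "s_age": 0.0})
    scales: dict = field(default_factory=lambda: {
        "lrc": 1.0, "m1": 1.0, "i1": 1.0, "m2": 1.0, "i2": 3.0,
        "s_r2": 0.5, "s_r7": 0.5, "s_age": 0.5})
    # inverse-gamma(2, b) on group-level variances; b = prior-mean variance
    tau_b: dict = field(default_factory=lambda: {
        "lrc": 0.2 ** 2, "m1": 0.2 ** 2, "i1": 0.2 ** 2, "m2": 0.2 ** 2,
        "i2": 1.0 ** 2, "sage": 0.1 ** 2, "shape": 0.3 ** 2})
    a0_center: float = 2.0
    a0_scale: float = 1.0


class InternodeModel:
    """Model specification with its own Metropolis-within-Gibbs sampler."""

    def __init__(self, df: pd.DataFrame, variant: str = "final",
                 priors: _Priors | None = None, store_group_effects: bool = True):
        if variant not in INTERNODE_VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {INTERNODE_VARIANTS}")
        self.variant = variant
        self.priors = priors or _Priors()
        self.store_group_effects = store_group_effects

        self.y = df["length_cm"].to_numpy(dtype=float)
        if np.any(self.y <= 0):
            raise ValueError("internode lengths must be positive")
        self.logy = np.log(self.y)
        self.rank = df["rank"].to_numpy(dtype=int)
        self.age = df["cdd_age"].to_numpy(dtype=float)
        self.n = len(df)

        ring = df["ring"].astype(str)
        plant = ring + "/" + df["plant"].astype(str)
        shoot = plant + "/" + df["shoot"].astype(str) + "@" + df["year"].astype(str)
        shoot_date = shoot + ":" + df["doy"].astype(str)
        self.shoot_idx, self.n_shoot = _factorize(shoot)
        self.shoot_labels = pd.factorize(shoot, sort=True)[1]
        self.sd_idx, self.n_sd = _factorize(shoot_date)
        # level index for the five coefficients: none (shared), trt or year
        if variant == "fixed-trt":
            self.level_idx, self.n_level = _factorize(df["trt"])
            self.level_names = list(pd.factorize(df["trt"], sort=True)[1])
        elif variant == "fixed-year":
            self.level_idx, self.n_level = _factorize(df["year"])
            self.level_names = [str(v) for v in pd.factorize(df["year"], sort=True)[1]]
        else:
            self.level_idx, self.n_level = np.zeros(self.n, dtype=int), 1
            self.level_names = [""]

        shape_factors = {"rank": df["rank"], "ring": ring, "plant": plant, "shoot": shoot}
        if variant != "final":  # final drops year from the shape heterogeneity
            shape_factors["year"] = df["year"].astype(str)
        self.shape_idx = {}
        self.shape_sizes = {}
        for name, key in shape_factors.items():
            idx, k = _factorize(key)
            self.shape_idx[name] = idx
            self.shape_sizes[name] = k

    # -- likelihood pieces -------------------------------------------------
    def _mu(self, coefs, u, v):
        """Per-row Gamma mean; coefs is (n_level, 5) + the 3 shared params."""
        lev = self.level_idx
        si = self.shoot_idx
        lrc = coefs["five"][lev, 0] + u[si, 0]
        m1 = coefs["five"][lev, 1] + u[si, 1]
        i1 = coefs["five"][lev, 2] + u[si, 2]
        m2 = coefs["five"][lev, 3] + u[si, 3]
        i2 = coefs["five"][lev, 4] + u[si, 4]
        A = np.where(self.rank <= 7,
                     m1 * ((self.rank - 1) + (self.rank == 2) * coefs["s_r2"]
                           + (self.rank == 7) * coefs["s_r7"]) + i1,
                     ((self.rank + 1) % 3) * m2 + i2)
        eff = self.age + coefs["s_age"] + v[self.sd_idx]
        bad = (A <= 0) | (eff <= 0)
        mu = A * (1.0 - np.exp(-np.exp(lrc) * np.maximum(eff, 1e-12)))
        return mu, bad

    def _row_loglik(self, mu, bad, log_alpha):
        alpha = np.exp(log_alpha)
        ll = np.where(bad | (mu <= 0), -np.inf,
                      alpha * (log_alpha - np.log(np.maximum(mu, 1e-300)))
                      - gammaln(alpha) + (alpha - 1.0) * self.logy
                      - alpha * self.y / np.maximum(mu, 1e-300))
        return ll

    def _log_alpha(self, a0, effects):
        la = np.full(self.n, a0)
        for name, e in effects.items():
            la = la + e[self.shape_idx[name]]
        return la

    def _fixed_vector(self, coefs):
        return np.concatenate([coefs["five"].ravel(),
                               [coefs["s_r2"], coefs["s_r7"], coefs["s_age"]]])

    def _unpack_fixed(self, vec):
        k = self.n_level * 5
        return {"five": vec[:k].reshape(self.n_level, 5),
                "s_r2": vec[k], "s_r7": vec[k + 1], "s_age": vec[k + 2]}

    def _fixed_logprior(self, vec):
        pr = self.priors
        k = self.n_level * 5
        five = vec[:k].reshape(self.n_level, 5)
        lp = 0.0
        for c, nm in enumerate(COEF_NAMES):
            lp += -0.5 * np.sum((five[:, c] - pr.centers[nm]) ** 2) / pr.scales[nm] ** 2
        for j, nm in enumerate(("s_r2", "s_r7", "s_age")):
            lp += -0.5 * (vec[k + j] - pr.centers[nm]) ** 2 / pr.scales[nm] ** 2
        return lp

    # -- sampler -----------------------------------------------------------
    def _run_chain(self, n_iter, keep_from, rng):
        pr = self.priors
        coefs = {"five": np.tile([pr.centers[nm] for nm in COEF_NAMES], (self.n_level, 1)),
                 "s_r2": -0.2, "s_r7": -0.1, "s_age": -0.1}
        u = np.zeros((self.n_shoot, 5))
        tau2 = np.array([pr.tau_b[nm] for nm in COEF_NAMES])
        v = np.zeros(self.n_sd)
        tau2_sage = pr.tau_b["sage"]
        a0 = pr.a0_center
        effects = {nm: np.zeros(k) for nm, k in self.shape_sizes.items()}
        sd2_shape = {nm: pr.tau_b["shape"] for nm in effects}

        nfix = self.n_level * 5 + 3
        prop_cov = np.diag(np.full(nfix, 1e-3))
        prop_scale = 1.0
        hist = []
        acc_fix = 0
        u_scales = np.array([0.1, 0.1, 0.1, 0.1, 0.3])
        v_scale = 0.05
        a0_scale = 0.1
        e_scales = {nm: 0.1 for nm in effects}

        mu, bad = self._mu(coefs, u, v)
        la = self._log_alpha(a0, effects)
        ll = self._row_loglik(mu, bad, la)

        n_kept = n_iter - keep_from
        store = {"fixed": np.empty((n_kept, nfix)),
                 "tau": np.empty((n_kept, 5)),
                 "tau_sage": np.empty(n_kept),
                 "a0": np.empty(n_kept),
                 "sd_shape": {nm: np.empty(n_kept) for nm in effects}}
        if self.store_group_effects:
            store["u"] = np.empty((n_kept, self.n_shoot, 5))

        for it in range(n_iter):
            # 1) fixed coefficients: adaptive multivariate random walk
            vec = self._fixed_vector(coefs)
            cur_lp = ll.sum() + self._fixed_logprior(vec)
            prop = rng.multivariate_normal(vec, prop_scale * prop_cov, method="cholesky")
            coefs_p = self._unpack_fixed(prop)
            mu_p, bad_p = self._mu(coefs_p, u, v)
            ll_p = self._row_loglik(mu_p, bad_p, la)
            new_lp = ll_p.sum() + self._fixed_logprior(prop)
            if np.log(rng.uniform()) < new_lp - cur_lp:
                coefs, mu, bad, ll = coefs_p, mu_p, bad_p, ll_p
                acc_fix += 1
            if it < keep_from:
                hist.append(self._fixed_vector(coefs))
                if it % 100 == 99 and len(hist) > 2 * nfix:
                    h = np.asarray(hist[len(hist) // 2:])
                    prop_cov = (2.38 ** 2 / nfix) * np.cov(h.T) + 1e-9 * np.eye(nfix)
                    rate = acc_fix / (it + 1)
                    prop_scale = float(np.clip(prop_scale * np.exp(rate - 0.25), 0.05, 20))

            # 2) per-shoot deviations, one coefficient column at a time
            for c in range(5):
                u_p = u.copy()
                u_p[:, c] = u[:, c] + u_scales[c] * rng.standard_normal(self.n_shoot)
                mu_p, bad_p = self._mu(coefs, u_p, v)
                ll_p = self._row_loglik(mu_p, bad_p, la)
                d_ll = np.bincount(self.shoot_idx, ll_p - ll, minlength=self.n_shoot)
                d_prior = -0.5 * (u_p[:, c] ** 2 - u[:, c] ** 2) / tau2[c]
                accept = np.log(rng.uniform(size=self.n_shoot)) < d_ll + d_prior
                if accept.any():
                    u[accept, c] = u_p[accept, c]
                    mu, bad = self._mu(coefs, u, v)
                    ll = self._row_loglik(mu, bad, la)
                if it < keep_from:
                    rate = accept.mean()
                    u_scales[c] = float(np.clip(u_scales[c] * np.exp(0.05 * (rate - 0.44)),
                                                1e-4, 5.0))
            for c in range(5):
                tau2[c] = 1.0 / rng.gamma(2.0 + self.n_shoot / 2.0,
                                          1.0 / (pr.tau_b[COEF_NAMES[c]]
                                                 + 0.5 * np.sum(u[:, c] ** 2)))

            # 3) shoot-by-date age deviations
            v_p = v + v_scale * rng.standard_normal(self.n_sd)
            mu_p, bad_p = self._mu(coefs, u, v_p)
            ll_p = self._row_loglik(mu_p, bad_p, la)
            d_ll = np.bincount(self.sd_idx, ll_p - ll, minlength=self.n_sd)
            d_prior = -0.5 * (v_p ** 2 - v ** 2) / tau2_sage
            accept = np.log(rng.uniform(size=self.n_sd)) < d_ll + d_prior
            if accept.any():
                v[accept] = v_p[accept]
                mu, bad = self._mu(coefs, u, v)
                ll = self._row_loglik(mu, bad, la)
            if it < keep_from:
                v_scale = float(np.clip(v_scale * np.exp(0.05 * (accept.mean() - 0.44)),
                                        1e-4, 2.0))
            tau2_sage = 1.0 / rng.gamma(2.0 + self.n_sd / 2.0,
                                        1.0 / (pr.tau_b["sage"] + 0.5 * np.sum(v ** 2)))

            # 4) baseline log shape
            a0_p = a0 + a0_scale * rng.standard_normal()
            la_p = self._log_alpha(a0_p, effects)
            ll_p = self._row_loglik(mu, bad, la_p)
            d = (ll_p.sum() - ll.sum()
                 - 0.5 * ((a0_p - pr.a0_center) ** 2 - (a0 - pr.a0_center) ** 2)
                 / pr.a0_scale ** 2)
            if np.log(rng.uniform()) < d:
                a0, la, ll = a0_p, la_p, ll_p

            # 5) shape heterogeneity per factor
            for nm, e in effects.items():
                idx = self.shape_idx[nm]
                e_p = e + e_scales[nm] * rng.standard_normal(len(e))
                la_p = self._log_alpha(a0, {**effects, nm: e_p})
                ll_p = self._row_loglik(mu, bad, la_p)
                d_ll = np.bincount(idx, ll_p - ll, minlength=len(e))
                d_prior = -0.5 * (e_p ** 2 - e ** 2) / sd2_shape[nm]
                accept = np.log(rng.uniform(size=len(e))) < d_ll + d_prior
                if accept.any():
                    effects[nm][accept] = e_p[accept]
                    la = self._log_alpha(a0, effects)
                    ll = self._row_loglik(mu, bad, la)
                if it < keep_from:
                    e_scales[nm] = float(np.clip(
                        e_scales[nm] * np.exp(0.05 * (accept.mean() - 0.44)), 1e-4, 2.0))
                sd2_shape[nm] = 1.0 / rng.gamma(
                    2.0 + len(e) / 2.0,
                    1.0 / (pr.tau_b["shape"] + 0.5 * np.sum(effects[nm] ** 2)))

            if it >= keep_from:
                j = it - keep_from
                store["fixed"][j] = self._fixed_vector(coefs)
                store["tau"][j] = np.sqrt(tau2)
                store["tau_sage"][j] = math.sqrt(tau2_sage)
                store["a0"][j] = a0
                for nm in effects:
                    store["sd_shape"][nm][j] = math.sqrt(sd2_shape[nm])
                if self.store_group_effects:
                    store["u"][j] = u

        out = {}
        k = 0
        for lev in range(self.n_level):
            suffix = f"_{self.level_names[lev]}" if self.n_level > 1 else ""
            for c, nm in enumerate(COEF_NAMES):
                out[nm + suffix] = store["fixed"][:, lev * 5 + c]
        k = self.n_level * 5
        out["s_r2"] = store["fixed"][:, k]
        out["s_r7"] = store["fixed"][:, k + 1]
        out["s_age"] = store["fixed"][:, k + 2]
        for c, nm in enumerate(COEF_NAMES):
            out[f"sd_shoot_{nm}"] = store["tau"][:, c]
        out["sd_sage_slope"] = store["tau_sage"]
        out["shape_log"] = store["a0"]
        for nm in store["sd_shape"]:
            out[f"sd_shape_{nm}"] = store["sd_shape"][nm]
        if self.store_group_effects:
            for s in range(self.n_shoot):
                for c, nm in enumerate(COEF_NAMES):
                    out[f"u[{self.shoot_labels[s]}]_{nm}"] = store["u"][:, s, c]
        return out

    def sample(self, config: MCMCConfig, rng) -> dict[str, np.ndarray]:
        seeds = rng.integers(2**31, size=config.n_chains)
        chains = [self._run_chain(config.n_warmup + config.n_kept, config.n_warmup,
                                  np.random.default_rng(int(s))) for s in seeds]
        return {name: np.stack([c[name] for c in chains]) for name in chains[0]}


@dataclass
class GrowthPosterior:
    """Posterior over the growth coefficients, group SDs and shape structure."""

    variant: str
    draws: PosteriorSamples
    shoot_labels: list[str]
    level_names: list[str]

    def point_estimate(self, level: str = "") -> GrowthParameters:
        suffix = f"_{level}" if level else ""
        d = self.draws
        return GrowthParameters(
            lrc=float(d.draws("lrc" + suffix).mean()),
            m1=float(d.draws("m1" + suffix).mean()),
            i1=float(d.draws("i1" + suffix).mean()),
            m2=float(d.draws("m2" + suffix).mean()),
            i2=float(d.draws("i2" + suffix).mean()),
            s_r2=float(d.draws("s_r2").mean()),
            s_r7=float(d.draws("s_r7").mean()),
            s_age=float(d.draws("s_age").mean()),
        )

    def parameter_draw(self, i: int, level: str = "") -> GrowthParameters:
        """One joint posterior draw of the seven simulation coefficients."""
        suffix = f"_{level}" if level else ""
        d = self.draws
        flat = {nm: d.draws(nm + suffix)[i] for nm in COEF_NAMES}
        return GrowthParameters(lrc=flat["lrc"], m1=flat["m1"], i1=max(flat["i1"], 1e-6),
                                m2=flat["m2"], i2=max(flat["i2"], 1e-6),
                                s_r2=d.draws("s_r2")[i], s_r7=d.draws("s_r7")[i],
                                s_age=d.draws("s_age")[i])

    def group_sds(self, i: int) -> np.ndarray:
        d = self.draws
        return np.array([d.draws(f"sd_shoot_{nm}")[i] for nm in COEF_NAMES])


def fit_internode_bayes(observations: pd.DataFrame, variant: str = "final",
                        config: MCMCConfig | None = None, iar: float | None = None,
                        store_group_effects: bool = True,
                        require_convergence: bool = False) -> GrowthPosterior:
    """Fit one internode-model variant by Metropolis-within-Gibbs.

    ``observations`` needs a ``cdd_age`` column or an ``iar`` to derive it.
    """
    df = observations
    if "cdd_age" not in df.columns:
        if iar is None:
            raise ValueError("provide a cdd_age column or an iar to derive it")
        df = attach_cdd_age(df, iar)
    model = InternodeModel(df, variant=variant, store_group_effects=store_group_effects)
    draws = run_mcmc(model, config)
    if require_convergence and not draws.converged:
        raise RuntimeError("internode posterior failed convergence diagnostics "
                           f"(max Rhat {draws.diagnostics['rhat'].max():.3f})")
    return GrowthPosterior(variant=variant, draws=draws,
                           shoot_labels=list(model.shoot_labels),
                           level_names=model.level_names)


def _prediction_mu(posterior: GrowthPosterior, df: pd.DataFrame, idx: np.ndarray,
                   use_group_effects: bool) -> np.ndarray:
    d = posterior.draws
    rank = df["rank"].to_numpy(dtype=int)
    age = df["cdd_age"].to_numpy(dtype=float)
    if posterior.level_names != [""]:
        raise ValueError("pointwise prediction is defined for the shared-coefficient "
                         "(final / no-fixed) variants")
    if use_group_effects:
        ring = df["ring"].astype(str)
        labels = (ring + "/" + df["plant"].astype(str) + "/" + df["shoot"].astype(str)
                  + "@" + df["year"].astype(str))
        known = set(posterior.shoot_labels)
        unknown = sorted(set(labels) - known)
        if unknown:
            raise KeyError(f"no group-level effects for shoot(s) {unknown[:3]}; "
                           "predict held-out data with use_group_effects=False")
        lab_list = list(labels)
    mus = np.empty((len(idx), len(df)))
    for j, i in enumerate(idx):
        base = {nm: d.draws(nm)[i] for nm in COEF_NAMES}
        s_r2, s_r7, s_age = d.draws("s_r2")[i], d.draws("s_r7")[i], d.draws("s_age")[i]
        if use_group_effects:
            devs = np.array([[d.draws(f"u[{lab}]_{nm}")[i] for nm in COEF_NAMES]
                             for lab in lab_list])
        else:
            devs = np.zeros((len(df), 5))
        A = _asymptote_arrays(rank, base["m1"] + devs[:, 1], base["i1"] + devs[:, 2],
                              base["m2"] + devs[:, 3], base["i2"] + devs[:, 4], s_r2, s_r7)
        eff = np.maximum(age + s_age, 1e-9)
        mus[j] = np.maximum(A, 1e-9) * (1.0 - np.exp(-np.exp(base["lrc"] + devs[:, 0]) * eff))
    return mus


def predict_lengths(posterior: GrowthPosterior, new_observations: pd.DataFrame,
                    use_group_effects: bool = False, n_draws: int = 400,
                    seed: int = 0, include_noise: bool = True) -> pd.DataFrame:
    """Pointwise predictive summaries and error metrics for new internodes.

    Held-out shoots have no estimated group-level effects, so test-data
    prediction must leave them out (an unknown shoot raises).  Returns a
    frame with predictive mean and quantiles; rmse/mae/bias against
    ``length_cm`` are stored in ``.attrs['metrics']`` when lengths are given.
    """
    from vinedev.inference_core import error_metrics

    rng = np.random.default_rng(seed)
    d = posterior.draws
    total = d.n_chains * d.n_kept
    idx = rng.choice(total, size=min(n_draws, total), replace=False)
    mus = _prediction_mu(posterior, new_observations, idx, use_group_effects)
    if include_noise:
        alpha = np.exp(d.draws("shape_log")[idx])[:, None]
        pred = rng.gamma(alpha, mus / alpha)
    else:
        pred = mus
    out = pd.DataFrame({
        "mean": mus.mean(axis=0),
        "q2.5": np.quantile(pred, 0.025, axis=0),
        "q25": np.quantile(pred, 0.25, axis=0),
        "q75": np.quantile(pred, 0.75, axis=0),
        "q97.5": np.quantile(pred, 0.975, axis=0),
    }, index=new_observations.index)
    if "length_cm" in new_observations:
        y = new_observations["length_cm"].to_numpy(dtype=float)
        out.attrs["metrics"] = {k: error_metrics(y, out["mean"].to_numpy(), k)
                                for k in ("rmse", "mae", "bias")}
    return out


def internode_pointwise_loglik(posterior: GrowthPosterior, observations: pd.DataFrame,
                               n_draws: int = 400, seed: int = 0) -> np.ndarray:
    """Draws x observations Gamma log-likelihood (fixed effects + base shape),
    the common footing on which the variant ladder is compared by PSIS-LOO."""
    rng = np.random.default_rng(seed)
    d = posterior.draws
    total = d.n_chains * d.n_kept
    idx = rng.choice(total, size=min(n_draws, total), replace=False)
    mus = _prediction_mu(posterior, observations, idx, use_group_effects=False)
    y = observations["length_cm"].to_numpy(dtype=float)
    alpha = np.exp(d.draws("shape_log")[idx])[:, None]
    mus = np.maximum(mus, 1e-9)
    return (alpha * (np.log(alpha) - np.log(mus)) - gammaln(alpha)
            + (alpha - 1.0) * np.log(y)[None, :] - alpha * y[None, :] / mus)
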