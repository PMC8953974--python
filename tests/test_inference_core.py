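"""Inference toolbox: MCMC contract, pd, PSIS-LOO, HDI, splitting, metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vinedev.inference_core import (
    HierarchicalLinearModel,
    MCMCConfig,
    PosteriorSamples,
    blocked_split,
    error_metrics,
    hdi,
    hdi_discrete,
    probability_of_direction,
    psis_loo,
    run_mcmc,
)


class _ConjugateNormalMean:
    """y_i ~ N(mu, s2) with mu ~ N(0, t2): posterior in closed form."""

    param_names = ["mu"]

    def __init__(self, y, s2=1.0, t2=100.0):
        self.y, self.s2, self.t2 = np.asarray(y), s2, t2
        n = len(y)
        self.post_var = 1.0 / (n / s2 + 1.0 / t2)
        self.post_mean = self.post_var * self.y.sum() / s2

    def initial(self):
        return np.array([self.y.mean()])

    def log_posterior(self, theta):
        mu = theta[0]
        return (-0.5 * np.sum((self.y - mu) ** 2) / self.s2
                - 0.5 * mu**2 / self.t2)


class TestRunMCMC:
    def test_default_config_yields_4x2000_draws(self):
        y = np.random.default_rng(0).normal(1.0, 1.0, 30)
        post = run_mcmc(_ConjugateNormalMean(y), MCMCConfig(seed=1, n_warmup=200))
        assert post.n_chains == 4 and post.n_kept == 2000
        assert post.parameters["mu"].shape == (4, 2000)

    def test_conjugate_posterior_recovered(self):
        y = np.random.default_rng(1).normal(2.0, 1.0, 50)
        m = _ConjugateNormalMean(y)
        post = run_mcmc(m, MCMCConfig(n_chains=4, n_warmup=500, n_kept=500, seed=2))
        draws = post.draws("mu")
        mcse = draws.std() / np.sqrt(post.diagnostics.loc["mu", "ess"])
        assert abs(draws.mean() - m.post_mean) < 3 * max(mcse, 1e-3)
        assert draws.std() == pytest.approx(np.sqrt(m.post_var), rel=0.2)

    def test_identical_seed_identical_draws(self):
        y = np.random.default_rng(2).normal(size=20)
        cfg = MCMCConfig(n_chains=2, n_warmup=100, n_kept=100, seed=5)
        a = run_mcmc(_ConjugateNormalMean(y), cfg)
        b = run_mcmc(_ConjugateNormalMean(y), cfg)
        assert np.array_equal(a.parameters["mu"], b.parameters["mu"])

    def test_nonfinite_initialization_raises(self):
        from vinedev.inference_core import InitializationError

        class Bad(_ConjugateNormalMean):
            def initial(self):
                return np.array([np.nan])

        with pytest.raises(InitializationError):
            run_mcmc(Bad(np.ones(5)), MCMCConfig(n_warmup=10, n_kept=10))

    def test_noise_free_regression_concentrates_at_truth(self):
        # ordinary-least-squares oracle: exact slope on noise-free data
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 40)
        y = 0.5 + 2.0 * x
        X = np.column_stack([np.ones_like(x), x])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]

        class Reg:
            param_names = ["b0", "b1"]

            def initial(self):
                return np.zeros(2)

            def log_posterior(self, theta):
                r = y - X @ theta
                return -0.5 * np.sum(r**2) / 1e-4 - 0.5 * theta @ theta / 1e4

        post = run_mcmc(Reg(), MCMCConfig(n_chains=2, n_warmup=2000, n_kept=1000, seed=4))
        assert ols[1] == pytest.approx(2.0, abs=1e-9)
        assert post.draws("b1").mean() == pytest.approx(ols[1], abs=1e-2)


class TestGibbsHierarchical:
    def test_gaussian_mixed_model_recovery(self):
        rng = np.random.default_rng(10)
        n, g = 300, 12
        x = rng.uniform(0, 10, n)
        grp = rng.integers(0, g, n)
        u = rng.normal(0, 1.2, g)
        y = 1.0 + 2.5 * x + u[grp] + rng.normal(0, 0.7, n)
        model = HierarchicalLinearModel(
            y, np.column_stack([np.ones(n), x]), ["intercept", "slope"],
            [("grp", np.eye(g)[grp])])
        post = run_mcmc(model, MCMCConfig(2, 500, 500, seed=1))
        slope = post.draws("slope")
        assert abs(slope.mean() - 2.5) < 3 * slope.std()
        assert post.draws("sd_grp").mean() == pytest.approx(1.2, rel=0.5)
        assert post.draws("sigma").mean() == pytest.approx(0.7, rel=0.2)

    def test_exgaussian_mean_decomposition(self):
        # response = location + Exp(beta): fitted location stays comparable
        rng = np.random.default_rng(11)
        n = 400
        x = rng.uniform(0, 10, n)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.8, n) + rng.exponential(1.5, n)
        model = HierarchicalLinearModel(
            y, np.column_stack([np.ones(n), x]), ["intercept", "slope"],
            likelihood="exgaussian")
        post = run_mcmc(model, MCMCConfig(2, 800, 800, seed=2))
        assert post.draws("slope").mean() == pytest.approx(2.0, abs=0.06)
        total_mean = post.draws("intercept") + post.draws("beta_exg")
        assert total_mean.mean() == pytest.approx(2.5, abs=0.4)


class TestProbabilityOfDirection:
    def test_reference_fractions(self):
        assert probability_of_direction(np.ones(10)) == 100.0
        assert probability_of_direction(np.r_[np.ones(5), -np.ones(5)]) == 50.0
        draws = np.r_[np.ones(975), -np.ones(25)]
        assert probability_of_direction(draws) == 97.5

    def test_zeros_count_toward_neither_side(self):
        assert probability_of_direction([1.0, 1.0, 0.0, -1.0]) == 50.0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10**6), st.floats(0.1, 100.0))
    def test_scale_invariance_and_sign_flip(self, seed, scale):
        rng = np.random.default_rng(seed)
        draws = rng.normal(0.3, 1.0, 200)
        p = probability_of_direction(draws)
        assert probability_of_direction(scale * draws) == p
        # sign flip swaps the directional fractions, leaving the maximum as is
        assert probability_of_direction(-draws) == p
        frac_pos = np.mean(draws > 0)
        assert np.mean(-draws < 0) == pytest.approx(frac_pos)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            probability_of_direction([1.0])


class TestPsisLoo:
    def test_constant_loglik_single_observation(self):
        c = -1.37
        out = psis_loo(np.full((200, 1), c))
        assert out.elpd == pytest.approx(c, abs=1e-9)
        assert out.looic == pytest.approx(-2 * c, abs=1e-9)

    def test_matches_exact_loo_of_conjugate_model(self):
        # independent oracle: exact leave-one-out refits of a conjugate
        # normal-mean model give the LOO predictive density in closed form
        rng = np.random.default_rng(5)
        y = rng.normal(0.5, 1.0, 40)
        s2, t2 = 1.0, 4.0
        mu = run_mcmc(_ConjugateNormalMean(y, s2, t2),
                      MCMCConfig(4, 500, 1000, seed=6)).draws("mu")
        ll = stats.norm.logpdf(y[None, :], loc=mu[:, None], scale=np.sqrt(s2))
        est = psis_loo(ll)

        exact = 0.0
        for i in range(len(y)):
            rest = np.delete(y, i)
            v = 1.0 / (len(rest) / s2 + 1.0 / t2)
            m = v * rest.sum() / s2
            exact += stats.norm.logpdf(y[i], loc=m, scale=np.sqrt(v + s2))
        assert est.elpd == pytest.approx(exact, abs=0.1)

    def test_additive_over_duplicated_data(self):
        rng = np.random.default_rng(6)
        ll = rng.normal(-1.0, 0.1, size=(300, 15))
        single = psis_loo(ll)
        double = psis_loo(np.hstack([ll, ll]))
        assert double.looic == pytest.approx(2 * single.looic, abs=2 * single.se + 1e-6)

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        ll = rng.normal(-2.0, 0.3, size=(200, 20))
        perm = rng.permutation(20)
        assert psis_loo(ll).elpd == pytest.approx(psis_loo(ll[:, perm]).elpd, abs=1e-9)

    def test_nonfinite_entries_rejected(self):
        ll = np.zeros((10, 3))
        ll[0, 0] = np.inf
        with pytest.raises(ValueError):
            psis_loo(ll)


class TestHDI:
    def test_standard_normal_central_interval(self):
        draws = np.random.default_rng(8).standard_normal(100_000)
        (lo, hi), = hdi(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.1)
        assert hi == pytest.approx(1.96, abs=0.1)

    def test_two_point_pmf_keeps_gap(self):
        out = hdi_discrete([10, 20], [0.5, 0.5], 0.95)
        assert out == [(10, 10), (20, 20)]

    def test_discrete_matches_exhaustive_subset_search(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            k = rng.integers(4, 12)
            p = rng.dirichlet(np.ones(k))
            support = np.sort(rng.choice(np.arange(100, 200), size=k, replace=False))
            got = hdi_discrete(support, p, 0.9)
            got_points = {int(v) for lo, hi in got
                          for v in support[(support >= lo) & (support <= hi)]}
            # brute force: smallest subset with mass >= 0.9
            best = None
            for size in range(1, k + 1):
                candidates = [set(c) for c in itertools.combinations(range(k), size)
                              if sum(p[j] for j in c) >= 0.9]
                if candidates:
                    best = max(candidates, key=lambda c: sum(p[j] for j in c))
                    break
            assert len(got_points) == len(best)
            assert sum(p[list(best)]) <= sum(
                p[j] for j in range(k) if int(support[j]) in got_points) + 1e-12

    def test_mass_monotonicity_unimodal(self):
        draws = np.random.default_rng(10).normal(5.0, 2.0, 50_000)
        (l50, h50), = hdi(draws, 0.5)
        (l95, h95), = hdi(draws, 0.95)
        assert l95 <= l50 and h50 <= h95

    def test_full_mass_covers_support(self):
        draws = np.array([1, 2, 2, 3, 7, 7, 9] * 10)
        out = hdi(draws, 0.999, discrete=True)
        covered = {v for lo, hi in out for v in range(lo, hi + 1)}
        assert {1, 2, 3, 7, 9} <= covered

    def test_few_draws_warn(self):
        with pytest.warns(UserWarning):
            hdi(np.arange(5, dtype=float), 0.9)


class TestBlockedSplit:
    @staticmethod
    def _records(n_units=10, rows_per_unit=6, n_strata=2, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_strata):
            for u in range(n_units):
                for r in range(rows_per_unit):
                    rows.append({"year": 2018 + s, "trt": "aCO2",
                                 "unit": f"y{s}u{u}", "val": rng.normal()})
        return pd.DataFrame(rows)

    def test_equal_units_meet_ratio_exactly(self):
        df = self._records()
        plan = blocked_split(df, ["year", "trt"], "unit", 0.8, seed=1)
        per_stratum = df.groupby("year")["unit"].nunique()
        for year in per_stratum.index:
            units = set(df[df["year"] == year]["unit"])
            assert len(units & plan.train_ids) == 8
            assert len(units & plan.test_ids) == 2

    def test_units_stay_whole_and_partition(self):
        df = self._records(seed=2)
        plan = blocked_split(df, ["year", "trt"], "unit", 0.8, seed=3)
        assert plan.train_ids.isdisjoint(plan.test_ids)
        assert plan.train_ids | plan.test_ids == set(df["unit"])
        mask = plan.mask(df, "unit")
        for _, g in df.groupby("unit"):
            vals = mask[g.index]
            assert vals.all() or not vals.any()

    def test_achieved_ratio_within_five_points(self):
        rng = np.random.default_rng(4)
        rows = []
        for u in range(100):
            for _ in range(int(rng.integers(2, 12))):
                rows.append({"year": 2018, "trt": "e" if u % 2 else "a", "unit": u})
        df = pd.DataFrame(rows)
        plan = blocked_split(df, ["year", "trt"], "unit", 0.8, seed=5)
        assert abs(plan.achieved_ratio - 0.8) < 0.05

    def test_reproducible_bit_exact(self):
        df = self._records(seed=6)
        a = blocked_split(df, ["year"], "unit", 0.8, seed=9)
        b = blocked_split(df, ["year"], "unit", 0.8, seed=9)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_single_unit_stratum_goes_to_training(self):
        df = pd.DataFrame({"year": [2018] * 3, "trt": ["a"] * 3, "unit": ["only"] * 3})
        with pytest.warns(UserWarning):
            plan = blocked_split(df, ["year", "trt"], "unit", 0.8, seed=1)
        assert plan.train_ids == {"only"}


class TestErrorMetrics:
    def test_hand_arithmetic(self):
        obs, pred = [2.0, 4.0], [3.0, 5.0]
        assert error_metrics(obs, pred, "rmse") == pytest.approx(1.0)
        assert error_metrics(obs, pred, "nrmse") == pytest.approx(1.0 / 3.0)
        assert error_metrics(obs, pred, "bias") == pytest.approx(1.0)
        assert error_metrics(obs, obs, "mae") == 0.0

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10**6))
    def test_matches_naive_loops(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.uniform(1, 10, 23)
        pred = obs + rng.normal(0, 1, 23)
        rmse = (sum((o - p) ** 2 for o, p in zip(obs, pred)) / 23) ** 0.5
        assert error_metrics(obs, pred, "rmse") == pytest.approx(rmse, abs=1e-12)
        assert error_metrics(obs, pred, "nrmse") == pytest.approx(
            rmse / (sum(obs) / 23), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            error_metrics([1.0], [1.0, 2.0])


class TestPosteriorSamplesRoundTrip:
    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(12)
        ps = PosteriorSamples({"a": rng.normal(size=(2, 50)),
                               "b": rng.normal(size=(2, 50))}, 2, 50)
        path = tmp_path / "post.csv"
        ps.to_csv(path)
        back = PosteriorSamples.from_csv(path)
        for k in ("a", "b"):
            assert np.allclose(back.parameters[k], ps.parameters[k])
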