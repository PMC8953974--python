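"""Grid enumeration, objectives, thresholds and weighted-sum Pareto voting."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vinedev.cardinal_optimization import (
    GridSpec,
    ObjectiveSet,
    Thresholds,
    WeatherCache,
    coarse_grid_paper,
    delta_odr,
    evaluate_triplet,
    generate_grid,
    minmax_normalize,
    pareto_select,
    refined_grid_around,
    threshold_filter,
    weight_lattice,
)
from vinedev.thermal_time import CardinalTemperatures


class TestGridGeneration:
    def test_refined_grid_adds_6858_new_triplets(self):
        # 0.1 degree steps over +-0.9 around (11, 19, 25): 19^3 = 6859
        # triplets, all constraint-satisfying, one of which (the centre)
        # already sits on the integer coarse grid
        spec = refined_grid_around(CardinalTemperatures(11.0, 19.0, 25.0))
        refined = generate_grid(spec)
        assert len(refined) == 6859
        coarse = {(float(tb), float(to), float(tu))
                  for tb, to, tu in itertools.product(range(-60, 16), range(10, 36),
                                                      range(15, 56))
                  if tb <= to - 2 and to <= tu - 2}
        new = [ct for ct in refined if ct.as_tuple() not in coarse]
        assert len(new) == 6858

    def test_equality_constraint_boundary(self):
        grid = generate_grid(GridSpec((0,), (2,), (4,)))
        assert len(grid) == 1  # both constraints met with equality

    def test_tiny_ranges_match_triple_loop_oracle(self):
        spec = GridSpec((8, 9, 10), (10, 11, 12, 13), (12, 13, 14, 15))
        count = sum(1 for tb, to, tu in itertools.product(spec.t_base_values,
                                                          spec.t_opt_values,
                                                          spec.t_upper_values)
                    if tb <= to - 2 and to <= tu - 2)
        grid = generate_grid(spec)
        assert len(grid) == count
        assert len(set(grid)) == len(grid)  # duplicate-free

    def test_empty_grid_is_configuration_error(self):
        with pytest.raises(ValueError):
            generate_grid(GridSpec((10,), (11,), (12,)))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10**6))
    def test_random_specs_satisfy_constraints(self, seed):
        rng = np.random.default_rng(seed)
        tb = np.sort(rng.choice(np.arange(-10, 16), 4, replace=False)).astype(float)
        to = np.sort(rng.choice(np.arange(10, 30), 4, replace=False)).astype(float)
        tu = np.sort(rng.choice(np.arange(15, 45), 4, replace=False)).astype(float)
        try:
            grid = generate_grid(GridSpec(tuple(tb), tuple(to), tuple(tu)))
        except ValueError:
            return  # legitimately empty
        for ct in grid:
            assert ct.t_base <= ct.t_opt - 2 and ct.t_opt <= ct.t_upper - 2
        assert len(set(grid)) == len(grid)

    def test_paper_scale_coarse_grid_enumerates(self):
        grid = generate_grid(coarse_grid_paper())
        # closed-form count: sum over t_opt of (#t_base <= t_opt-2) x
        # (#t_upper >= t_opt+2) = 41*(69+70+71+72) + (73*40+74*39+75*38+76*37)
        # + 76*(36+35+...+19) = 60,650
        assert len(grid) == 60650


class TestDeltaODR:
    def test_zero_when_rates_agree(self):
        assert delta_odr(1.285, 1.285, 1 / 1.285, 1 / 1.285) == pytest.approx(0.0)

    def test_hand_value(self):
        # |1.5 - 1.0| / 1.25 = 0.4 in both treatments
        assert delta_odr(1.0, 1.0, 1 / 1.5, 1 / 1.5) == pytest.approx(0.4)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.5, 3.0), st.floats(0.5, 3.0), st.floats(0.3, 2.0),
           st.floats(0.3, 2.0))
    def test_symmetry_and_scale_invariance(self, lar_a, lar_e, iar_a, iar_e):
        d = delta_odr(lar_a, lar_e, iar_a, iar_e)
        swapped = delta_odr(1 / iar_a, 1 / iar_e, 1 / lar_a, 1 / lar_e)
        assert d == pytest.approx(swapped, rel=1e-9)
        c = 1.7
        assert delta_odr(c * lar_a, c * lar_e, iar_a / c, iar_e / c) == \
            pytest.approx(d, rel=1e-9)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            delta_odr(0.0, 1.0, 1.0, 1.0)


def _objset(**kw):
    base = dict(delta_odr=0.01, e_year_phen=0.01, e_year_apex=0.01,
                nrmse_train_phen=0.1, nrmse_test_phen=0.11,
                nrmse_train_apex=0.1, nrmse_test_apex=0.12,
                lar={}, iar={})
    base.update(kw)
    return ObjectiveSet(**base)


class TestThresholdFilter:
    def test_all_conditions_enforced(self):
        t1 = CardinalTemperatures(10, 19, 25)
        t2 = CardinalTemperatures(11, 19, 25)
        t3 = CardinalTemperatures(12, 19, 25)
        results = {
            t1: _objset(),                                  # feasible
            t2: _objset(nrmse_test_phen=0.16),              # gap 0.06 > 0.05
            t3: None,                                       # failed fit
        }
        feas = threshold_filter(results)
        assert set(feas) == {t1}

    def test_all_zero_objectives_included(self):
        t = CardinalTemperatures(10, 19, 25)
        o = _objset(delta_odr=0.0, e_year_phen=0.0, e_year_apex=0.0,
                    nrmse_train_phen=0.0, nrmse_test_phen=0.0,
                    nrmse_train_apex=0.0, nrmse_test_apex=0.0)
        assert set(threshold_filter({t: o})) == {t}

    def test_matches_naive_row_filter(self):
        rng = np.random.default_rng(0)
        results = {}
        for i in range(45):
            results[CardinalTemperatures(i - 30, 19, 40)] = _objset(
                delta_odr=rng.uniform(0, 0.1), e_year_phen=rng.uniform(0, 0.1),
                e_year_apex=rng.uniform(0, 0.1),
                nrmse_train_phen=rng.uniform(0, 0.3),
                nrmse_test_phen=rng.uniform(0, 0.3),
                nrmse_train_apex=rng.uniform(0, 0.3),
                nrmse_test_apex=rng.uniform(0, 0.3))
        th = Thresholds()
        feas = threshold_filter(results, th)
        for ct, o in results.items():
            expected = (o.delta_odr < 0.05 and o.e_year_phen < 0.05
                        and o.e_year_apex < 0.05 and o.nrmse_train_phen < 0.2
                        and o.nrmse_train_apex < 0.2
                        and abs(o.nrmse_train_phen - o.nrmse_test_phen) < 0.05
                        and abs(o.nrmse_train_apex - o.nrmse_test_apex) < 0.05)
            assert (ct in feas) == expected


class TestNormalization:
    def test_affine_map_and_idempotence(self):
        out = minmax_normalize([1.0, 2.0, 3.0])
        assert np.allclose(out, [0.0, 0.5, 1.0])
        assert np.allclose(minmax_normalize(out), out)

    def test_degenerate_range_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            out = minmax_normalize([0.7, 0.7, 0.7])
        assert np.allclose(out, 0.0)


class TestParetoSelect:
    def test_weight_lattice_has_231_exact_sum_triples(self):
        w = weight_lattice(0.05)
        assert len(w) == 231
        assert np.allclose(w.sum(axis=1), 1.0)
        assert len({tuple(np.round(r, 10)) for r in w}) == 231

    def test_single_triplet_wins_every_weight(self):
        t = CardinalTemperatures(10.8, 19.0, 24.7)
        with pytest.warns(UserWarning):  # degenerate normalization ranges
            counts, winner = pareto_select({t: _objset()})
        assert winner == t and counts[t] == 231

    def test_dominated_triplet_earns_zero(self):
        good = CardinalTemperatures(10, 19, 25)
        bad = CardinalTemperatures(12, 20, 26)
        feas = {good: _objset(delta_odr=0.001, e_year_phen=0.001, e_year_apex=0.001),
                bad: _objset(delta_odr=0.04, e_year_phen=0.04, e_year_apex=0.04)}
        counts, winner = pareto_select(feas)
        assert winner == good
        assert counts[bad] == 0 and counts[good] == 231

    def test_counts_match_exhaustive_two_loop_oracle(self):
        rng = np.random.default_rng(5)
        feas = {}
        for i in range(8):
            feas[CardinalTemperatures(i, 19, 40)] = _objset(
                delta_odr=rng.uniform(0, 0.05), e_year_phen=rng.uniform(0, 0.05),
                e_year_apex=rng.uniform(0, 0.05))
        counts, _ = pareto_select(feas)
        keys = sorted(feas, key=lambda ct: ct.as_tuple())
        obj = np.column_stack([
            [feas[k].delta_odr for k in keys],
            minmax_normalize([feas[k].e_year_phen for k in keys]),
            minmax_normalize([feas[k].e_year_apex for k in keys])])
        oracle = {k: 0 for k in keys}
        for w in weight_lattice(0.05):
            f = [w @ row for row in obj]
            fmin = min(f)
            for k, v in zip(keys, f):
                if abs(v - fmin) < 1e-12:
                    oracle[k] += 1
        assert counts == oracle

    def test_empty_feasible_set_signals(self):
        with pytest.raises(ValueError):
            pareto_select({})


class TestEvaluateTriplet:
    def test_pure_function_and_nonnegative_nrmse(self, small_bundle):
        from vinedev.pipeline import apex_split, phenology_split

        ptr, pte, _ = phenology_split(small_bundle.ratings, 0.8, seed=1)
        atr, ate, _ = apex_split(small_bundle.apex, 0.8, seed=2)
        wc = WeatherCache(small_bundle.weather)
        ct = small_bundle.truth.cardinal
        o1 = evaluate_triplet(ct, ptr, pte, atr, ate, wc)
        o2 = evaluate_triplet(ct, ptr, pte, atr, ate, wc)
        assert o1 is not None
        for field in ("nrmse_train_phen", "nrmse_test_phen",
                      "nrmse_train_apex", "nrmse_test_apex"):
            assert getattr(o1, field) >= 0
            assert getattr(o1, field) == getattr(o2, field)
        assert o1.delta_odr == o2.delta_odr

    def test_truth_triplet_objectives_near_zero_on_twin_year_bundle(self):
        # year effects exactly zero by construction: identical weather in
        # both seasons, so even discretization artefacts cancel
        from vinedev.pipeline import apex_split, phenology_split
        from vinedev.synthetic_data import Design, GroundTruth, make_bundle

        d = Design(plants_per_ring=4, shoots_per_plant=2,
                   rating_doys={2018: tuple(range(100, 152, 3)),
                                2019: tuple(range(100, 152, 3))},
                   digitized_shoots_per_plant=12,
                   digitization_doys={2018: (122, 132, 142, 152),
                                      2019: (122, 132, 142, 152)})
        truth = GroundTruth.strong_signal(
            design=d,
            # group effects and observation noise are redrawn per year, so
            # they must be tight for the year effects to vanish; identical
            # weather (equal climates, shared noise) cancels everything
            # else, discretization included
            exgauss_sigma=0.08, exgauss_beta=0.02, stage_jitter_sd=0.05,
            sd_plant_slope=0.002,
            apex_sd_ring=0.02, apex_sd_plant=0.02, apex_sd_shoot=0.02,
            apex_sd_shoot_slope=0.002, apex_resid_sd=0.03, climate_by_year={})
        b = make_bundle(truth, seed=13, twin_years=True)
        ptr, pte, _ = phenology_split(b.ratings, 0.8, seed=3)
        atr, ate, _ = apex_split(b.apex, 0.8, seed=4)
        o = evaluate_triplet(b.truth.cardinal, ptr, pte, atr, ate,
                             WeatherCache(b.weather))
        assert o.delta_odr < 0.05
        assert o.e_year_phen < 0.05
        assert o.e_year_apex < 0.05
        assert threshold_filter({b.truth.cardinal: o})
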