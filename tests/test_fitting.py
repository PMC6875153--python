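import itertools
import math

import numpy as np
import pandas as pd
import pytest

from stngrad import (FitOptions, ModelParams, SectorGrid, bic,
                     compare_models, fit_model, nb_neg_loglik,
                     sector_center_coords, simulate_intensities,
                     tally_preferences, wbic_weights)
from stngrad.fitting import (STUDY_PREFERRED_MODELS, aggregate_preferences,
                             build_preference_table, preferred_model)

from conftest import grid_from_y

FAST = FitOptions(maxiter=60)


def _simulated_grid(params, shape, seed, specimen="S01", marker="TH"):
    rec = sector_center_coords(shape)
    y = simulate_intensities(params, rec[["x1", "x2", "x3"]].to_numpy(), seed)
    rec["y"] = y
    rec["included"] = True
    return SectorGrid(specimen, marker, shape, rec)


class TestBic:
    def test_direct_arithmetic(self):
        assert np.isclose(bic(100.0, 5, 1000), 200 + 5 * math.log(1000))
        assert np.isclose(bic(100.0, 5, 1000), 234.5388, atol=1e-4)

    def test_zero_parameters_no_penalty(self):
        assert bic(42.0, 0, 10) == bic(42.0, 0, 10_000) == 84.0

    def test_penalty_monotone_in_k(self):
        assert bic(10.0, 9, 100) > bic(10.0, 8, 100) > bic(10.0, 2, 100)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            bic(1.0, 2, 0)


class TestWbic:
    def test_equal_bics_uniform_weights(self):
        np.testing.assert_allclose(wbic_weights([10.0] * 4), 0.25)

    def test_two_point_logistic(self):
        w = wbic_weights([100.0, 102.0])
        np.testing.assert_allclose(w, [1 / (1 + np.exp(-1.0)),
                                       1 / (1 + np.exp(1.0))], rtol=1e-12)
        assert np.isclose(w[0], 0.7311, atol=1e-4)

    def test_shift_invariance(self):
        b = np.array([300.0, 310.0, 305.0, 302.0])
        np.testing.assert_allclose(wbic_weights(b), wbic_weights(b + 1234.5))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            w = wbic_weights(rng.normal(500, 50, 4))
            assert abs(w.sum() - 1.0) < 1e-12

    def test_all_infinite_rejected(self):
        with pytest.raises(ValueError):
            wbic_weights([np.inf, np.inf])


class TestPreferredModel:
    def test_lowest_bic_wins(self):
        assert preferred_model({"A": 10.0, "B": 5.0, "C": 20.0}) == "B"

    def test_exact_tie_goes_to_simpler_model(self):
        assert preferred_model({"A": 7.0, "B": 7.0}) == "A"
        assert preferred_model({"C": 7.0, "D": 7.0}) == "C"


class TestFitModel:
    def test_homogeneous_intercept_recovery(self):
        truth = ModelParams("A", lambda0=math.log(20.0), alpha=10.0)
        errs = []
        for seed in range(20):
            g = _simulated_grid(truth, (10, 10, 10), 1000 + seed)
            res = fit_model(g, "A", seed=seed, options=FAST)
            errs.append(abs(res.params.lambda0 - truth.lambda0))
        assert np.mean(errs) < 0.05

    def test_nested_nll_monotone(self, cube_grid):
        res_a = fit_model(cube_grid, "A", seed=0, options=FAST)
        for mid in "BCD":
            res = fit_model(cube_grid, mid, seed=0, options=FAST,
                            inject=[res_a.params])
            assert res.nll <= res_a.nll + 1e-9

    def test_beats_coarse_grid_oracle(self, cube_grid):
        y = cube_grid.intensities()
        coords = cube_grid.coords()
        best = np.inf
        for lam in itertools.product([-2, -1, 0, 1, 2], repeat=4):
            for alpha in (1.0, 10.0, 100.0):
                p = ModelParams("B", lambda0=float(lam[0]), alpha=alpha,
                                lambda1=float(lam[1]), lambda2=float(lam[2]),
                                lambda3=float(lam[3]))
                best = min(best, nb_neg_loglik(p, y, coords))
        res = fit_model(cube_grid, "B", seed=3, options=FAST)
        assert res.nll <= best + 1e-3

    def test_bic_invariant_holds(self, cube_grid):
        res = fit_model(cube_grid, "B", seed=1, options=FAST)
        assert np.isclose(res.bic, 2 * res.nll + res.k * math.log(res.n))
        assert res.n > res.k

    def test_flat_grid_flagged_for_gradient_models(self):
        g = grid_from_y(np.full(125, 9.0))
        res_a = fit_model(g, "A", seed=0, options=FAST)
        res_b = fit_model(g, "B", seed=0, options=FAST)
        assert res_a.converged
        assert not res_b.converged

    def test_too_small_grid_rejected(self):
        g = grid_from_y(np.arange(8.0))
        with pytest.raises(ValueError):
            fit_model(g, "D", seed=0)


class TestCompareModels:
    def test_linear_gradient_data_prefers_gradient_model(self):
        truth = ModelParams("B", lambda0=3.0, alpha=10.0, lambda1=1.0,
                            lambda2=-1.0, lambda3=1.5)
        wins = 0
        for seed in range(10):
            g = _simulated_grid(truth, (10, 10, 10), 2000 + seed)
            row = compare_models(g, seed=seed, options=FAST)
            wins += row["preferred"] == "B"
            assert abs(sum(row["wbic"].values()) - 1.0) < 1e-12
        assert wins >= 8

    def test_homogeneous_data_prefers_null_model(self):
        truth = ModelParams("A", lambda0=3.0, alpha=10.0)
        wins = 0
        for seed in range(10):
            g = _simulated_grid(truth, (10, 10, 10), 3000 + seed)
            row = compare_models(g, seed=seed, options=FAST)
            wins += row["preferred"] == "A"
        assert wins >= 8


class TestTallies:
    def test_published_grid_percentages(self):
        pct = tally_preferences(STUDY_PREFERRED_MODELS)
        assert round(pct["B"], 1) == 61.9
        assert round(pct["D"], 2) == 29.76
        assert round(pct["C"], 2) == 8.33
        assert pct["A"] == 0.0

    def test_uniform_grid(self):
        labels = pd.DataFrame([["B", "B"], ["B", "B"]])
        assert tally_preferences(labels)["B"] == 100.0

    def test_percentages_partition(self):
        rng = np.random.default_rng(3)
        labels = pd.DataFrame(
            rng.choice(list("ABCD"), size=(7, 12)))
        assert np.isclose(sum(tally_preferences(labels).values()), 100.0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            tally_preferences(pd.DataFrame())


class TestAggregation:
    @staticmethod
    def _table(rows):
        results = []
        for spec, marker, bics in rows:
            w = wbic_weights(list(bics.values()))
            results.append({"specimen": spec, "marker": marker,
                            "bic": bics,
                            "wbic": dict(zip(bics, w)),
                            "preferred": preferred_model(bics)})
        return build_preference_table(results)

    def test_all_b_specimen_wins_b(self):
        rows = [("s1", m, {"A": 110.0, "B": 100.0, "C": 120.0, "D": 121.0})
                for m in ("TH", "CALR", "SERT")]
        table = self._table(rows)
        agg = aggregate_preferences(table)
        assert agg["per_specimen"]["s1"] == "B"
        assert agg["overall"] == "B"

    def test_mean_wbic_tie_goes_to_simpler(self):
        rows = [("s1", "TH", {"A": 100.0, "B": 100.0})]
        agg = aggregate_preferences(self._table(rows))
        assert agg["overall"] == "A"

    def test_single_row_margin_is_its_preference(self):
        rows = [("s1", "TH", {"A": 130.0, "B": 100.0, "C": 125.0, "D": 140.0}),
                ("s2", "TH", {"A": 100.0, "B": 130.0, "C": 125.0, "D": 140.0})]
        agg = aggregate_preferences(self._table(rows))
        assert agg["per_specimen"]["s1"] == "B"
        assert agg["per_specimen"]["s2"] == "A"
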