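"""Trend testing, curve fitting, model selection and BMC estimation."""

import numpy as np
import pytest

import httrpod as h
from httrpod.dose_response import (
    _make_fit,
    _williams_stats,
    bmc_from_fit,
    lack_of_fit_p,
    postfilter,
)
import pandas as pd


class TestWilliamsTrend:
    def test_equal_group_means_give_null(self):
        rng = np.random.default_rng(0)
        groups = [5.0 + rng.normal(0, 1, 4) - 0 for _ in range(4)]
        groups = [g - g.mean() + 5.0 for g in groups]  # force equal means
        stat, p = h.williams_trend(groups, n_perm=400, seed=1)
        assert abs(stat) < 1.5
        assert p > 0.2

    def test_identical_values_degenerate(self):
        groups = [np.full(3, 7.0) for _ in range(3)]
        stat, p = h.williams_trend(groups, n_perm=200, seed=1)
        assert stat == 0.0
        assert p == 1.0

    def test_pava_amalgamation_single_violator(self):
        # group means [0, 5, 3] amalgamate upward to [0, 4, 4]: the
        # statistic uses the amalgamated top mean 4 over SE sqrt(2)
        y = np.array([[-1.0, 1.0, 4.0, 6.0, 2.0, 4.0]])
        member = np.array([0, 0, 1, 1, 2, 2])
        sizes = np.array([2.0, 2.0, 2.0])
        t = _williams_stats(y, sizes, member)
        assert t[0] == pytest.approx(4.0 / np.sqrt(2.0))

    def test_strong_monotone_trend_detected(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(mu, 0.5, 4) for mu in (0, 1, 2, 4)]
        stat, p = h.williams_trend(groups, n_perm=400, seed=3)
        assert stat > 3
        assert p < 0.05

    def test_shift_invariance(self, small_responses):
        resp, conc = small_responses
        y = resp.to_numpy()[:20]
        t1, p1 = h.williams_trend_matrix(y, conc, n_perm=200, seed=5)
        t2, p2 = h.williams_trend_matrix(y + 17.3, conc, n_perm=200, seed=5)
        np.testing.assert_allclose(t1, t2, rtol=1e-9)
        np.testing.assert_array_equal(p1, p2)

    def test_downward_trend_negative_statistic(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(mu, 0.3, 4) for mu in (4, 3, 2, 0)]
        stat, p = h.williams_trend(groups, n_perm=400, seed=4)
        assert stat < -3
        assert p < 0.05


def _conc_grid(reps=4):
    levels = [0.0, 0.1, 1.0, 10.0, 50.0]
    return np.repeat(levels, reps)


class TestFitModels:
    def test_exact_line_recovered(self):
        c = _conc_grid()
        y = 2.0 + 0.3 * c
        fits = {f.model_name: f for f in h.fit_models(c, y)}
        a, b = fits["linear"].params
        assert a == pytest.approx(2.0, abs=1e-6)
        assert b == pytest.approx(0.3, abs=1e-8)
        assert fits["linear"].ss < 1e-12

    def test_constant_data_selects_fewest_parameters(self):
        c = _conc_grid()
        y = np.full_like(c, 5.0)
        best = h.select_best(h.fit_models(c, y))
        assert best.model_name == "linear"
        assert best.params[1] == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_hill_favors_exp5(self):
        t = h.GeneTruth("g", 100.0, 10.0, True, "up", 4.0, 1.0, 1.5)
        c = _conc_grid(reps=6)
        y = np.log2(h.hill_mean(c, t))
        fits = {f.model_name: f for f in h.fit_models(c, y)}
        assert fits["exp5"].ss == min(f.ss for f in fits.values())

    def test_requires_enough_concentrations(self):
        with pytest.raises(ValueError):
            h.fit_models(np.array([0.0, 1.0, 1.0, 2.0]), np.zeros(4))


class TestSelectBest:
    def _fit(self, name, aic):
        c = _conc_grid()
        f = _make_fit(name, {"linear": (0, 0), "poly2": (0, 0, 0)}[name], c, np.zeros_like(c))
        f.aic = aic
        return f

    def test_lowest_aic_wins(self):
        a, b = self._fit("linear", 10.0), self._fit("poly2", 12.0)
        assert h.select_best([b, a]) is a

    def test_tie_broken_by_fewer_parameters(self):
        a, b = self._fit("linear", 10.0), self._fit("poly2", 10.0)
        assert h.select_best([b, a]) is a

    def test_single_converged_fit_returned(self):
        a = self._fit("poly2", 3.0)
        assert h.select_best([a]) is a
        a.converged = False
        with pytest.raises(ValueError):
            h.select_best([a])


class TestBMCFromFit:
    def test_linear_closed_form(self):
        c = _conc_grid()
        for slope, direction in ((2.0, "up"), (-2.0, "down")):
            y = 100.0 + slope * c
            fit = _make_fit("linear", (100.0, slope), c, y)
            est = bmc_from_fit(fit, control_sd=10.0, max_conc=50.0)
            assert est.bmc == pytest.approx(5.0, rel=1e-6)
            assert est.direction == direction
            assert est.bmcl <= est.bmc <= est.bmcu

    def test_flat_curve_has_no_bmc(self):
        c = _conc_grid()
        fit = _make_fit("linear", (100.0, 0.0), c, np.full_like(c, 100.0))
        est = bmc_from_fit(fit, control_sd=10.0, max_conc=50.0)
        assert est.bmc is None

    def test_control_sd_must_be_positive(self):
        c = _conc_grid()
        fit = _make_fit("linear", (0.0, 1.0), c, c)
        with pytest.raises(ValueError):
            bmc_from_fit(fit, control_sd=0.0, max_conc=50.0)

    def test_profile_bounds_bracket_estimate(self, small_bmc_table):
        tab = small_bmc_table.dropna(subset=["bmcl", "bmcu"])
        assert len(tab) > 10
        assert (tab["bmcl"] <= tab["bmc"] + 1e-9).all()
        assert (tab["bmc"] <= tab["bmcu"] + 1e-9).all()

    def test_noisy_fit_flagged_by_lack_of_fit(self):
        # group structure wildly non-monotone: the linear model misfits
        rng = np.random.default_rng(6)
        c = _conc_grid(reps=8)
        means = {0.0: 0.0, 0.1: 5.0, 1.0: -5.0, 10.0: 5.0, 50.0: -5.0}
        y = np.array([means[v] for v in c]) + rng.normal(0, 0.1, len(c))
        fit = _make_fit("linear", np.polyfit(c, y, 1)[::-1], c, y)
        assert lack_of_fit_p(fit) < 0.01


class TestPostfilter:
    def _results(self, rows):
        return pd.DataFrame(
            rows, columns=["probe_id", "model", "aic", "fit_p", "bmc", "bmcl",
                           "bmcu", "direction", "control_sd"],
        ).set_index("probe_id")

    def test_five_criteria(self):
        rows = [
            ("a", "linear", 0, 0.5, 60.0, 30.0, 90.0, "up", 1),    # above max conc
            ("b", "linear", 0, 0.5, 1.0, 0.5, 2.0, "up", 1),       # multi-gene
            ("c", "linear", 0, 0.05, 1.0, 0.5, 2.0, "up", 1),      # poor fit
            ("d", "linear", 0, 0.5, 1.0, 0.04, 2.0, "up", 1),      # bmc/bmcl 25
            ("e", "linear", 0, 0.5, 1.0, 0.1, 4.1, "up", 1),       # bmcu/bmcl 41
            ("f", "linear", 0, 0.5, 1.0, 0.1, 3.9, "up", 1),       # survives
        ]
        gene_map = {"a": "A", "b": ["B1", "B2"], "c": "C", "d": "D", "e": "E", "f": "F"}
        genes, flagged = postfilter(self._results(rows), 50.0, gene_map)
        assert list(genes.index) == ["F"]
        assert flagged.loc["a", "bmc_above_max_conc"]
        assert flagged.loc["b", "multi_gene_probe"]
        assert flagged.loc["c", "poor_fit"]
        assert flagged.loc["d", "bmc_bmcl_ratio"]
        assert flagged.loc["e", "bmcu_bmcl_ratio"]

    def test_unmapped_probe_removed(self):
        rows = [("a", "linear", 0, 0.5, 1.0, 0.5, 2.0, "up", 1)]
        genes, flagged = postfilter(self._results(rows), 50.0, {})
        assert len(genes) == 0
        assert flagged.loc["a", "multi_gene_probe"]

    def test_lowest_bmc_probe_kept_per_gene(self):
        rows = [
            ("p1", "linear", 0, 0.5, 2.0, 1.0, 3.0, "up", 1),
            ("p2", "linear", 0, 0.5, 1.0, 0.5, 2.0, "up", 1),
        ]
        genes, _ = postfilter(self._results(rows), 50.0, {"p1": "G", "p2": "G"})
        assert len(genes) == 1
        assert genes.loc["G", "probe_id"] == "p2"
        assert genes.loc["G", "bmc"] == 1.0


class TestMonotoneFamilies:
    def test_power_and_exp_fits_are_monotone(self, small_responses):
        resp, conc = small_responses
        grid = np.linspace(0, 50, 100)
        checked = 0
        for pid in resp.index[:40]:
            fits = h.fit_models(conc, resp.loc[pid].to_numpy(float))
            for f in fits:
                if f.model_name in ("power", "exp3", "exp5"):
                    vals = f.predict(grid)
                    d = np.diff(vals)
                    assert (d >= -1e-9).all() or (d <= 1e-9).all()
                    checked += 1
        assert checked > 0
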