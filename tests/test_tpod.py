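"""tPOD definitions, invariances and the parametric bootstrap."""

import numpy as np
import pytest

import httrpod as h
from httrpod.dose_response import _make_fit, control_sd_log2, fit_models, select_best
from httrpod.tpod import bootstrap_ci, bootstrap_gene_bmcs, tpod_report

from conftest import rank_table


class TestGene25:
    def test_rank_identity(self):
        t = h.tpod_gene25(rank_table(np.arange(1, 31)))
        assert t.value == 25.0
        assert t.n_genes == 30

    def test_boundary_undefined(self):
        t = h.tpod_gene25(rank_table(np.arange(1, 25)))
        assert not t.defined
        assert "fewer than 25" in t.status

    def test_ci_borrows_selected_gene_bounds(self):
        bmcs = np.arange(1, 31)
        t = h.tpod_gene25(rank_table(bmcs, bmcls=bmcs / 3, bmcus=bmcs * 3))
        assert (t.lower, t.upper) == (25 / 3, 75.0)

    def test_tie_break_deterministic(self):
        bmcs = np.concatenate([np.arange(1, 24), [24.0, 24.0, 30.0]])
        bmcls = bmcs / 2
        bmcls[24] = 11.0  # distinguish the tied pair by BMCL
        t1 = h.tpod_gene25(rank_table(bmcs, bmcls=bmcls))
        t2 = h.tpod_gene25(rank_table(bmcs[::-1], bmcls=bmcls[::-1],
                                      genes=[f"g{i}" for i in range(25, -1, -1)]))
        assert t1.value == t2.value == 24.0
        assert t1.lower == t2.lower

    def test_row_order_invariance(self, small_bmc_table):
        fwd = h.tpod_gene25(small_bmc_table)
        rev = h.tpod_gene25(small_bmc_table.iloc[::-1])
        assert (fwd.value, fwd.lower, fwd.upper) == (rev.value, rev.lower, rev.upper)

    def test_at_least_minimum_bmc(self, small_bmc_table):
        t = h.tpod_gene25(small_bmc_table)
        if t.defined:
            assert t.value >= small_bmc_table["bmc"].min()


class TestPathway:
    def test_interpolated_percentile(self):
        table = rank_table([1.0, 2.0, 3.0], genes=["a", "b", "c"])
        catalog = {"set40": ["a", "b", "c"] + [f"x{i}" for i in range(37)]}
        t = h.tpod_pathway(table, catalog)
        assert t.value == pytest.approx(1.1)
        assert t.source_set == "set40"
        assert t.n_genes == 3

    def test_underpopulated_set_ineligible(self):
        table = rank_table([1, 2, 3, 4], genes=list("abcd"))
        catalog = {"big": list("abcd") + [f"x{i}" for i in range(96)]}  # 4/100 < 5%
        assert not h.tpod_pathway(table, catalog).defined

    def test_small_set_ineligible(self):
        table = rank_table([1, 2, 3], genes=list("abc"))
        catalog = {"tiny": list("abc") + [f"x{i}" for i in range(10)]}  # 13 < 40
        assert not h.tpod_pathway(table, catalog).defined

    def test_minimum_over_eligible_sets(self):
        genes = [f"g{i}" for i in range(10)]
        table = rank_table([0.5, 0.5, 0.5, 0.8, 0.8, 0.8, 1, 1, 1, 1], genes=genes)
        pad = lambda k: [f"{k}{i}" for i in range(37)]
        catalog = {"lo": genes[:3] + pad("a"), "hi": genes[3:6] + pad("b")}
        t = h.tpod_pathway(table, catalog)
        assert t.value == pytest.approx(0.5)
        assert t.source_set == "lo"


class TestLCRD:
    def test_outlier_skipped_by_gap_rule(self):
        t = h.tpod_lcrd(rank_table([0.001, 1.0, 1.1, 1.2, 1.3, 1.4]))
        assert t.value == pytest.approx(1.0)

    def test_even_accumulation_starts_at_smallest(self):
        bmcs = np.geomspace(0.1, 10, 20)  # log10 gaps ~0.105 each
        t = h.tpod_lcrd(rank_table(bmcs))
        assert t.value == pytest.approx(0.1)

    def test_too_few_genes_undefined(self):
        assert not h.tpod_lcrd(rank_table([1, 2, 3, 4])).defined


class TestBiomarkerTPOD:
    def test_median_of_members(self):
        table = rank_table([1.0, 2.0, 3.0, 9.0], genes=list("abcx"))
        t = h.tpod_biomarker(table, ["a", "b", "c"], mode="median")
        assert t.value == 2.0

    def test_min_three_members(self):
        table = rank_table([1.0, 2.0], genes=list("ab"))
        t = h.tpod_biomarker(table, ["a", "b", "zz"], mode="fifth")
        assert not t.defined

    def test_activation_required(self):
        table = rank_table([1.0, 2.0, 3.0], genes=list("abc"))
        t = h.tpod_biomarker(table, list("abc"), activation_required=True, activated=False)
        assert not t.defined and "not activated" in t.status

    def test_fifth_leq_median(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            bmcs = rng.lognormal(0, 1, rng.integers(3, 30))
            genes = [f"g{i}" for i in range(len(bmcs))]
            table = rank_table(bmcs, genes=genes)
            lo = h.tpod_biomarker(table, genes, mode="fifth").value
            mid = h.tpod_biomarker(table, genes, mode="median").value
            assert lo <= mid

    def test_unit_equivariance(self, small_bmc_table):
        k = 3.7
        scaled = small_bmc_table.copy()
        for col in ("bmc", "bmcl", "bmcu"):
            scaled[col] = scaled[col] * k
        for fn in (h.tpod_gene25, h.tpod_lcrd):
            a, b = fn(small_bmc_table), fn(scaled)
            if a.defined:
                assert b.value == pytest.approx(a.value * k)


def _linear_fit(noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    c = np.repeat([0.0, 0.1, 1.0, 10.0, 50.0], 4)
    y = 10.0 + 0.2 * c + rng.normal(0, noise, len(c))
    return _make_fit("linear", np.polyfit(c, y, 1)[::-1], c, y)


class TestBootstrap:
    def test_zero_noise_collapses_to_point(self):
        fit = _linear_fit(noise=0.0)
        pt, lo, hi = bootstrap_ci({"g": (fit, 1.0)}, 50.0, "median",
                                  n_boot_per_gene=50, n_experiments=500, seed=1)
        assert pt == lo == hi == pytest.approx(5.0, rel=1e-6)

    def test_seeded_reproducibility(self):
        fit = _linear_fit(noise=0.5, seed=3)
        args = dict(statistic="median", n_boot_per_gene=40, n_experiments=400, seed=9)
        r1 = bootstrap_ci({"g": (fit, 1.0)}, 50.0, **args)
        r2 = bootstrap_ci({"g": (fit, 1.0)}, 50.0, **args)
        assert r1 == r2

    def test_inclusion_probability_zero_gives_undefined(self):
        # flat curve: no resample ever yields a BMC
        c = np.repeat([0.0, 1.0, 10.0, 50.0], 3)
        fit = _make_fit("linear", (5.0, 0.0), c, np.full_like(c, 5.0))
        assert bootstrap_ci({"g": (fit, 1.0)}, 50.0, n_boot_per_gene=20,
                            n_experiments=100, seed=1) == (None, None, None)

    def test_gene_bmcs_within_range(self):
        fit = _linear_fit(noise=0.5, seed=5)
        bmcs = bootstrap_gene_bmcs(fit, 1.0, 50.0, n_boot=40,
                                   rng=np.random.default_rng(2))
        assert len(bmcs) > 0
        assert ((bmcs > 0) & (bmcs <= 50.0)).all()


class TestGMT:
    def test_round_trip(self, tmp_path):
        sets = {"s1": ["a", "b", "c"], "s2": ["d"]}
        path = tmp_path / "sets.gmt"
        h.write_gmt(sets, path)
        assert h.read_gmt(path) == sets

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_name\tdesc\n")
        with pytest.raises(ValueError):
            h.read_gmt(path)

    def test_report_frame(self):
        t = h.tpod_gene25(rank_table(np.arange(1, 31)))
        frame = tpod_report([t])
        assert frame.loc["gene25", "value"] == 25.0
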