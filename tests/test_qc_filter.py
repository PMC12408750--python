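"""QC rules, normalization, probe filters and contrast statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import httrpod as h
from httrpod.qc_filter import QCThresholds, cpm, qc_report_frame


class TestGini:
    def test_closed_form_cases(self):
        assert h.gini([1, 1, 1, 1]) == 0.0
        assert h.gini([0, 0, 0, 100]) == pytest.approx(0.75)
        assert h.gini([1, 2, 3, 4]) == pytest.approx(0.25)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            h.gini([0, 0, 0])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=50).filter(
            lambda x: sum(x) > 0
        ),
        st.floats(1e-3, 1e3),
    )
    def test_scale_invariance_and_range(self, x, c):
        g = h.gini(x)
        assert 0.0 <= g <= 1.0
        assert h.gini(np.asarray(x) * c) == pytest.approx(g, abs=1e-9)


class TestSampleQC:
    def test_clean_experiment_all_pass(self, small_experiment):
        exp, _ = small_experiment
        target = float(exp.library_sizes.median())
        reports = h.sample_qc(exp, QCThresholds(target_reads=target))
        assert all(r.pass_ for r in reports)

    def test_each_corruption_fails_with_its_reason(self, small_experiment):
        exp, _ = small_experiment
        low, spiked, decor = exp.sample_ids[0], exp.sample_ids[5], exp.sample_ids[10]
        bad = h.inject_qc_failures(
            exp, {"low_depth": [low], "spiked": [spiked], "decorrelated": [decor]},
            seed=2, low_depth_reads=1500,
        )
        target = float(exp.library_sizes.median())
        reports = {r.sample_id: r for r in h.sample_qc(bad, QCThresholds(target_reads=target))}
        assert "mapped_reads" in reports[low].fail_reasons
        assert "gini" in reports[spiked].fail_reasons
        assert "spearman" in reports[decor].fail_reasons

    def test_target_reads_required(self, small_experiment):
        exp, _ = small_experiment
        with pytest.raises(ValueError):
            h.sample_qc(exp, QCThresholds())

    def test_identical_samples_all_pass(self):
        # zero distances, zero IQR: fence boundaries are inclusive
        rng = np.random.default_rng(0)
        col = rng.poisson(50, 100)
        counts = pd.DataFrame(
            np.tile(col[:, None], (1, 6)),
            index=[f"p{i}" for i in range(100)],
            columns=[f"s{j}" for j in range(6)],
        )
        meta = pd.DataFrame(
            {
                "chemical": "x", "concentration_uM": 0.0, "plate": 0,
                "replicate": range(6), "role": "control",
            },
            index=counts.columns,
        )
        exp = h.CountExperiment(counts, meta)
        reports = h.sample_qc(exp, QCThresholds(target_reads=float(col.sum())))
        assert all(r.pass_ for r in reports)

    def test_order_independence(self, small_experiment):
        exp, _ = small_experiment
        target = float(exp.library_sizes.median())
        fwd = qc_report_frame(h.sample_qc(exp, QCThresholds(target_reads=target)))
        shuffled = exp.subset_samples(exp.sample_ids[::-1])
        rev = qc_report_frame(h.sample_qc(shuffled, QCThresholds(target_reads=target)))
        pd.testing.assert_frame_equal(fwd.sort_index(), rev.sort_index())


class TestSizeFactors:
    def test_scalar_multiple_columns(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(100, 50).astype(float) + 1
        counts = np.column_stack([a, 2 * a])
        f = h.size_factors_median_of_ratios(counts)
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_identical_columns_equal_factors(self):
        a = np.arange(1, 21, dtype=float)
        f = h.size_factors_median_of_ratios(np.column_stack([a, a, a]))
        assert np.allclose(f, f[0])

    def test_hand_evaluated_medians(self):
        counts = np.array([[10, 20], [100, 200], [1000, 2000]], dtype=float)
        f = h.size_factors_median_of_ratios(counts)
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_fallback_warns_without_common_probe(self):
        counts = np.array([[5, 0], [0, 5]], dtype=float)
        with pytest.warns(UserWarning):
            f = h.size_factors_median_of_ratios(counts)
        assert np.allclose(f, 1.0)


def _frame(arr, groups):
    arr = np.asarray(arr, dtype=float)
    cols = [f"s{j}" for j in range(arr.shape[1])]
    return (
        pd.DataFrame(arr, index=[f"p{i}" for i in range(arr.shape[0])], columns=cols),
        pd.Series(groups, index=cols),
    )


class TestRelevanceFilter:
    def test_boundary_three_of_four(self):
        # CPM above threshold in 3 of 4 treated samples -> kept (3/4 >= 0.75)
        counts = np.full((2, 8), 1000.0)
        counts[0] = [5, 5, 5, 0, 0, 0, 0, 0]  # high CPM in 3 of 4 of group A
        counts[1] = [1000] * 8
        df, groups = _frame(counts, list("AAAABBBB"))
        kept = h.relevance_filter(df, groups, cpm_min=0.5)
        assert "p0" in kept

    def test_all_zero_probe_removed(self):
        counts = np.vstack([np.zeros(8), np.full(8, 100.0)])
        df, groups = _frame(counts, list("AAAABBBB"))
        assert "p0" not in h.relevance_filter(df, groups)

    def test_half_per_group_removed(self):
        counts = np.full((2, 8), 0.0)
        counts[0] = [50, 50, 0, 0, 50, 50, 0, 0]  # 2 of 4 in each group
        counts[1] = [1000] * 8
        df, groups = _frame(counts, list("AAAABBBB"))
        assert "p0" not in h.relevance_filter(df, groups)

    def test_idempotent(self, small_experiment):
        exp, _ = small_experiment
        groups = exp.metadata["concentration_uM"].astype(float)
        once = h.relevance_filter(exp.counts, groups)
        twice = h.relevance_filter(exp.counts.loc[once], groups)
        assert list(once) == list(twice)


class TestSpikeFilter:
    def test_formula_evaluation(self):
        df, groups = _frame([[0, 0, 0, 500], [10, 12, 11, 13], [5, 5, 5, 5]], "AAAA")
        kept = h.spike_filter(df, groups)
        assert list(kept) == ["p1", "p2"]  # p0: 500-0 >= 500/5 -> spike

    def test_polarity_configurable(self):
        df, groups = _frame([[0, 0, 0, 500], [10, 12, 11, 13]], "AAAA")
        kept = h.spike_filter(df, groups, remove_when_spiked=False)
        assert list(kept) == ["p0"]

    def test_idempotent(self, small_experiment):
        exp, _ = small_experiment
        groups = exp.metadata["concentration_uM"].astype(float)
        once = h.spike_filter(exp.counts, groups)
        twice = h.spike_filter(exp.counts.loc[once], groups)
        assert list(once) == list(twice)


class TestContrastStats:
    def test_null_contrast_has_no_signal(self, small_experiment):
        # relabel a homogeneous pool: |log2FC| near 0, few small p-values
        exp, _ = small_experiment
        ctrl = exp.control_samples()
        pool = exp.subset_samples(ctrl + exp.treated_samples("chemA", 0.001))
        resp = h.contrast_stats(pool, "chemA", 0.001)
        assert resp["unadjusted_p"].lt(0.05).mean() < 0.10
        assert resp["log2_fold_change"].abs().median() < 0.5

    def test_simulated_fold_change_recovered(self):
        design = h.SimDesign(n_probes=60, size_factor_sigma=0.0)
        truths = [
            h.GeneTruth(f"g{i}", 100.0, 20.0, i == 0, "up",
                        4.0 if i == 0 else 1.0, 0.05, 1.0)
            for i in range(60)
        ]
        exp, _ = h.generate_experiment(design, truths, seed=9)
        resp = h.contrast_stats(exp, "chemA", 50.0)
        assert 3.0 <= resp.loc["g0", "linear_fold_change"] <= 5.0
        assert resp.loc["g0", "unadjusted_p"] < 0.05

    def test_cpm_columns_present(self, small_experiment):
        exp, _ = small_experiment
        resp = h.contrast_stats(exp, "chemA", 50.0)
        assert {"mean_cpm_treated", "mean_cpm_control"} <= set(resp.columns)
        assert (resp["mean_cpm_control"] >= 0).all()
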