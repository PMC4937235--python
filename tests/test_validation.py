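"""Count normalization, paired testing, BH adjustment and concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hccsig import (
    CohortConfig,
    bh_adjust,
    concordance,
    normalize_counts_fullquantile,
    paired_de,
    simulate_counts,
    simulate_expression,
    validate_signature,
)
from hccsig.validation import filter_low_counts

from conftest import planted


def counts_frame(values, genes=None):
    arr = np.atleast_2d(np.asarray(values))
    return pd.DataFrame(
        arr,
        index=genes or [f"g{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )


def design_frame(n):
    return pd.DataFrame(
        {"tumor_sample_id": [f"t{i}" for i in range(n)],
         "normal_sample_id": [f"n{i}" for i in range(n)]},
        index=pd.Index([f"P{i}" for i in range(n)], name="patient_id"),
    )


class TestNormalizeCounts:
    def test_proportional_libraries_become_identical(self):
        c = counts_frame([[10, 20], [40, 80], [5, 10], [100, 200]])
        norm = normalize_counts_fullquantile(c, pseudocount=1.0)
        np.testing.assert_allclose(norm["s0"], norm["s1"])

    def test_all_zero_gene_maps_to_shared_minimum(self):
        c = counts_frame([[0, 0, 0], [50, 70, 90], [10, 20, 30]])
        norm = normalize_counts_fullquantile(c, pseudocount=1.0)
        zero_row = norm.loc["g0"]
        assert zero_row.nunique() == 1
        assert (zero_row == norm.min()).all()

    def test_hand_computed_order_statistic_oracle_4x3(self):
        c = counts_frame([[3, 15, 0], [7, 1, 31], [1, 63, 7], [15, 7, 3]])
        log = np.log2(c.to_numpy() + 1.0)
        ref = np.sort(log, axis=0).mean(axis=1)  # oracle: mean order statistics
        expected = np.empty_like(log)
        for j in range(3):
            expected[np.argsort(log[:, j]), j] = ref
        norm = normalize_counts_fullquantile(c, pseudocount=1.0)
        np.testing.assert_allclose(norm.to_numpy(), expected, atol=1e-12)

    def test_zero_pseudocount_with_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="pseudocount"):
            normalize_counts_fullquantile(counts_frame([[0, 1]]), pseudocount=0.0)

    def test_low_count_filter(self):
        c = counts_frame([[1, 2, 3], [10, 20, 30]])
        assert list(filter_low_counts(c, 5.0).index) == ["g1"]


class TestPairedDe:
    def _norm(self, tumor_cols, normal_cols):
        n = len(tumor_cols[0])
        values = {}
        for i in range(n):
            values[f"t{i}"] = [row[i] for row in tumor_cols]
            values[f"n{i}"] = [row[i] for row in normal_cols]
        return pd.DataFrame(values, index=[f"g{i}" for i in range(len(tumor_cols))])

    def test_zero_differences_are_null(self):
        norm = self._norm([[5.0, 6.0, 7.0]], [[5.0, 6.0, 7.0]])
        rec = paired_de(norm, design_frame(3)).iloc[0]
        assert rec["p_value"] == 1.0
        assert rec["log2fc_seq"] == 0.0

    def test_constant_nonzero_difference_degenerate_flagged(self):
        norm = self._norm([[6.0, 7.0, 8.0, 9.0]], [[5.0, 6.0, 7.0, 8.0]])
        rec = paired_de(norm, design_frame(4)).iloc[0]
        assert rec["log2fc_seq"] == 1.0
        assert rec["p_value"] == 0.0
        assert rec["degenerate"]

    def test_closed_form_one_sample_t_oracle(self):
        d = np.array([2.1, 1.9, 2.0])
        norm = self._norm([[5 + d[0], 5 + d[1], 5 + d[2]]], [[5.0, 5.0, 5.0]])
        rec = paired_de(norm, design_frame(3)).iloc[0]
        t_exp = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        p_exp = 2 * stats.t.sf(abs(t_exp), 2)
        assert rec["t_stat"] == pytest.approx(t_exp, abs=1e-10)
        assert rec["p_value"] == pytest.approx(p_exp, abs=1e-10)
        assert rec["log2fc_seq"] == pytest.approx(2.0, abs=1e-12)

    def test_single_pair_rejected(self):
        norm = self._norm([[5.0]], [[4.0]])
        with pytest.raises(ValueError, match="pairs"):
            paired_de(norm, design_frame(1))


def brute_force_bh(p):
    """Independent step-up oracle: q_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBhAdjust:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate_vectors(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    def test_matches_brute_force_step_up_exactly(self, p):
        got = bh_adjust(p)
        np.testing.assert_allclose(got, brute_force_bh(p), atol=1e-12)
        # q >= p element-wise and monotone along sorted p
        assert (got >= np.asarray(p) - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(got[order]) >= -1e-12).all()

    def test_null_counts_false_confirmation_rate(self):
        # all-background cohort: fraction of genes at q < 0.05 stays near 0
        config = CohortConfig(
            n_genes=400,
            n_planted_per_class={c: 0 for c in
                                 ("tumor_specific", "tumor_associated",
                                  "liver_specific", "down_in_tumor")},
            seed=21,
        )
        _, _, _, truth = simulate_expression(config)
        fracs = []
        for seed in range(20):
            counts, design = simulate_counts(config, truth, 9, 0.1, seed=200 + seed)
            rec = paired_de(normalize_counts_fullquantile(filter_low_counts(counts)), design)
            fracs.append((bh_adjust(rec["p_value"].to_numpy()) < 0.05).mean())
        fracs = np.array(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert fracs.mean() <= 0.05 + 3 * se


class TestConcordance:
    def _records(self, array_fc, seq_fc, q):
        return pd.DataFrame(
            {"log2fc_seq": seq_fc, "log2fc_array": array_fc, "q_value": q},
            index=[f"g{i}" for i in range(len(q))],
        )

    def test_identity_gives_unit_r2_and_slope(self):
        fc = np.array([1.0, 2.0, 3.0, -1.0])
        rec = self._records(fc, fc, [0.01] * 4)
        s = concordance(rec, set(rec.index), fdr_max=0.05)
        assert s.r_squared == pytest.approx(1.0)
        assert s.slope == pytest.approx(1.0)
        assert s.n_confirmed_up == 3 and s.n_confirmed_down == 1

    def test_anti_correlation_high_r2_but_nothing_confirmed_up(self):
        fc = np.array([1.0, 2.0, 3.0])
        rec = self._records(fc, -fc, [0.01] * 3)
        s = concordance(rec, set(rec.index), fdr_max=0.05)
        assert s.r_squared == pytest.approx(1.0)
        assert s.slope == pytest.approx(-1.0)
        assert s.n_confirmed_up == 0 and s.n_confirmed_down == 0

    def test_too_few_genes_reports_counts_only(self):
        rec = self._records([1.0, 2.0], [1.0, 2.0], [0.01, 0.2])
        s = concordance(rec, {"g0", "g1"}, fdr_max=0.05)
        assert s.r_squared is None and s.slope is None
        assert s.n_confirmed_up == 1

    def test_paired_estimator_recovers_delta(self):
        # the paired estimator is unbiased on the raw paired log ratios:
        # per-library size factors are mean-zero in log scale and cancel
        # in expectation within pairs; 20 seeds, SE across seed means
        config = CohortConfig(seed=1)
        _, _, _, truth = simulate_expression(config)
        ts = planted(truth, "tumor_specific")
        means = []
        for seed in range(20):
            counts, design = simulate_counts(config, truth, 9, 0.1, seed=300 + seed)
            rec = paired_de(np.log2(counts + 1.0), design)
            means.append(rec.loc[rec.index.isin(ts), "log2fc_seq"].mean())
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - config.delta) < 3 * se

    def test_full_quantile_path_compresses_but_preserves_signal(self):
        # full-quantile normalization maps every library onto one shared
        # distribution, which pulls the planted genes' tail values toward
        # the bulk: the recovered fold change sits a little below delta
        # but stays well clear of the null
        config = CohortConfig(seed=1)
        _, _, _, truth = simulate_expression(config)
        ts = planted(truth, "tumor_specific")
        means = []
        for seed in range(10):
            counts, design = simulate_counts(config, truth, 9, 0.1, seed=300 + seed)
            rec = paired_de(normalize_counts_fullquantile(filter_low_counts(counts)), design)
            means.append(rec.loc[rec.index.isin(ts), "log2fc_seq"].mean())
        mean = np.mean(means)
        assert 0.75 * config.delta < mean < config.delta

    def test_end_to_end_planted_genes_confirmed(self, default_cohort):
        config, expr, sheet, probe_map, truth = default_cohort
        from hccsig import SignatureScreen

        res = SignatureScreen(expr, sheet, probe_map, normalized=True).fit()
        counts, design = simulate_counts(config, truth, 9, 0.1, seed=2)
        records, summary = validate_signature(
            counts, design, res.gene_log2fc, res.signature_set.tumor_specific
        )
        ts = planted(truth, "tumor_specific")
        confirmed = set(records.index[records["confirmed"]])
        assert ts <= confirmed
        assert summary.n_confirmed_up == len(ts)
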