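"""Winsorizing, FDR, subject/group aggregation, networks, and differences."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from cueconn import (GroupConnectivity, GroupSummary, Montage, bh_fdr,
                     difference_matrix, extract_network, group_aggregate,
                     region_aggregate, subject_summary, winsorize_iqr)
from conftest import make_subject_matrix


class TestWinsorizeIqr:
    def test_hand_oracle_with_linear_interpolation_quantiles(self):
        # Q1=2, Q3=4, IQR=2 -> bounds [-1, 7]; 100 capped to 7
        out = winsorize_iqr([1, 2, 3, 4, 100])
        np.testing.assert_allclose(out, [1, 2, 3, 4, 7])

    def test_all_equal_values_unchanged(self):
        out = winsorize_iqr([5.0] * 6)
        np.testing.assert_allclose(out, [5.0] * 6)

    def test_fewer_than_four_values_errors(self):
        with pytest.raises(ValueError, match=">= 4"):
            winsorize_iqr([1.0, 2.0, 3.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=50))
    def test_preserves_count_median_and_order(self, values):
        arr = np.array(values)
        out = winsorize_iqr(arr)
        assert out.size == arr.size
        assert np.median(out) == pytest.approx(np.median(arr))
        # capping never reorders: sorting keys agree
        order = np.argsort(arr, kind="mergesort")
        assert np.all(np.diff(out[order]) >= 0)
        q1, q3 = np.percentile(arr, [25, 75])
        iqr = q3 - q1
        assert out.min() >= q1 - 1.5 * iqr - 1e-9
        assert out.max() <= q3 + 1.5 * iqr + 1e-9


class TestBhFdr:
    def test_all_ones_reject_nothing(self):
        rej, adj = bh_fdr(np.ones(10))
        assert not rej.any()
        np.testing.assert_allclose(adj, 1.0)

    def test_single_small_p(self):
        rej, adj = bh_fdr([0.01])
        assert rej[0] and adj[0] == pytest.approx(0.01)

    def test_step_up_boundary_all_rejected(self):
        rej, _ = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05], alpha=0.05)
        assert rej.all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_matches_statsmodels_on_random_sets(self):
        rng = np.random.default_rng(61)
        for _ in range(20):
            p = rng.random(100) ** rng.uniform(0.5, 3.0)
            rej, adj = bh_fdr(p, alpha=0.05)
            rej_sm, adj_sm, _, _ = multipletests(p, alpha=0.05,
                                                 method="fdr_bh")
            assert np.array_equal(rej, rej_sm)
            np.testing.assert_allclose(adj, adj_sm, atol=1e-12)

    def test_adjusted_monotone_in_rank(self):
        rng = np.random.default_rng(62)
        p = rng.random(50)
        _, adj = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestSubjectSummary:
    def test_single_epoch_is_identity_with_winsorizing(self):
        rng = np.random.default_rng(70)
        F = rng.uniform(1, 5, (4, 4))
        p = rng.uniform(0, 1, (4, 4))
        m = make_subject_matrix(p, F=F)
        out = subject_summary([m])
        defined = out.defined_mask
        np.testing.assert_allclose(out.F[defined],
                                   winsorize_iqr(m.F[defined]))
        np.testing.assert_allclose(out.pvalue[defined], m.pvalue[defined],
                                   atol=1e-12)

    def test_null_epochs_stay_null(self):
        mats = [make_subject_matrix(np.ones((3, 3))) for _ in range(4)]
        out = subject_summary(mats)
        assert np.all(out.pvalue[out.defined_mask] > 0.99)

    def test_fisher_combination_matches_chi_square_oracle(self):
        # -2 (ln 0.1 + ln 0.1) = 9.21, chi2(4) upper tail ~ 0.056
        mats = [make_subject_matrix(np.full((2, 2), 0.1)) for _ in range(2)]
        out = subject_summary(mats)
        stat = -2 * 2 * np.log(0.1)
        assert stat == pytest.approx(9.21, abs=0.005)
        expect = chi2.sf(stat, 4)
        assert out.pvalue[0, 1] == pytest.approx(expect, abs=1e-12)
        assert out.pvalue[0, 1] == pytest.approx(0.056, abs=1e-3)

    def test_proportion_rule_records_majority_vote(self):
        lo = make_subject_matrix(np.full((2, 2), 0.001))
        hi = make_subject_matrix(np.full((2, 2), 0.9))
        out = subject_summary([lo, lo, hi], combine="proportion")
        assert out.sig_mask[0, 1]
        out2 = subject_summary([lo, hi, hi], combine="proportion")
        assert not out2.sig_mask[0, 1]

    def test_mismatched_channels_error(self):
        a = make_subject_matrix(np.ones((2, 2)))
        b = make_subject_matrix(np.ones((2, 2)), labels=["x", "y"])
        with pytest.raises(ValueError, match="mismatch"):
            subject_summary([a, b])


def _cohort(n_sig, n_subj=40, pair=(0, 1), C=3):
    """Subject matrices where `pair` is significant for n_sig subjects."""
    mats = []
    for i in range(n_subj):
        p = np.full((C, C), 0.6)
        if i < n_sig:
            p[pair[1], pair[0]] = 1e-8
        mats.append(make_subject_matrix(p, subject_id=f"S{i}"))
    return mats


class TestGroupAggregate:
    def test_strict_robustness_boundary_39_vs_38_of_40(self):
        g39 = group_aggregate(_cohort(39))
        assert g39.consistency[1, 0] == pytest.approx(0.975)
        assert g39.robust_mask[1, 0]
        g38 = group_aggregate(_cohort(38))
        assert g38.consistency[1, 0] == pytest.approx(0.95)
        assert not g38.robust_mask[1, 0]

    def test_consistency_lies_on_subject_grid(self):
        rng = np.random.default_rng(80)
        mats = [make_subject_matrix(rng.uniform(0, 1, (4, 4)))
                for _ in range(17)]
        g = group_aggregate(mats)
        vals = g.consistency[g.defined_mask]
        np.testing.assert_allclose(vals * 17, np.round(vals * 17), atol=1e-9)

    def test_fdr_scope_none_uses_raw_alpha(self):
        p = np.full((3, 3), 0.04)
        mats = [make_subject_matrix(p) for _ in range(3)]
        g_raw = group_aggregate(mats, fdr_scope="none")
        assert g_raw.consistency[0, 1] == pytest.approx(1.0)

    def test_fewer_than_two_subjects_errors(self):
        with pytest.raises(ValueError, match=">= 2"):
            group_aggregate(_cohort(1, n_subj=1))

    def test_null_cohort_has_no_robust_connections(self):
        rng = np.random.default_rng(81)
        mats = [make_subject_matrix(rng.uniform(0, 1, (4, 4)))
                for _ in range(40)]
        g = group_aggregate(mats)
        assert g.robust_mask.sum() == 0


def _toy_summary(mean_F, labels, robust=None, subj=None):
    C = len(labels)
    defined = ~np.eye(C, dtype=bool)
    mean_F = np.where(defined, mean_F, np.nan)
    if robust is None:
        robust = np.zeros((C, C), bool)
    if subj is None:
        subj = np.broadcast_to(mean_F, (6, C, C)).copy()
    return GroupSummary(
        condition="lexical", channel_labels=list(labels), mean_F=mean_F,
        sd_F=np.where(defined, 1.0, np.nan),
        consistency=np.where(defined, 0.5, np.nan), robust_mask=robust,
        fdr_rejected=np.zeros((C, C), bool),
        zscore_F=np.where(defined, 0.0, np.nan), subject_F=subj,
        subject_sig=np.zeros((6, C, C), bool),
    )


class TestNetworksAndRegions:
    def test_threshold_above_max_gives_empty_network(self):
        s = _toy_summary(np.full((3, 3), 5.0), ["a", "b", "c"])
        assert extract_network(s, threshold=100.0).empty

    def test_equal_f_values_mean_plus_sd_gives_no_edges(self):
        s = _toy_summary(np.full((3, 3), 5.0), ["a", "b", "c"])
        # SD 0 -> threshold = mean; strict inequality keeps nothing
        assert extract_network(s, "mean_plus_sd").empty

    def test_mean_plus_sd_threshold_recomputed(self):
        rng = np.random.default_rng(90)
        s = _toy_summary(rng.uniform(10, 30, (4, 4)), list("abcd"))
        vals = s.mean_F[s.defined_mask]
        assert s.viz_threshold == pytest.approx(
            vals.mean() + vals.std(ddof=1))
        edges = extract_network(s, "mean_plus_sd")
        assert (edges["F"] > s.viz_threshold).all()
        assert len(edges) == (vals > s.viz_threshold).sum()
        assert (edges["F"].diff().dropna() <= 0).all()

    def test_single_edge_region_bookkeeping(self):
        labels = ["F7", "FT7", "Cz"]
        mean_F = np.zeros((3, 3))
        mean_F[1, 0] = 30.0  # F7 -> FT7, both frontal
        s = _toy_summary(mean_F, labels)
        table = region_aggregate(s, Montage(labels=labels), reducer="count",
                                 threshold=10.0)
        assert table.loc["frontal", "frontal"] == 1
        assert table.to_numpy().sum() == 1

    def test_empty_edge_list_all_zero_table(self):
        s = _toy_summary(np.zeros((3, 3)), ["F7", "FT7", "Cz"])
        table = region_aggregate(s, Montage(labels=["F7", "FT7", "Cz"]),
                                 threshold=10.0)
        assert (table.to_numpy() == 0).all()

    def test_sum_equals_mean_times_count(self):
        rng = np.random.default_rng(91)
        labels = ["Fp1", "Fp2", "Cz", "O1", "T7", "P3"]
        s = _toy_summary(rng.uniform(5, 40, (6, 6)), labels)
        mont = Montage(labels=labels)
        kw = dict(threshold=15.0)
        total = region_aggregate(s, mont, "sum", **kw).to_numpy()
        mean = region_aggregate(s, mont, "mean", **kw).to_numpy()
        count = region_aggregate(s, mont, "count", **kw).to_numpy()
        np.testing.assert_allclose(total, mean * count, atol=1e-9)

    def test_unmapped_channel_named_in_error(self):
        s = _toy_summary(np.zeros((2, 2)), ["F7", "XX1"])
        with pytest.raises(KeyError, match="XX1"):
            region_aggregate(s, Montage(labels=["F7"]))


class TestDifferenceMatrix:
    def test_self_difference_is_zero_with_no_markers(self):
        rng = np.random.default_rng(95)
        s = _toy_summary(rng.uniform(10, 30, (4, 4)), list("abcd"))
        d = difference_matrix(s, s)
        assert np.nanmax(np.abs(d.diff_F)) == 0
        assert (d.marker == "").all()
        assert not d.star.any()

    def test_color_specific_robust_pair_marked_c(self):
        labels = list("abc")
        robust_c = np.zeros((3, 3), bool)
        robust_c[1, 0] = True
        color = _toy_summary(np.full((3, 3), 20.0), labels, robust=robust_c)
        lexical = _toy_summary(np.full((3, 3), 15.0), labels)
        d = difference_matrix(color, lexical)
        assert d.marker[1, 0] == "C"
        assert (d.marker == "C").sum() == 1
        # C and L are mutually exclusive per pair by construction
        assert not ((d.marker == "C") & (d.marker == "L")).any()

    def test_antisymmetric_in_argument_order(self):
        rng = np.random.default_rng(96)
        a = _toy_summary(rng.uniform(10, 30, (4, 4)), list("abcd"),
                         subj=rng.uniform(10, 30, (6, 4, 4)))
        b = _toy_summary(rng.uniform(10, 30, (4, 4)), list("abcd"),
                         subj=rng.uniform(10, 30, (6, 4, 4)))
        dab = difference_matrix(a, b)
        dba = difference_matrix(b, a)
        np.testing.assert_allclose(dab.diff_F, -dba.diff_F, equal_nan=True)

    def test_channel_mismatch_errors(self):
        a = _toy_summary(np.zeros((2, 2)), ["a", "b"])
        b = _toy_summary(np.zeros((2, 2)), ["a", "c"])
        with pytest.raises(ValueError, match="differ"):
            difference_matrix(a, b)

    def test_consistent_paired_shift_earns_stars(self):
        rng = np.random.default_rng(97)
        base = rng.uniform(10, 20, (12, 3, 3))
        labels = list("abc")
        lex = _toy_summary(base.mean(0), labels, subj=base)
        shifted = base + 5.0  # every subject higher under color
        col = _toy_summary(shifted.mean(0), labels, subj=shifted)
        d = difference_matrix(col, lex)
        assert d.star[~np.eye(3, dtype=bool)].all()


class TestGroupModelFrontend:
    def test_fit_reports_robust_edges_and_summary(self):
        gr = GroupConnectivity(_cohort(40)).fit()
        assert gr.robust_edges == [("ch0", "ch1")]
        text = gr.summary()
        assert "robust connections" in text
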