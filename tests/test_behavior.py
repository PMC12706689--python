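"""Nonparametric behavioral battery vs hand computations and scipy oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as ss

from cueconn import (chi_square_independence, dunn_posthoc, generate_trials,
                     kruskal_wallis, mann_whitney_u, rank_correlations,
                     run_battery)


class TestChiSquare:
    def test_naming_accuracy_contingency_table(self):
        # 2x3 cue-by-response count table of the odor naming task
        r = chi_square_independence([[442, 740, 258], [439, 238, 763]])
        assert r.statistic == pytest.approx(507.463, abs=0.01)
        assert r.df == 2
        assert r.pvalue < 0.001
        assert r.n == 2880

    def test_proportional_rows_give_zero(self):
        r = chi_square_independence([[10, 20, 30], [20, 40, 60]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_2x2_hand_value(self):
        r = chi_square_independence([[10, 0], [0, 10]])
        assert r.statistic == pytest.approx(20.0)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="zero row or column"):
            chi_square_independence([[0, 0], [5, 5]])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.integers(1, 50), min_size=3, max_size=3),
                    min_size=2, max_size=2))
    def test_invariant_under_permutation_and_transpose(self, rows):
        t = np.array(rows)
        base = chi_square_independence(t).statistic
        assert chi_square_independence(t[::-1]).statistic == pytest.approx(base)
        assert chi_square_independence(t[:, ::-1]).statistic == pytest.approx(base)
        assert chi_square_independence(t.T).statistic == pytest.approx(base)


class TestMannWhitney:
    def test_complete_separation_and_conservation(self):
        r_x = mann_whitney_u([1, 2], [3, 4])
        r_y = mann_whitney_u([3, 4], [1, 2])
        assert r_x.statistic == 0.0
        assert r_x.statistic + r_y.statistic == 4.0  # n1 * n2

    def test_exact_p_matches_enumeration_with_ties(self):
        x = [1.0, 2.0, 2.0, 5.0]
        y = [2.0, 3.0, 4.0, 6.0]
        r = mann_whitney_u(x, y)
        # independent enumeration over all C(8,4)=70 assignments
        combined = np.array(x + y)
        ranks = ss.rankdata(combined)
        n1 = 4
        mu = 4 * 4 / 2.0
        u_obs = ss.rankdata(combined)[:4].sum() - n1 * (n1 + 1) / 2.0
        count = 0
        for subset in itertools.combinations(range(8), 4):
            u = ranks[list(subset)].sum() - n1 * (n1 + 1) / 2.0
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
        assert r.pvalue == pytest.approx(count / 70.0)

    def test_asymptotic_matches_scipy_with_ties(self):
        rng = np.random.default_rng(7)
        x = rng.integers(1, 10, 40).astype(float)
        y = rng.integers(1, 12, 35).astype(float)
        r = mann_whitney_u(x, y)
        sp = ss.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
        assert r.statistic == pytest.approx(sp.statistic)
        assert r.pvalue == pytest.approx(sp.pvalue, abs=1e-10)

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(8)
        rejections = sum(
            mann_whitney_u(rng.standard_normal(50),
                           rng.standard_normal(50)).pvalue < 0.05
            for _ in range(500)
        )
        assert 0.03 <= rejections / 500 <= 0.07

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_hand_formula_on_three_clean_groups(self):
        # rank sums 6, 15, 24 -> H = (12/90)(12+75+192) - 30 = 7.2
        r = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert r.statistic == pytest.approx(7.2)
        assert r.df == 2

    def test_all_identical_returns_zero_by_convention(self):
        r = kruskal_wallis([[3, 3], [3, 3], [3, 3]])
        assert r.statistic == 0.0

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(9)
        groups = [rng.integers(1, 6, 25).astype(float) for _ in range(3)]
        r = kruskal_wallis(groups)
        sp = ss.kruskal(*groups)
        assert r.statistic == pytest.approx(sp.statistic, abs=1e-10)
        assert r.pvalue == pytest.approx(sp.pvalue, abs=1e-10)

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(10)
        rejections = sum(
            kruskal_wallis([rng.standard_normal(20) for _ in range(3)]).pvalue
            < 0.05
            for _ in range(500)
        )
        assert 0.03 <= rejections / 500 <= 0.07

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty"):
            kruskal_wallis([[1, 2], []])


def _dunn_oracle_z(groups, i, j):
    """Independently coded Dunn z on pooled tie-corrected variance."""
    allv = np.concatenate(groups)
    ranks = ss.rankdata(allv)
    sizes = [len(g) for g in groups]
    starts = np.cumsum([0] + sizes)
    mean_ranks = [ranks[starts[k]:starts[k + 1]].mean()
                  for k in range(len(groups))]
    N = allv.size
    _, t = np.unique(allv, return_counts=True)
    var = N * (N + 1) / 12.0 - ((t ** 3 - t).sum()) / (12.0 * (N - 1))
    se = np.sqrt(var * (1 / sizes[i] + 1 / sizes[j]))
    return (mean_ranks[i] - mean_ranks[j]) / se


class TestDunnPosthoc:
    def test_identical_groups_all_adjusted_p_one(self):
        res = dunn_posthoc([[1, 2, 3]] * 3)
        assert all(r.pvalue == 1.0 for r in res)

    def test_three_groups_three_bonferroni_comparisons(self):
        res = dunn_posthoc([[1, 2], [3, 4], [5, 6]])
        assert len(res) == 3
        assert all(r.extra["comparisons"] == 3 for r in res)

    def test_z_matches_rank_oracle(self):
        rng = np.random.default_rng(11)
        groups = [rng.integers(1, 8, n).astype(float) for n in (12, 15, 9)]
        res = dunn_posthoc(groups)
        for r, (i, j) in zip(res, itertools.combinations(range(3), 2)):
            assert r.statistic == pytest.approx(_dunn_oracle_z(groups, i, j),
                                                abs=1e-8)

    def test_two_groups_redirects_to_mann_whitney(self):
        with pytest.raises(ValueError, match="mann_whitney"):
            dunn_posthoc([[1, 2], [3, 4]])


class TestRankCorrelations:
    def test_perfect_concordance(self):
        sp, kd = rank_correlations([1, 2, 3, 4], [10, 20, 30, 40])
        assert sp.statistic == pytest.approx(1.0)
        assert kd.statistic == pytest.approx(1.0)

    def test_perfect_discordance(self):
        sp, kd = rank_correlations([1, 2, 3, 4], [40, 30, 20, 10])
        assert sp.statistic == pytest.approx(-1.0)
        assert kd.statistic == pytest.approx(-1.0)

    def test_tau_b_matches_pair_count_oracle_with_ties(self):
        rng = np.random.default_rng(12)
        a = rng.integers(1, 6, 20).astype(float)
        b = rng.integers(1, 6, 20).astype(float)
        _, kd = rank_correlations(a, b)
        conc = disc = ties_a = ties_b = 0
        for i in range(20):
            for j in range(i + 1, 20):
                da, db = a[i] - a[j], b[i] - b[j]
                if da == 0 and db == 0:
                    continue
                elif da == 0:
                    ties_a += 1
                elif db == 0:
                    ties_b += 1
                elif da * db > 0:
                    conc += 1
                else:
                    disc += 1
        n0 = 20 * 19 / 2
        n1 = sum(t * (t - 1) / 2 for t in np.unique(a, return_counts=True)[1])
        n2 = sum(t * (t - 1) / 2 for t in np.unique(b, return_counts=True)[1])
        tau_oracle = (conc - disc) / np.sqrt((n0 - n1) * (n0 - n2))
        assert kd.statistic == pytest.approx(tau_oracle, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(13)
        a = rng.integers(1, 9, 200).astype(float)
        b = a * 0.3 + rng.standard_normal(200) * 2
        sp, kd = rank_correlations(a, b)
        sp_ref = ss.spearmanr(a, b)
        kd_ref = ss.kendalltau(a, b)
        assert sp.statistic == pytest.approx(sp_ref.statistic, abs=1e-12)
        assert sp.pvalue == pytest.approx(sp_ref.pvalue, rel=1e-6)
        assert kd.statistic == pytest.approx(kd_ref.statistic, abs=1e-12)
        assert kd.pvalue == pytest.approx(kd_ref.pvalue, rel=1e-6)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            rank_correlations([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="equal length"):
            rank_correlations([1, 2], [1, 2, 3])


class TestBattery:
    def test_full_battery_runs_on_generated_table(self):
        trials = generate_trials(10, seed=14)
        out = run_battery(trials)
        assert {"chi_square_independence"} <= set(out["test"])
        assert out["p"].between(0, 1).all()
        # cue effect at the observed rates is overwhelming
        chi_row = out.loc[out["test"] == "chi_square_independence"].iloc[0]
        assert chi_row["p"] < 0.001

    def test_no_systematic_rejections_with_effects_off(self):
        trials = generate_trials(
            10,
            accuracy_by_cue=(0.3, 0.3),
            no_answer_by_cue=(0.3, 0.3),
            rating_effects={"acc_familiarity": 0.0, "acc_liking": 0.0,
                            "rt_familiarity": 0.0, "rt_liking": 0.0},
            seed=15,
        )
        out = run_battery(trials)
        # with all structure removed, at most a small fraction rejects
        assert out["significant"].mean() <= 0.15
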