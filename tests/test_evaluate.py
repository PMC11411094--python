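"""Summary marginals against the published six-cow table, blocked ANOVA and
paired contrasts against independent oracles, and recovery scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from calvesig import (
    cv_percent,
    omnibus_compare,
    paired_difference,
    pairwise_compare,
    recovery,
    summarize,
)
from calvesig.datasets import remaining_hours_matrix


@pytest.fixture(scope="module")
def matrix():
    return remaining_hours_matrix()


class TestSummarize:
    @pytest.mark.parametrize(
        "row, mean, sd",
        [("SMA", 54.1, 11.3), ("MAD", 58.7, 12.3), ("MACD", 55.5, 11.4),
         ("RSI", 55.7, 11.9)],
    )
    def test_row_marginals_match_published_table(self, matrix, row, mean, sd):
        table = summarize(matrix)
        assert table.row_mean[row] == pytest.approx(mean, abs=0.051)
        assert table.row_sd[row] == pytest.approx(sd, abs=0.051)

    @pytest.mark.parametrize(
        "col, mean, sd",
        [("h021", 54.6, 1.6), ("h045", 72.4, 2.7), ("h057", 62.8, 2.2),
         ("h055", 42.8, 0.35), ("h058", 44.3, 2.2), ("h886", 53.1, 9.8)],
    )
    def test_column_marginals_match_published_table(self, matrix, col, mean, sd):
        table = summarize(matrix)
        assert table.col_mean[col] == pytest.approx(mean, abs=0.051)
        assert table.col_sd[col] == pytest.approx(sd, abs=0.051)

    def test_single_cell_column_has_no_sd(self):
        m = pd.DataFrame({"s1": [10.0, np.nan]}, index=["MAD", "MACD"])
        table = summarize(m)
        assert table.col_mean["s1"] == 10.0
        assert np.isnan(table.col_sd["s1"])


class TestCV:
    def test_h886_column(self, matrix):
        assert cv_percent(matrix["h886"]) == pytest.approx(18.5, abs=0.05)

    def test_identical_values_zero(self):
        assert cv_percent([50.0, 50.0, 50.0]) == 0.0

    def test_hand_computed(self):
        assert cv_percent([10.0, 20.0]) == pytest.approx(100 * np.sqrt(50) / 15,
                                                         rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            cv_percent([5.0])
        with pytest.raises(ValueError):
            cv_percent([-10.0, 10.0])


class TestOmnibus:
    def test_identical_rows_degenerate(self):
        m = pd.DataFrame(
            [[50.0, 60.0, 55.0], [50.0, 60.0, 55.0], [50.0, 60.0, 55.0]],
            index=["MAD", "MACD", "RSI"], columns=["a", "b", "c"],
        )
        res = omnibus_compare(m)
        assert res.omnibus_f == 0.0

    def test_matches_brute_force_anova_oracle(self):
        rng = np.random.default_rng(31)
        subj = rng.normal(0, 5, 5)
        effect = np.array([3.0, 0.0, -1.0])
        y = 50.0 + effect[:, None] + subj[None, :] + rng.normal(0, 1, (3, 5))
        m = pd.DataFrame(y, index=["MAD", "MACD", "RSI"],
                         columns=[f"s{i}" for i in range(5)])
        res = omnibus_compare(m)
        # oracle: explicit sums of squares, independently coded
        grand = y.mean()
        ss_t = 5 * sum((y[i].mean() - grand) ** 2 for i in range(3))
        ss_b = 3 * sum((y[:, j].mean() - grand) ** 2 for j in range(5))
        ss_e = ((y - grand) ** 2).sum() - ss_t - ss_b
        f_oracle = (ss_t / 2) / (ss_e / 8)
        assert res.omnibus_f == pytest.approx(f_oracle, rel=1e-8)
        assert res.df_num == 2 and res.df_den == 8
        assert res.omnibus_p == pytest.approx(stats.f.sf(f_oracle, 2, 8), rel=1e-8)

    def test_block_permutation_invariance(self):
        rng = np.random.default_rng(8)
        y = 50.0 + rng.normal(0, 3, (3, 6))
        m = pd.DataFrame(y, index=["MAD", "MACD", "RSI"],
                         columns=list("abcdef"))
        res1 = omnibus_compare(m)
        res2 = omnibus_compare(m[list("fedcba")])
        assert res1.omnibus_f == pytest.approx(res2.omnibus_f, rel=1e-12)

    def test_incomplete_subjects_dropped(self, matrix):
        res = omnibus_compare(matrix)
        assert "h055" not in res.subjects_used
        assert len(res.subjects_used) == 5

    def test_unbalanced_mixed_model_path_runs(self, matrix):
        res = omnibus_compare(matrix, exclude_incomplete=False)
        assert res.method == "mixed_model"
        assert len(res.subjects_used) == 6
        assert res.omnibus_f > 0 and 0 < res.omnibus_p <= 1


class TestPairwise:
    def test_published_mad_macd_f_on_complete_cows(self, matrix):
        complete = [c for c in matrix.columns if c != "h055"]
        f, p = pairwise_compare(matrix, ("MAD", "MACD"), subjects=complete)
        assert f == pytest.approx(152.11, abs=0.01)
        assert p < 0.001

    def test_published_six_cow_paired_difference(self, matrix):
        mean, sd, n = paired_difference(matrix, ("MAD", "MACD"))
        assert n == 6
        assert mean == pytest.approx(3.17, abs=0.005)
        assert sd == pytest.approx(1.44, abs=0.005)

    def test_f_equals_squared_paired_t(self, matrix):
        for pair in [("MAD", "MACD"), ("MAD", "RSI"), ("MACD", "RSI")]:
            f, p = pairwise_compare(matrix, pair)
            sub = matrix.loc[list(pair)].dropna(axis=1)
            t, p_t = stats.ttest_rel(sub.iloc[0], sub.iloc[1])
            assert f == pytest.approx(t**2, rel=1e-10)
            assert p == pytest.approx(p_t, rel=1e-10)

    def test_identical_columns_degenerate(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]],
                         index=["MAD", "MACD"], columns=list("abc"))
        with pytest.warns(UserWarning):
            f, p = pairwise_compare(m, ("MAD", "MACD"))
        assert f == 0.0


class TestRecovery:
    def test_perfect_detector(self):
        rep = recovery([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert rep.bias_h == 0.0 and rep.rmse_h == 0.0
        assert rep.proportion_within == 1.0

    def test_constant_offset(self):
        rep = recovery([11.0, 21.0], [10.0, 20.0], tolerance=2.0)
        assert rep.bias_h == pytest.approx(1.0)
        assert rep.rmse_h == pytest.approx(1.0)
        assert rep.proportion_within == 1.0

    def test_missing_detections_count_as_failures(self):
        rep = recovery([10.0, None], [10.0, 20.0])
        assert rep.n_no_signal == 1
        assert rep.proportion_within == 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            recovery([1.0], [1.0, 2.0])
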