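"""Contingency statistics: tabulation, chi-square, adjusted residuals,
proportions and Kruskal-Wallis, checked against independent oracles."""

from fractions import Fraction
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import brainmets as bm
from brainmets.stats import AnalysisConfig, ContingencyTable


def exact_adjusted_residuals(observed: np.ndarray) -> np.ndarray:
    """Spreadsheet-style oracle with exact rational arithmetic until the sqrt."""
    O = observed
    n_rows, n_cols = O.shape
    N = int(O.sum())
    row = [int(O[i].sum()) for i in range(n_rows)]
    col = [int(O[:, j].sum()) for j in range(n_cols)]
    out = np.zeros(O.shape)
    for i in range(n_rows):
        for j in range(n_cols):
            E = Fraction(row[i] * col[j], N)
            var = E * (1 - Fraction(row[i], N)) * (1 - Fraction(col[j], N))
            if var == 0:
                out[i, j] = 0.0
            else:
                out[i, j] = float((Fraction(int(O[i, j])) - E) / Fraction(math.sqrt(var)))
    return out


class TestTabulate:
    def test_example_cerebellum_row(self, example_table):
        row = example_table.observed.loc["cerebellum"]
        assert int(row.sum()) == 143
        assert list(row[["luminal A", "luminal B", "HER2", "TNBC"]]) == [64, 18, 48, 13]

    def test_counts_from_records_conserve_total(self):
        records = bm.datasets.example_records()
        table = bm.tabulate(records, list(bm.CANONICAL_REGIONS), list(bm.SUBTYPES))
        assert table.grand_total == len(records) == 437

    def test_unassigned_records_excluded_with_warning(self, caplog):
        frame = pd.DataFrame(
            {
                "patient_id": ["a", "a", "b"],
                "subtype": ["HER2", "HER2", "TNBC"],
                "region": ["cerebellum", "unassigned", "putamen"],
            }
        )
        with caplog.at_level("WARNING", logger="brainmets.stats"):
            table = bm.tabulate(frame, list(bm.CANONICAL_REGIONS), list(bm.SUBTYPES))
        assert table.grand_total == 2
        assert "unassigned" in caplog.text

    def test_empty_region_list_rejected(self):
        with pytest.raises(ValueError):
            bm.tabulate(pd.DataFrame(columns=["patient_id", "subtype", "region"]), [], ["HER2"])

    def test_no_records_gives_all_zero_table(self):
        frame = pd.DataFrame(columns=["patient_id", "subtype", "region"])
        table = bm.tabulate(frame, list(bm.CANONICAL_REGIONS), list(bm.SUBTYPES))
        assert table.grand_total == 0
        assert table.observed.shape == (11, 4)


class TestChiSquare:
    def test_hand_computed_2x2(self):
        # all expected counts are 15, so X2 = 4 * 25/15 = 20/3
        table = ContingencyTable(pd.DataFrame([[10, 20], [20, 10]]))
        res = bm.chi_square_independence(table)
        assert res.statistic == pytest.approx(20 / 3, abs=1e-12)
        assert res.df == 1
        assert res.p == pytest.approx(sps.chi2.sf(20 / 3, 1), rel=1e-12)
        assert res.p == pytest.approx(0.0098, abs=5e-5)

    def test_proportional_rows_give_zero_statistic(self):
        table = ContingencyTable(pd.DataFrame([[10, 20], [5, 10]]))
        res = bm.chi_square_independence(table)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            O = rng.integers(1, 40, size=(rng.integers(2, 6), rng.integers(2, 5)))
            res = bm.chi_square_independence(ContingencyTable(pd.DataFrame(O)))
            ref = sps.chi2_contingency(O, correction=False)
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_invariant_under_row_and_column_permutation(self, example_table):
        base = bm.chi_square_independence(example_table)
        rng = np.random.default_rng(2)
        obs = example_table.observed
        perm = obs.iloc[rng.permutation(len(obs)), rng.permutation(obs.shape[1])]
        res = bm.chi_square_independence(ContingencyTable(perm))
        assert res.statistic == pytest.approx(base.statistic, rel=1e-12)

    def test_empty_rows_dropped_with_warning(self, caplog):
        O = pd.DataFrame([[5, 10], [0, 0], [10, 5]], index=["a", "b", "c"])
        with caplog.at_level("WARNING", logger="brainmets.stats"):
            res = bm.chi_square_independence(ContingencyTable(O))
        assert res.dropped_rows == ["b"]
        assert res.df == 1

    def test_degenerate_table_rejected(self):
        O = pd.DataFrame([[5, 10], [0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            bm.chi_square_independence(ContingencyTable(O))

    def test_monte_carlo_agrees_with_analytic_when_expected_adequate(self):
        O = pd.DataFrame([[30, 20, 25], [18, 28, 24], [22, 25, 30]])
        cfg = AnalysisConfig(mc_reps=4000, seed=8)
        res = bm.chi_square_independence(ContingencyTable(O), cfg)
        E = np.outer(O.sum(1), O.sum(0)) / O.to_numpy().sum()
        assert E.min() >= 5
        se = math.sqrt(res.p * (1 - res.p) / cfg.mc_reps)
        assert abs(res.p_monte_carlo - res.p) <= 3 * se + 1e-9

    def test_yates_correction_reduces_2x2_statistic(self):
        table = ContingencyTable(pd.DataFrame([[10, 20], [20, 10]]))
        plain = bm.chi_square_independence(table)
        yates = bm.chi_square_independence(table, AnalysisConfig(continuity=True))
        assert yates.statistic < plain.statistic


class TestAdjustedResiduals:
    def test_match_exact_fraction_oracle_on_example(self, example_table):
        oracle = exact_adjusted_residuals(example_table.observed.to_numpy())
        resid = bm.adjusted_residuals(example_table)
        assert np.allclose(resid.adjusted.to_numpy(), oracle, atol=1e-9)

    def test_match_oracle_on_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            O = rng.integers(0, 30, size=(4, 3))
            if O.sum() == 0:
                continue
            resid = bm.adjusted_residuals(ContingencyTable(pd.DataFrame(O)))
            assert np.allclose(resid.adjusted.to_numpy(), exact_adjusted_residuals(O), atol=1e-9)

    def test_raw_residual_margins_vanish(self, example_table):
        resid = bm.adjusted_residuals(example_table)
        assert np.allclose(resid.raw.sum(axis=0), 0, atol=1e-9)
        assert np.allclose(resid.raw.sum(axis=1), 0, atol=1e-9)
        assert resid.expected.to_numpy().sum() == pytest.approx(example_table.grand_total)

    def test_proportional_table_has_zero_residuals(self):
        resid = bm.adjusted_residuals(ContingencyTable(pd.DataFrame([[10, 20], [5, 10]])))
        assert np.allclose(resid.adjusted.to_numpy(), 0, atol=1e-9)

    def test_zero_expected_cell_gets_zero_residual_and_warning(self, caplog):
        O = pd.DataFrame([[5, 0], [10, 0], [3, 4]])
        with caplog.at_level("WARNING", logger="brainmets.stats"):
            resid = bm.adjusted_residuals(ContingencyTable(O))
        assert np.isfinite(resid.adjusted.to_numpy()).all()

    def test_flags_carry_direction(self, example_table):
        flags = bm.flag_significant(bm.adjusted_residuals(example_table))
        assert ("cerebellum", "luminal B", "over") in flags
        assert ("cerebellum", "HER2", "under") in flags


class TestGroupProportions:
    def test_example_percentages(self, example_table):
        pct = bm.group_proportions(example_table)
        assert pct.loc["cerebellum", "all"] == 32.7
        assert pct.loc["cerebellum", "luminal B"] == 60.0
        assert pct.loc["putamen", "HER2"] == 7.1

    def test_half_up_rounding_at_boundary(self):
        # 3/2000 = 0.15% exactly: half-up gives 0.2, bankers would give 0.2/0.1 split
        O = pd.DataFrame({"g": [3, 1997]}, index=["a", "b"])
        pct = bm.group_proportions(ContingencyTable(O))
        assert pct.loc["a", "g"] == 0.2

    def test_zero_column_total_blank_with_warning(self, caplog):
        O = pd.DataFrame({"g1": [3, 4], "g2": [0, 0]})
        with caplog.at_level("WARNING", logger="brainmets.stats"):
            pct = bm.group_proportions(ContingencyTable(O))
        assert pct["g2"].isna().all()
        assert not pct["g1"].isna().any()

    def test_empty_table_all_blank(self, caplog):
        O = pd.DataFrame({"g": [0, 0]})
        with caplog.at_level("WARNING", logger="brainmets.stats"):
            pct = bm.group_proportions(ContingencyTable(O))
        assert pct.isna().all().all()


def brute_force_kruskal(groups):
    """Direct rank computation of the tie-corrected H statistic."""
    allvals = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    order = np.argsort(allvals, kind="mergesort")
    ranks = np.empty(len(allvals))
    sorted_vals = allvals[order]
    i = 0
    pos = 0
    while i < len(sorted_vals):
        j = i
        while j < len(sorted_vals) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    N = len(allvals)
    start = 0
    H = 0.0
    for g in groups:
        n = len(g)
        H += np.sum(ranks[start:start + n]) ** 2 / n
        start += n
    H = 12.0 / (N * (N + 1)) * H - 3 * (N + 1)
    # tie correction
    _, counts = np.unique(sorted_vals, return_counts=True)
    correction = 1 - np.sum(counts ** 3 - counts) / (N ** 3 - N)
    return H / correction


class TestKruskalWallis:
    def test_identical_groups_give_null_result(self):
        H, p = bm.kruskal_wallis([[3, 3, 3], [3, 3], [3, 3, 3, 3]])
        assert (H, p) == (0.0, 1.0)

    def test_matches_rank_oracle(self):
        groups = [[1, 2, 3], [4, 5, 6]]
        H, p = bm.kruskal_wallis(groups)
        assert H == pytest.approx(brute_force_kruskal(groups), rel=1e-12)
        assert p == pytest.approx(sps.chi2.sf(H, 1), rel=1e-12)

    def test_matches_rank_oracle_with_ties(self):
        groups = [[1.0, 2.0, 2.0, 5.0], [2.0, 3.0, 4.0], [0.5, 2.0, 6.0, 6.0]]
        H, _ = bm.kruskal_wallis(groups)
        assert H == pytest.approx(brute_force_kruskal(groups), rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bm.kruskal_wallis([[1, 2], [], [3, 4]])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            bm.kruskal_wallis([[1, 2, 3]])
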