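import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

import cometh as cm
from cometh.track import STATES


def oracle_chi_square(obs: np.ndarray) -> tuple[float, int]:
    """Direct cell-by-cell evaluation of the Pearson formula."""
    obs = np.asarray(obs, dtype=float)
    total = obs.sum()
    stat = 0.0
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            e = obs[i].sum() * obs[:, j].sum() / total
            stat += (obs[i, j] - e) ** 2 / e
    return stat, (obs.shape[0] - 1) * (obs.shape[1] - 1)


def make_ct(rows: dict[str, list[float]], state="A") -> cm.ContingencyTable:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(STATES))
    return cm.ContingencyTable(state, df)


@pytest.fixture(scope="module")
def spleen_tables():
    return cm.spleen_transition_tables()


class TestBuildContingency:
    def test_rows_are_the_published_initial_state_counts(self, spleen_tables):
        ct = cm.build_contingency(spleen_tables, "A")
        assert ct.counts.loc["STL001"].tolist() == [159513, 12082, 7505, 16928]
        assert ct.counts.loc["STL002"].tolist() == [170787, 13663, 9638, 18661]
        assert ct.counts.loc["STL003"].tolist() == [209282, 13179, 8953, 17408]

    def test_fewer_than_two_samples_rejected(self, spleen_tables):
        with pytest.raises(cm.UsageError):
            cm.build_contingency(spleen_tables[:1], "A")

    def test_zero_row_rejected_naming_sample(self):
        def empty_table(label):
            return cm.count_transitions(pd.DataFrame(
                {"initial": [], "terminal": [], "distance": []}), label)
        with pytest.raises(cm.UsageError, match="e1"):
            cm.build_contingency([empty_table("e1"), empty_table("e2")], "A")

    def test_row_sums_match_per_sample_totals(self, spleen_tables):
        ct = cm.build_contingency(spleen_tables, "C")
        for t in spleen_tables:
            assert ct.counts.loc[t.sample_id].sum() == t.row_totals["C"]


class TestPearsonChiSquare:
    @pytest.mark.parametrize(
        "state, expected",
        [("A", 1323.14), ("B", 1056.65), ("C", 1492.95), ("D", 9013.65)],
    )
    def test_reproduces_published_spleen_statistics(
        self, spleen_tables, state, expected
    ):
        res = cm.pearson_chi_square(cm.build_contingency(spleen_tables, state))
        assert res.statistic == pytest.approx(expected, abs=0.015)
        assert res.df == 6

    def test_proportional_rows_give_zero_statistic(self):
        ct = make_ct({"s1": [10, 20, 30, 40], "s2": [20, 40, 60, 80]})
        res = cm.pearson_chi_square(ct)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_by_two_matches_hand_oracle(self):
        obs = np.array([[10, 20], [30, 40]], dtype=float)
        df = pd.DataFrame(obs, index=["s1", "s2"], columns=["A", "B"])
        res = cm.pearson_chi_square(cm.ContingencyTable("A", df))
        stat, dof = oracle_chi_square(obs)
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert res.df == dof

    def test_agrees_with_scipy_on_random_tables(self, rng):
        for _ in range(200):
            obs = rng.integers(1, 500, size=(rng.integers(2, 5), 4))
            df = pd.DataFrame(obs, index=[f"s{i}" for i in range(len(obs))],
                              columns=list(STATES))
            res = cm.pearson_chi_square(cm.ContingencyTable("A", df))
            ref = chi2_contingency(obs, correction=False)
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-300)
            assert res.df == ref.dof

    def test_expected_counts_conserve_total(self, spleen_tables):
        ct = cm.build_contingency(spleen_tables, "B")
        res = cm.pearson_chi_square(ct)
        assert res.expected.to_numpy().sum() == pytest.approx(
            ct.counts.to_numpy().sum()
        )

    def test_low_expected_warning_flag(self):
        ct = make_ct({"s1": [1, 1, 1, 1], "s2": [1, 1, 1, 1]})
        assert cm.pearson_chi_square(ct).low_expected_warning


class TestContributions:
    def test_published_cell_contributions(self, spleen_tables):
        contrib_a = cm.cell_contributions(cm.build_contingency(spleen_tables, "A"))
        assert contrib_a.cells.loc["STL001", "A"] == pytest.approx(11.07, abs=0.005)
        contrib_d = cm.cell_contributions(cm.build_contingency(spleen_tables, "D"))
        assert contrib_d.cells.loc["STL001", "C"] == pytest.approx(4666.12, abs=0.005)

    def test_contributions_sum_to_statistic(self, spleen_tables):
        for state in STATES:
            ct = cm.build_contingency(spleen_tables, state)
            res = cm.pearson_chi_square(ct)
            contrib = cm.cell_contributions(ct)
            assert contrib.total == pytest.approx(res.statistic, rel=1e-9)
            assert contrib.by_sample.sum() == pytest.approx(res.statistic, rel=1e-9)
            assert contrib.by_terminal_state.sum() == pytest.approx(
                res.statistic, rel=1e-9
            )

    def test_proportional_rows_have_zero_contributions(self):
        ct = make_ct({"s1": [10, 20, 30, 40], "s2": [20, 40, 60, 80]})
        assert np.allclose(cm.cell_contributions(ct).cells, 0.0)


class TestScaling:
    def test_default_rounding_is_half_away_from_zero(self, spleen_tables):
        ct = cm.build_contingency(spleen_tables, "A")
        scaled = cm.scale_counts(ct, 10)
        assert scaled.counts.loc["STL001", "A"] == 15951
        assert cm.scale_counts(ct, 1).counts.equals(ct.counts.astype(float))

    def test_half_away_rounding_on_exact_halves(self):
        ct = make_ct({"s1": [15, 25, 35, 45], "s2": [10, 10, 10, 10]})
        scaled = cm.scale_counts(ct, 10)
        assert scaled.counts.loc["s1"].tolist() == [2, 3, 4, 5]

    def test_nonpositive_divisor_rejected(self, spleen_tables):
        ct = cm.build_contingency(spleen_tables, "A")
        with pytest.raises(cm.UsageError):
            cm.scale_counts(ct, 0)

    def test_statistic_homogeneous_without_rounding(self, spleen_tables):
        # X^2(O / n) == X^2(O) / n exactly when counts stay fractional
        ct = cm.build_contingency(spleen_tables, "D")
        base = cm.pearson_chi_square(ct).statistic
        for n in (10, 100, 1000):
            scaled = cm.scale_counts(ct, n, rounding="none")
            assert cm.pearson_chi_square(scaled).statistic == pytest.approx(
                base / n, rel=1e-12
            )


class TestSensitivityScan:
    def test_division_one_row_matches_full_test(self, spleen_tables):
        scan = cm.sensitivity_scan(spleen_tables, "A")
        assert scan[1].statistic == pytest.approx(1323.14, abs=0.015)

    def test_thousandfold_division_reaches_published_null_result(
        self, spleen_tables
    ):
        # with half-away rounding, the state-A test on counts divided by
        # 1000 lands on the published end of the scan: X2 = 1.64, p = 0.95
        res = cm.sensitivity_scan(spleen_tables, "A")[1000]
        assert res.statistic == pytest.approx(1.64, abs=0.005)
        assert res.p_value == pytest.approx(0.95, abs=0.005)

    def test_p_values_become_less_significant(self, spleen_tables):
        for state in STATES:
            scan = cm.sensitivity_scan(spleen_tables, state)
            ps = [r.p_value for r in scan.values() if r is not None]
            assert ps == sorted(ps)

    def test_min_expected_flag_raised_at_large_divisors(self, spleen_tables):
        scan = cm.sensitivity_scan(spleen_tables, "B", divisors=(1, 100_000))
        assert not scan[1].low_expected_warning
        assert scan[100_000] is None or scan[100_000].low_expected_warning


class TestPairwise:
    def test_three_samples_give_three_pairs(self, spleen_tables):
        pw = cm.pairwise_chi_square(spleen_tables, "A")
        assert set(pw) == {
            ("STL001", "STL002"), ("STL001", "STL003"), ("STL002", "STL003")
        }
        for res in pw.values():
            assert res.df == 3

    def test_identical_tables_give_zero(self, spleen_tables):
        t = spleen_tables[0]
        t2 = cm.TransitionCountTable("copy", t.counts.copy())
        res = cm.pairwise_chi_square([t, t2], "A")[("STL001", "copy")]
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_pairwise_equals_direct_test_on_row_subset(self, spleen_tables):
        pw = cm.pairwise_chi_square(spleen_tables, "A")
        a, b = spleen_tables[0], spleen_tables[1]
        obs = np.vstack([
            a.counts.loc["A"].to_numpy(), b.counts.loc["A"].to_numpy()
        ])
        stat, dof = oracle_chi_square(obs)
        res = pw[(a.sample_id, b.sample_id)]
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert res.df == dof
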