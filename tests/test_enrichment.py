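"""Contingency tables, chi-square/G/Fisher tests, residuals, frequencies."""

import math
from itertools import product

import numpy as np
import pytest
from scipy.special import comb

from ycnv import defaults
from ycnv.enrichment import (
    ContingencyTable,
    DegenerateTableError,
    build_table,
    fisher_exact,
    frequency_report,
    frequency_report_from_counts,
    g_test,
    pearson_chi_square,
    residuals,
)


def table1_variant_table(variant):
    t1 = defaults.load_table1_counts()
    carriers = t1[variant]
    rows = np.column_stack([carriers, t1["n"] - carriers]).astype(np.int64)
    return ContingencyTable.from_array(
        rows, rows=list(t1.index), cols=["carrier", "non_carrier"]
    )


def enumerate_fisher_2x2(a, b, c, d):
    """Exhaustive two-sided Fisher p over all tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True) / comb(
            n, c1, exact=True
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


class TestBuildTable:
    def test_no_carriers_gives_zero_column(self):
        hg = {"s1": "A", "s2": "A", "s3": "B"}
        t = build_table(hg, {}, "v")
        assert (t.values[:, 0] == 0).all()
        assert t.grand_total == 3

    def test_reference_counts_reconstruct_12x2_total_1506(self):
        t = table1_variant_table("b2/b3 del (c35)")
        assert t.values.shape == (12, 2)
        assert t.grand_total == 1506
        assert t.counts.loc["NO-M214(xM175)", "carrier"] == 27
        assert t.counts.loc["C-M130", "carrier"] == 1
        assert t.counts.loc["O-M175", "carrier"] == 2
        assert t.values[:, 0].sum() == 30

    def test_double_carrier_counted_once(self):
        hg = {"s1": "A", "s2": "A"}
        calls = {"s1": ["v", "v"]}
        t = build_table(hg, calls, "v")
        assert t.counts.loc["A", "carrier"] == 1

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="not in catalog"):
            build_table({"s": "A"}, {}, "v", catalog_names=["w"])


class TestPearsonChiSquare:
    def test_uniform_table_statistic_zero(self):
        r = pearson_chi_square(ContingencyTable.from_array([[10, 10], [10, 10]]))
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)
        assert r.df == 1

    def test_hand_computed_2x2(self):
        r = pearson_chi_square(ContingencyTable.from_array([[5, 5], [0, 10]]))
        assert r.statistic == pytest.approx(20 / 3, rel=1e-6)

    def test_matches_bruteforce_double_loop(self, rng):
        for _ in range(20):
            t = rng.integers(1, 40, size=(3, 2))
            table = ContingencyTable.from_array(t)
            expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
            stat = sum(
                (t[i, j] - expected[i, j]) ** 2 / expected[i, j]
                for i, j in product(range(3), range(2))
            )
            assert pearson_chi_square(table).statistic == pytest.approx(stat)

    def test_zero_row_rejected(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi_square(ContingencyTable.from_array([[0, 0], [5, 5]]))


class TestGTest:
    def test_uniform_table_zero(self):
        r = g_test(ContingencyTable.from_array([[7, 7], [7, 7]]))
        assert r.statistic == pytest.approx(0.0)

    def test_nonnegative_and_matches_loop(self, rng):
        for _ in range(20):
            t = rng.integers(0, 30, size=(2, 3))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            table = ContingencyTable.from_array(t)
            expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
            g = 2 * sum(
                t[i, j] * math.log(t[i, j] / expected[i, j])
                for i in range(2)
                for j in range(3)
                if t[i, j] > 0
            )
            got = g_test(table).statistic
            assert got >= -1e-9
            assert got == pytest.approx(g, rel=1e-9, abs=1e-9)


class TestFisherExact:
    def test_case_control_reference_value(self):
        """13/139 schizophrenia cases vs 21/132 controls: two-sided p
        rounds to 0.14."""
        t = ContingencyTable.from_array([[13, 126], [21, 111]])
        assert fisher_exact(t).p == pytest.approx(0.14, abs=0.01)

    def test_identical_rows_p_one(self):
        t = ContingencyTable.from_array([[6, 4], [6, 4]])
        assert fisher_exact(t).p == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_tables(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 11, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            t = ContingencyTable.from_array([[a, b], [c, d]])
            assert fisher_exact(t).p == pytest.approx(
                enumerate_fisher_2x2(a, b, c, d), rel=1e-9
            )

    def test_monte_carlo_rxc_close_to_exact_2x2_analogue(self):
        # r x c Monte Carlo route, checked for sanity against chi-square
        t = ContingencyTable.from_array([[20, 5, 5], [5, 20, 5], [5, 5, 20]])
        r = fisher_exact(t, mc_replicates=20_000, seed=1)
        assert r.method == "monte-carlo"
        assert r.p < 0.001
        assert r.se is not None and r.se < 0.01

    def test_monte_carlo_null_table_large_p(self):
        t = ContingencyTable.from_array([[10, 10, 10], [10, 10, 10]])
        r = fisher_exact(t, mc_replicates=20_000, seed=1)
        assert r.p == pytest.approx(1.0, abs=0.05)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable.from_array([[-1, 2], [3, 4]])


class TestResiduals:
    @pytest.mark.parametrize(
        "variant,hg,convention,value",
        [
            ("gr/gr del (c8)", "D-M174", "pearson", 14.9),
            ("q-arm dupl + U3 del", "C-M130", "pearson", 7.8),
            ("b1/b3 del (c3)", "C-M130", "pearson", 3.7),
            ("P5 dupl", "G-M201", "pearson", 7.0),
            ("P4 dupl", "F-M89(xM1329)", "pearson", 6.5),
            ("P4 dupl", "KLT-M9(xM526)", "pearson", 7.5),
            ("P5 dupl", "Q-M242", "pearson", 3.9),
            ("P4 dupl", "Q-M242", "pearson", 5.1),
            ("b1/b3 del (c3)", "O-M175", "adjusted", 2.5),
            ("blue-grey dupl (c449)", "NO-M214(xM175)", "adjusted", 12.1),
            ("blue-grey like dupl", "NO-M214(xM175)", "adjusted", 16.1),
            ("gr/gr dupl + distal dupl", "J-M304", "adjusted", 8.3),
            ("P3 dupl", "E-M96", "adjusted", 7.6),
        ],
    )
    def test_reference_carrier_cell_residuals(self, variant, hg, convention, value):
        """Carrier-cell residuals recompute from the reference counts to
        the printed 1-d.p. values (both conventions are reported because
        the source mixes them)."""
        res = residuals(table1_variant_table(variant))
        frame = res.pearson if convention == "pearson" else res.adjusted
        assert round(float(frame.loc[hg, "carrier"]), 1) == value

    def test_uniform_table_all_zero(self):
        res = residuals(ContingencyTable.from_array([[8, 8], [8, 8]]))
        assert np.allclose(res.pearson.to_numpy(), 0)
        assert np.allclose(res.adjusted.to_numpy(), 0)

    def test_adjusted_exceeds_pearson_in_magnitude(self, rng):
        t = ContingencyTable.from_array(rng.integers(1, 30, size=(3, 2)))
        res = residuals(t)
        assert (
            np.abs(res.adjusted.to_numpy()) >= np.abs(res.pearson.to_numpy()) - 1e-12
        ).all()


class TestFrequencyReport:
    def test_reference_overall_and_per_haplogroup(self):
        rep = frequency_report_from_counts(defaults.load_table2_counts())
        assert rep.overall_pct == 14.7
        assert rep.total_n == 1506 and rep.total_carriers == 221
        t = rep.table
        assert t.loc["NO-M214(xM175)", "pct_carriers"] == 97.5
        assert t.loc["D-M174", "pct_carriers"] == 83.3
        assert t.loc["R-M207", "pct_carriers"] == 7.1
        assert t.loc["R-M207", "pct_total"] == 31.7

    def test_reference_excluding_top_haplogroup(self):
        rep = frequency_report_from_counts(
            defaults.load_table2_counts(), exclude=["NO-M214(xM175)"]
        )
        assert rep.overall_pct == 12.4

    def test_empty_cohort_empty_report(self):
        rep = frequency_report({}, {})
        assert rep.total_n == 0
        assert len(rep.table) == 0

    def test_from_calls_counts_carriers_once(self):
        hg = {"a": "X", "b": "X", "c": "Y"}
        calls = {"a": ["v1", "v2"], "c": ["v1"]}
        rep = frequency_report(hg, calls)
        assert rep.total_carriers == 2
        assert rep.table.loc["X", "carriers"] == 1
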