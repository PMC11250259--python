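"""Disproportionality estimators against hand-derived and library oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from faersignal import (
    ContingencyTable,
    MedDRAHierarchy,
    bcpnn_ic,
    build_tables,
    chi_square,
    compute_signals,
    ebgm_simplified,
    prr,
    ror,
    screen_signal,
)


def _random_tables(rng, n, positive=False):
    lo = 1 if positive else 0
    a = rng.integers(lo, 50, size=n)
    b = rng.integers(max(lo, 1), 500, size=n)
    c = rng.integers(max(lo, 1), 500, size=n)
    d = rng.integers(max(lo, 1), 5000, size=n)
    return a, b, c, d


class TestContingencyTable:
    def test_rejects_negative_and_fractional_cells(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            ContingencyTable(1.5, 2, 3, 4)

    def test_expected_is_margin_product_over_n(self):
        t = ContingencyTable(10, 20, 30, 240)
        assert t.expected == pytest.approx(30 * 40 / 300)


class TestRor:
    def test_symmetric_table_gives_unity_with_ci_spanning_one(self):
        est, lo, hi, corrected = ror(10, 10, 10, 10)
        assert est == pytest.approx(1.0)
        assert lo < 1.0 < hi and not corrected

    def test_hand_computed_cross_product(self):
        est, *_ = ror(10, 20, 30, 240)
        assert est == pytest.approx(4.0)

    def test_large_table_mimicking_a_common_cardiac_term(self):
        est, lo, hi, _ = ror(984, 4188, 26841, 973159)
        assert est == pytest.approx(8.52, abs=0.005)

    def test_zero_cell_triggers_haldane_correction_and_flag(self):
        est, lo, hi, corrected = ror(5, 0, 10, 100)
        assert corrected and np.isfinite(est) and np.isfinite(hi)


class TestPrr:
    def test_symmetric_table_gives_unity(self):
        est, *_ = prr(10, 10, 10, 10)
        assert est == pytest.approx(1.0)

    def test_hand_computed_proportion_ratio(self):
        est, *_ = prr(10, 20, 30, 240)
        assert est == pytest.approx(3.0)  # (10/30)/(30/270)

    def test_cardiac_mimic_table(self):
        est, *_ = prr(984, 4188, 26841, 973159)
        assert est == pytest.approx(7.09, abs=0.005)


class TestChiSquare:
    def test_textbook_value_without_correction(self):
        assert chi_square(10, 20, 30, 240, yates=False) == pytest.approx(11.538, abs=1e-3)

    def test_textbook_value_with_yates(self):
        assert chi_square(10, 20, 30, 240, yates=True) == pytest.approx(9.695, abs=1e-3)

    def test_independent_table_gives_zero(self):
        assert chi_square(4, 26, 36, 234, yates=False) == pytest.approx(0.0)

    def test_matches_generic_contingency_oracle_on_random_tables(self):
        rng = np.random.default_rng(123)
        a, b, c, d = _random_tables(rng, 100, positive=True)
        ours = chi_square(a, b, c, d, yates=False)
        for i in range(100):
            ref = chi2_contingency(
                [[a[i], b[i]], [c[i], d[i]]], correction=False
            ).statistic
            assert ours[i] == pytest.approx(ref, abs=1e-9)


class TestBcpnn:
    def test_plain_ic_is_log2_observed_over_expected(self):
        ic, _ = bcpnn_ic(10, 20, 30, 240)
        assert ic == pytest.approx(np.log2(2.5))  # 10*300/(30*40)

    def test_no_disproportionality_gives_zero_ic(self):
        ic, _ = bcpnn_ic(4, 26, 36, 234)  # a == E
        assert ic == pytest.approx(0.0)

    def test_zero_count_plain_ic_is_negative_infinity(self):
        ic, _ = bcpnn_ic(0, 30, 30, 240)
        assert ic == -np.inf

    def test_noren_variant_shrinks_toward_zero(self):
        plain, _ = bcpnn_ic(3, 20, 30, 2000, variant="plain")
        noren, _ = bcpnn_ic(3, 20, 30, 2000, variant="noren")
        assert abs(noren) < abs(plain)

    def test_gamma_ic025_close_to_noren_approximation_for_large_counts(self):
        _, noren = bcpnn_ic(500, 5000, 5000, 500000, ic025_variant="noren")
        _, gamma = bcpnn_ic(500, 5000, 5000, 500000, ic025_variant="gamma")
        assert noren == pytest.approx(gamma, abs=0.15)

    def test_ic_equals_log2_of_simplified_ebgm_on_random_tables(self):
        rng = np.random.default_rng(7)
        a, b, c, d = _random_tables(rng, 1000, positive=True)
        ic, _ = bcpnn_ic(a, b, c, d, variant="plain")
        ebgm, _ = ebgm_simplified(a, b, c, d)
        np.testing.assert_allclose(ic, np.log2(ebgm), rtol=0, atol=1e-12)


class TestEbgmSimplified:
    def test_observed_over_expected(self):
        ebgm, _ = ebgm_simplified(10, 20, 30, 240)
        assert ebgm == pytest.approx(2.5)

    def test_unity_when_observed_equals_expected(self):
        ebgm, _ = ebgm_simplified(4, 26, 36, 234)
        assert ebgm == pytest.approx(1.0)

    def test_zero_count_gives_zero(self):
        ebgm, low = ebgm_simplified(0, 30, 30, 240)
        assert ebgm == 0.0 and low == 0.0


class TestOrderingProperty:
    def test_ror_exceeds_prr_exactly_when_above_one(self):
        rng = np.random.default_rng(99)
        a, b, c, d = _random_tables(rng, 1000, positive=True)
        r, *_ = ror(a, b, c, d)
        p, *_ = prr(a, b, c, d)
        neutral = np.isclose(r, 1.0)
        assert np.all(np.sign(np.round(r - p, 12))[~neutral] == np.sign(r - 1.0)[~neutral])


class TestScreen:
    def test_all_criteria_met_is_positive(self):
        sig, failed = screen_signal(10, 2.0, 1.8, 11.5, 0.5, 2.5)
        assert sig and failed == []

    def test_count_below_three_fails_regardless_of_strength(self):
        sig, failed = screen_signal(2, 2.0, 1.8, 11.5, 0.5, 2.5)
        assert not sig and failed == ["n>=3"]

    def test_thresholds_are_strict_where_specified(self):
        sig, failed = screen_signal(10, 2.0, 1.8, 11.5, 0.5, 2.0)
        assert not sig and failed == ["ebgm>2"]
        sig, failed = screen_signal(10, 1.0, 1.8, 11.5, 0.5, 2.5)
        assert not sig and "ror_low>1" in failed
        # chi2 >= 4 is inclusive
        sig, failed = screen_signal(10, 2.0, 1.8, 4.0, 0.5, 2.5)
        assert sig


class TestBuildTables:
    def test_within_report_duplicate_terms_count_once(self):
        pairs = pd.DataFrame(
            {"primaryid": ["1", "1", "1"], "pt": ["X", "X", "Y"]}
        )
        tables = build_tables({"1"}, pairs, level="PT")
        by_term = tables.set_index("term")
        assert by_term.loc["X", "a"] == 1 and by_term.loc["Y", "a"] == 1

    def test_toy_ten_report_enumeration(self):
        # cohort: 2 reports both with X; background: 8 reports, 3 with X,
        # every report also lists one other unique PT
        rows = []
        for i in range(2):
            rows += [(f"c{i}", "X"), (f"c{i}", f"K{i}")]
        for i in range(8):
            if i < 3:
                rows.append((f"b{i}", "X"))
            rows.append((f"b{i}", f"Z{i}"))
        pairs = pd.DataFrame(rows, columns=["primaryid", "pt"])
        tables = build_tables({"c0", "c1"}, pairs, level="PT")
        x = tables.set_index("term").loc["X"]
        total_pairs = len(pairs)
        assert (x["a"], x["c"]) == (2, 3)
        assert x["a"] + x["b"] == 4          # all cohort pairs
        assert x["c"] + x["d"] == total_pairs - 4
        # marginal conservation across all terms
        assert (tables["a"] + tables["b"]).nunique() == 1

    def test_min_count_marks_low_count_terms(self):
        pairs = pd.DataFrame(
            {"primaryid": ["1", "2", "3", "4"], "pt": ["X", "X", "Y", "Y"]}
        )
        tables = build_tables({"1", "2"}, pairs, level="PT", min_count=3)
        assert tables.set_index("term").loc["X", "low_count"]

    def test_soc_level_counts_report_once_per_soc(self, meddra_frame):
        hier = MedDRAHierarchy.from_frame(meddra_frame)
        pairs = pd.DataFrame(
            {
                "primaryid": ["1", "1", "2"],
                "pt": ["Bradycardia", "Cardiac arrest", "Mystery term"],
            }
        )
        tables = build_tables({"1"}, pairs, level="SOC", meddra=hier)
        by_term = tables.set_index("term")
        assert by_term.loc["Cardiac disorders", "a"] == 1  # two PTs, one SOC
        assert "Unmapped" in set(pairs["pt"].map(hier.soc))


class TestComputeSignals:
    def test_frame_carries_all_estimators_and_reasons(self):
        frame = pd.DataFrame(
            {"term": ["X"], "level": ["PT"], "a": [40], "b": [360],
             "c": [100], "d": [9500], "low_count": [False]}
        )
        out = compute_signals(frame)
        row = out.iloc[0]
        assert row["ror"] > 1 and row["ebgm"] == pytest.approx(
            40 * 10000 / (400 * 140)
        )
        assert row["signal"] in (True, False)
        assert isinstance(row["failed_criteria"], str)
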