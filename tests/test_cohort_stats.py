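import numpy as np
import pandas as pd
import pytest

from footmetry.cohort_stats import (
    CohortTable,
    PowerSpec,
    boxplot_stats,
    compare_tables,
    correlation_matrix,
    difference_summary,
    normality_test,
    paired_compare,
    pearson,
    required_sample_size,
    summarize,
)
from footmetry.measurements import CODES
from footmetry.reference import reference_means


def table_from_columns(columns: dict, n: int, method="A") -> CohortTable:
    """CohortTable with given columns; unspecified codes get benign filler."""
    rng = np.random.default_rng(123)
    data = {}
    for code in CODES:
        if code in columns:
            col = np.asarray(columns[code], dtype=float)
            data[code] = np.resize(col, n)
        else:
            data[code] = 10.0 + rng.standard_normal(n)
    df = pd.DataFrame(data, index=[f"foot{i}" for i in range(n)])
    return CohortTable(method, df)


def constant_table(means: dict, n: int, method="A") -> CohortTable:
    df = pd.DataFrame({c: [means[c]] * n for c in CODES},
                      index=[f"foot{i}" for i in range(n)])
    return CohortTable(method, df)


class TestSummarize:
    def test_hand_arithmetic(self):
        t = table_from_columns({"IL_TA": [1.0, 2.0, 3.0]}, 3)
        s = summarize(t)
        assert s.loc["IL_TA", "mean"] == pytest.approx(2.0)
        assert s.loc["IL_TA", "sd"] == pytest.approx(1.0)

    def test_constant_column(self):
        t = constant_table(reference_means("semi_auto"), 5)
        s = summarize(t)
        assert s.loc["RL_TACA", "mean"] == pytest.approx(33.16)
        assert s.loc["RL_TACA", "sd"] == pytest.approx(0.0)

    def test_against_two_pass_oracle(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(5, 3, 21)
        t = table_from_columns({"Hg_NA": vals}, 21)
        s = summarize(t)
        mu = sum(vals) / len(vals)
        sd = (sum((v - mu) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        assert s.loc["Hg_NA", "mean"] == pytest.approx(mu, abs=1e-12)
        assert s.loc["Hg_NA", "sd"] == pytest.approx(sd, abs=1e-12)

    def test_missing_values_excluded_with_count(self):
        col = np.array([1.0, 2.0, np.nan, 3.0])
        t = table_from_columns({"FAO_mm": col}, 4)
        s = summarize(t)
        assert s.loc["FAO_mm", "n_used"] == 3
        assert s.loc["FAO_mm", "mean"] == pytest.approx(2.0)


class TestNormality:
    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_test([1.0, 2.0, 3.0])

    def test_zero_variance(self):
        stat, p = normality_test([2.0] * 10)
        assert p == 0.0

    def test_bimodal_rejected(self):
        rng = np.random.default_rng(13)
        x = np.concatenate([rng.normal(-5, 1, 25), rng.normal(5, 1, 25)])
        _, p = normality_test(x)
        assert p < 0.01

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(99)
        rej = sum(normality_test(rng.standard_normal(100))[1] < 0.05
                  for _ in range(400))
        assert 0.02 <= rej / 400 <= 0.09


class TestPairedCompare:
    def test_identical_samples_degenerate(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(12)
        row = paired_compare(x, x.copy())
        assert row.test_name == "degenerate"
        assert row.p_value == 1.0
        assert row.mean_diff == pytest.approx(0.0)

    def test_normal_data_uses_paired_t(self):
        rng = np.random.default_rng(21)
        a = rng.standard_normal(30)
        b = a + 0.5 + 0.3 * rng.standard_normal(30)
        row = paired_compare(a, b)
        assert row.test_name == "paired-t"
        assert row.p_value < 0.01
        assert row.r2 == pytest.approx(row.r ** 2, abs=1e-12)

    def test_non_normal_data_falls_back_to_wilcoxon(self):
        rng = np.random.default_rng(5)
        a = np.concatenate([rng.normal(-8, 0.5, 25), rng.normal(8, 0.5, 25)])
        b = a + rng.normal(0.3, 0.2, 50)
        row = paired_compare(a, b)
        assert row.test_name == "wilcoxon-signed-rank"

    def test_affine_invariance_of_t_pvalue(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal(20)
        b = a + 0.4 + 0.5 * rng.standard_normal(20)
        p0 = paired_compare(a, b).p_value
        p1 = paired_compare(3.0 * a + 7.0, 3.0 * b + 7.0).p_value
        assert p1 == pytest.approx(p0, abs=1e-9)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_compare([1.0, 2, 3, 4], [1.0, 2, 3])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, r2, p = pearson(x, 2 * x + 3)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, _, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_four_points(self):
        r, r2, _ = pearson([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6, abs=1e-12)
        assert r2 == pytest.approx(0.36, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1, 1, 1], [1.0, 2, 3, 4])


class TestCorrelationMatrix:
    def test_structure(self):
        rng = np.random.default_rng(31)
        il_ta = rng.normal(24, 7, 20)
        il_ca = rng.normal(-9, 0.5, 20)  # small dispersion
        t = table_from_columns({"IL_TA": il_ta, "IL_CA": il_ca,
                                "RL_TACA": il_ta - il_ca}, 20)
        r, sig, flagged = correlation_matrix(t)
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r.to_numpy(), r.to_numpy().T, atol=1e-12,
                           equal_nan=True)
        assert not flagged
        # the identity RL_TACA = IL_TA - IL_CA with quiet IL_CA forces a
        # strong correlation between RL_TACA and IL_TA
        assert r.loc["RL_TACA", "IL_TA"] > 0.9
        assert sig.loc["RL_TACA", "IL_TA"]

    def test_constant_column_flagged(self):
        t = table_from_columns({"Hg_CM": np.full(10, 18.55)}, 10)
        _, _, flagged = correlation_matrix(t)
        assert flagged == ["Hg_CM"]


class TestSampleSize:
    def test_reference_design_gives_16(self):
        assert required_sample_size(PowerSpec(0.05, 0.80, 1.0, 1.0)) == 16

    def test_doubled_delta_gives_4(self):
        assert required_sample_size(PowerSpec(0.05, 0.80, 2.0, 1.0)) == 4

    def test_zero_sigma_floors_at_one(self):
        assert required_sample_size(PowerSpec(0.05, 0.80, 1.0, 1e-12)) == 1

    def test_paired_design_gives_10(self):
        assert required_sample_size(PowerSpec(0.05, 0.80, 1.0, 1.0),
                                    design="paired") == 10

    def test_higher_power_gives_22(self):
        assert required_sample_size(PowerSpec(0.05, 0.90, 1.0, 1.0)) == 22

    def test_monotonicity(self):
        base = required_sample_size(PowerSpec(0.05, 0.80, 1.0, 1.0))
        assert required_sample_size(PowerSpec(0.05, 0.80, 0.5, 1.0)) >= base
        assert required_sample_size(PowerSpec(0.05, 0.80, 1.0, 2.0)) >= base
        assert required_sample_size(PowerSpec(0.05, 0.95, 1.0, 1.0)) >= base

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(alpha=1.5)


class TestDifferenceSummary:
    def test_self_comparison_all_zero(self):
        t = table_from_columns({}, 8)
        box, count, codes = difference_summary(t, t)
        assert count == 0 and codes == []
        assert (box["median"] == 0).all()

    def test_reference_threshold_count_is_three(self):
        a = constant_table(reference_means("semi_auto"), 4, "semi")
        b = constant_table(reference_means("auto"), 4, "auto")
        _, count, codes = difference_summary(a, b, threshold=3.5)
        assert count == 3
        assert set(codes) == {"RL_TACA", "RL_TAM1", "RF_TACA"}

    def test_infinite_threshold_counts_nothing(self):
        a = constant_table(reference_means("semi_auto"), 4)
        b = constant_table(reference_means("auto"), 4)
        _, count, _ = difference_summary(a, b, threshold=float("inf"))
        assert count == 0

    def test_tukey_outlier_detection(self):
        stats = boxplot_stats(np.array([1.0, 2, 2, 3, 3, 3, 4, 4, 5, 50.0]))
        assert stats["outliers"] == [50.0]
        assert stats["whisker_hi"] <= 5.0

    def test_unpaired_tables_rejected(self):
        a = table_from_columns({}, 6)
        df = a.data.copy()
        df.index = [f"other{i}" for i in range(6)]
        b = CohortTable("B", df)
        with pytest.raises(ValueError):
            difference_summary(a, b)


class TestCompareTables:
    def test_self_comparison_no_significance(self):
        t = table_from_columns({}, 8)
        rows = compare_tables(t, t)
        assert len(rows) == 32
        assert all(r.test_name == "degenerate" and not r.significant
                   for r in rows)

    def test_unpairable_ids_rejected(self):
        a = table_from_columns({}, 6)
        df = a.data.copy()
        df.index = [f"x{i}" for i in range(6)]
        with pytest.raises(ValueError):
            compare_tables(a, CohortTable("B", df))
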