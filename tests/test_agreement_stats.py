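"""Agreement battery vs naive closed-form oracles, plus degenerate contracts."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinegait.agreement_stats import (
    accuracy_mape,
    agreement_table,
    bland_altman,
    ks_normality,
    paired_t,
    pearson,
    rmse,
)

# ---------------------------------------------------------------------------
# naive oracles, written independently of the implementation
# ---------------------------------------------------------------------------


def oracle_accuracy(m, a):
    return 100.0 - 100.0 * sum(abs(x - y) / abs(y) for x, y in zip(m, a)) / len(m)


def oracle_rmse(m, a):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(m, a)) / len(m))


def oracle_pearson_r(m, a):
    n = len(m)
    mm, ma = sum(m) / n, sum(a) / n
    cov = sum((x - mm) * (y - ma) for x, y in zip(m, a))
    vm = sum((x - mm) ** 2 for x in m)
    va = sum((y - ma) ** 2 for y in a)
    return cov / math.sqrt(vm * va)


def oracle_paired_t(m, a):
    d = [x - y for x, y in zip(m, a)]
    n = len(d)
    mean = sum(d) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in d) / (n - 1))
    return mean / (sd / math.sqrt(n))


def oracle_bland_altman(m, a):
    d = [x - y for x, y in zip(m, a)]
    n = len(d)
    mean = sum(d) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in d) / (n - 1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


@pytest.mark.parametrize("seed", range(5))
def test_all_statistics_match_naive_oracles(seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.5, 2.0, 20)
    m = a * rng.uniform(0.8, 1.2, 20) + rng.normal(0, 0.05, 20)
    assert accuracy_mape(m, a) == pytest.approx(oracle_accuracy(m, a), abs=1e-12)
    assert rmse(m, a) == pytest.approx(oracle_rmse(m, a), abs=1e-12)
    r, _ = pearson(m, a)
    assert r == pytest.approx(oracle_pearson_r(m, a), abs=1e-12)
    t, _ = paired_t(m, a)
    assert t == pytest.approx(oracle_paired_t(m, a), abs=1e-12)
    ba = bland_altman(m, a)
    om, olo, ohi = oracle_bland_altman(m, a)
    assert ba.mean_diff == pytest.approx(om, abs=1e-12)
    assert ba.loa_low == pytest.approx(olo, abs=1e-12)
    assert ba.loa_high == pytest.approx(ohi, abs=1e-12)


class TestTrivialCases:
    def test_identical_systems(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert accuracy_mape(a, a) == 100.0
        assert rmse(a, a) == 0.0
        t, p = paired_t(a, a)
        assert (t, p) == (0.0, 1.0)
        r, _ = pearson(a, a)
        assert r == pytest.approx(1.0)

    def test_ten_percent_bias_gives_ninety(self):
        a = np.array([0.5, 1.0, 2.0, 4.0])
        assert accuracy_mape(1.1 * a, a) == pytest.approx(90.0, abs=1e-10)

    def test_mixed_errors_arithmetic(self):
        m = np.array([1.0, 0.9, 1.2])
        a = np.ones(3)
        assert accuracy_mape(m, a) == pytest.approx(90.0, abs=1e-10)

    def test_rmse_three_four(self):
        assert rmse([3.0, 4.0], [0.0, 0.0]) == pytest.approx(
            math.sqrt(12.5), abs=1e-12
        )

    def test_rmse_scale_equivariant_accuracy_scale_invariant(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(1, 2, 15)
        m = a + rng.normal(0, 0.1, 15)
        assert rmse(3 * m, 3 * a) == pytest.approx(3 * rmse(m, a), rel=1e-12)
        assert accuracy_mape(3 * m, 3 * a) == pytest.approx(
            accuracy_mape(m, a), abs=1e-10
        )

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(c=st.floats(0.01, 100.0), seed=st.integers(0, 2**16))
    def test_property_scale_behaviour(self, c, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.5, 2.0, 12)
        m = a + rng.normal(0, 0.1, 12)
        assert accuracy_mape(c * m, c * a) == pytest.approx(
            accuracy_mape(m, a), abs=1e-8
        )
        assert rmse(c * m, c * a) == pytest.approx(c * rmse(m, a), rel=1e-9)
        r0, _ = pearson(m, a)
        r1, _ = pearson(c * m + 1.0, a)
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, _ = pearson(-x, x)
        assert r == pytest.approx(-1.0)

    def test_alternating_differences_zero_t(self):
        a = np.ones(6)
        m = a + np.array([0.1, -0.1] * 3)
        t, _ = paired_t(m, a)
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_constant_difference_degenerates_loa(self):
        a = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(a + 0.5, a)
        assert ba.mean_diff == pytest.approx(0.5)
        assert ba.loa_low == pytest.approx(ba.loa_high) == pytest.approx(0.5)

    def test_two_point_loa(self):
        ba = bland_altman([0.0, 2.0], [1.0, 1.0])  # diffs -1, +1
        assert ba.mean_diff == 0.0
        assert ba.loa_high == pytest.approx(1.96 * math.sqrt(2), abs=1e-12)

    def test_mean_diff_equals_mean_difference(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=25)
        m = rng.normal(size=25)
        ba = bland_altman(m, a)
        assert ba.mean_diff == pytest.approx(m.mean() - a.mean(), abs=1e-12)


class TestDegenerateContracts:
    def test_zero_reference_named(self):
        with pytest.raises(ValueError, match="index 1"):
            accuracy_mape([1.0, 1.0], [1.0, 0.0])

    def test_infinite_t_signalled(self):
        with pytest.raises(ValueError, match="infinite t"):
            paired_t([1.5, 2.5, 3.5], [1.0, 2.0, 3.0])

    def test_zero_variance_correlation(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_constant_sample_normality(self):
        with pytest.raises(ValueError, match="constant"):
            ks_normality(np.ones(10))


class TestNormality:
    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(42)
        assert ks_normality(rng.normal(0, 1, 1000)) > 0.05

    def test_exponential_sample_rejected(self):
        rng = np.random.default_rng(42)
        assert ks_normality(rng.exponential(1.0, 1000)) < 0.001

    def test_classic_variant_available(self):
        rng = np.random.default_rng(0)
        p = ks_normality(rng.normal(0, 1, 500), variant="ks")
        assert 0 < p <= 1


class TestBlandAltmanCoverage:
    def test_loa_cover_about_95_percent(self):
        rng = np.random.default_rng(123)
        a = rng.normal(10, 1, 1000)
        m = a + rng.normal(0.2, 0.5, 1000)
        ba = bland_altman(m, a)
        assert 0.93 <= ba.inside_fraction <= 0.97


class TestAgreementTable:
    def _pairs(self, seed=0, n=30):
        rng = np.random.default_rng(seed)
        rows = []
        for parameter in ("walking_speed", "cadence"):
            for group in ("stroke", "healthy"):
                a = rng.uniform(0.5, 1.5, n)
                m = a + rng.normal(0, 0.05, n)
                for x, y in zip(m, a):
                    rows.append(
                        {"parameter": parameter, "group": group,
                         "measured": x, "actual": y}
                    )
        return pd.DataFrame(rows)

    def test_three_cells_per_parameter(self):
        table = agreement_table(self._pairs())
        assert set(table["group"]) == {"all", "stroke", "healthy"}
        assert len(table) == 6

    def test_identical_systems_all_cells(self):
        pairs = self._pairs()
        pairs["measured"] = pairs["actual"]
        table = agreement_table(pairs)
        assert (table["accuracy_pct"] == 100.0).all()
        assert np.allclose(table["pearson_r"], 1.0)
        assert (table["rmse"] == 0.0).all()
        assert (table["t_p"] == 1.0).all()

    def test_group_permutation_leaves_pooled_row_invariant(self):
        pairs = self._pairs()
        table1 = agreement_table(pairs)
        shuffled = pairs.copy()
        shuffled["group"] = np.random.default_rng(5).permutation(
            shuffled["group"].to_numpy()
        )
        table2 = agreement_table(shuffled)
        a1 = table1[table1.group == "all"].set_index("parameter")
        a2 = table2[table2.group == "all"].set_index("parameter")
        pd.testing.assert_frame_equal(a1, a2)

    def test_small_cell_omitted_with_warning(self):
        pairs = self._pairs(n=4)
        pairs = pairs[~((pairs.group == "stroke") & (pairs.index % 2 == 0))]
        with pytest.warns(UserWarning, match="omitted"):
            table = agreement_table(pairs, min_pairs=3)
        assert "all" in set(table["group"])

    def test_known_r_recovered(self):
        rng = np.random.default_rng(7)
        n = 60
        a = rng.normal(1.0, 0.2, n)
        noise_sd = 0.2 * math.sqrt(1 / 0.9**2 - 1)
        m = a + rng.normal(0, noise_sd, n)
        r, _ = pearson(m, a)
        assert r == pytest.approx(0.9, abs=0.07)
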