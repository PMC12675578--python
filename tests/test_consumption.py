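import math

import numpy as np
import pytest
from scipy import stats

from beetox.bioassay import ValidationError
from beetox.consumption import (
    ai_intake,
    bartlett_test,
    cage_consumption,
    interval_consumption,
    one_way_anova,
    per_bee_consumption,
    scott_knott,
    shapiro_wilk,
    tukey_filter,
)

from conftest import make_bioassay


class TestIntervalConsumption:
    def test_simple_subtraction(self):
        (iv,) = interval_consumption([(0.0, 5.000, 0.0), (24.0, 4.700, None)])
        assert iv.consumed_g == pytest.approx(0.300)

    def test_refill_bookkeeping(self):
        ivs = interval_consumption(
            [(0.0, 5.000, 0.0), (24.0, 4.700, 1.000), (48.0, 5.200, None)]
        )
        assert ivs[0].consumed_g == pytest.approx(0.300)
        # start of (24,48) is 4.700 + 1.000 = 5.700; reading 5.200 -> 0.500 g
        assert ivs[1].consumed_g == pytest.approx(0.500)

    def test_negative_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            (iv,) = interval_consumption([(0.0, 5.000, 0.0), (24.0, 5.020, None)])
        assert iv.consumed_g == 0.0
        assert iv.clipped

    def test_conservation_total_equals_interval_sum(self):
        ivs = interval_consumption(
            [(0.0, 5.0, 0.0), (24.0, 4.6, 0.0), (48.0, 4.1, 1.0), (96.0, 4.4, None)]
        )
        assert sum(iv.consumed_g for iv in ivs) == pytest.approx((5.0 - 4.6) + (4.6 - 4.1) + (5.1 - 4.4))

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValidationError):
            interval_consumption([(0.0, 5.0, 0.0)])


class TestPerBee:
    def test_constant_occupancy(self):
        ivs = interval_consumption([(0.0, 5.0, 0.0), (24.0, 4.7, None)])
        per, total = per_bee_consumption(ivs, {0.0: 10, 24.0: 10})
        assert per[0] == pytest.approx(0.030)
        assert total == pytest.approx(0.030)

    def test_midpoint_rule_under_mortality(self):
        ivs = interval_consumption([(0.0, 5.0, 0.0), (24.0, 4.7, None)])
        per, _ = per_bee_consumption(ivs, {0.0: 10, 24.0: 6})
        assert per[0] == pytest.approx(0.300 / 8)

    def test_zero_consumption_any_occupancy(self):
        ivs = interval_consumption([(0.0, 5.0, 0.0), (24.0, 5.0, None)])
        per, total = per_bee_consumption(ivs, {0.0: 3, 24.0: 1})
        assert total == 0.0

    def test_consumption_without_bees_rejected(self):
        ivs = interval_consumption([(0.0, 5.0, 0.0), (24.0, 4.7, None)])
        with pytest.raises(ValidationError):
            per_bee_consumption(ivs, {0.0: 0, 24.0: 0})


class TestAiIntake:
    def test_arithmetic(self):
        assert ai_intake(0.030, 83.3) == pytest.approx(2.499)

    def test_control_zero(self):
        assert ai_intake(0.030, 0.0) == 0.0

    def test_density_linearity(self):
        assert ai_intake(0.030, 83.3, density_g_per_ml=1.2) == pytest.approx(2.499 / 1.2)

    def test_bad_density(self):
        with pytest.raises(ValueError):
            ai_intake(0.03, 10.0, density_g_per_ml=0.0)


def test_cage_consumption_from_bioassay():
    feeders = {"t": [[(5.0, 0.0), (4.7, 0.0), (4.4, None)]]}
    b = make_bioassay(
        {"t": [[0, 0, 0]]},
        times=(0.0, 24.0, 96.0),
        feeders=feeders,
        concentrations={"t": 83.3},
    )
    rec = cage_consumption(b, "t", "t_c1")
    assert rec.total_g == pytest.approx(0.6)
    assert rec.per_bee_g == pytest.approx(0.06)
    assert rec.ai_per_bee_ug == pytest.approx(0.06 * 83.3)


class TestTukeyFilter:
    def test_textbook_outlier(self):
        res = tukey_filter([1, 2, 3, 4, 100])
        assert res.kept.tolist() == [1, 2, 3, 4]
        assert res.rejected.tolist() == [100]
        assert res.lower_fence == pytest.approx(-1.0)
        assert res.upper_fence == pytest.approx(7.0)

    def test_all_equal_nothing_rejected(self):
        res = tukey_filter([5.0] * 6)
        assert len(res.rejected) == 0
        assert res.lower_fence == res.upper_fence == 5.0

    def test_small_sample_refuses(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            res = tukey_filter([1.0, 2.0, 50.0])
        assert len(res.kept) == 3

    def test_partition_property(self, rng):
        x = rng.normal(size=30)
        res = tukey_filter(x)
        assert len(res.kept) + len(res.rejected) == 30
        assert np.all((res.kept >= res.lower_fence) & (res.kept <= res.upper_fence))


class TestAnova:
    def test_degrees_of_freedom(self, rng):
        # 7 groups, 20 retained observations -> df (6, 13)
        sizes = [3, 3, 3, 3, 3, 3, 2]
        groups = {f"g{i}": rng.normal(size=n) for i, n in enumerate(sizes)}
        res = one_way_anova(groups)
        assert (res.df1, res.df2) == (6, 13)

    def test_identical_groups_zero_f(self):
        res = one_way_anova({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.F == pytest.approx(0.0)

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(size=6), rng.normal(1.0, 1.0, size=8)
        res = one_way_anova({"a": a, "b": b})
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        assert res.F == pytest.approx(t**2, rel=1e-10)

    def test_matches_scipy(self, rng):
        groups = {f"g{i}": rng.normal(i * 0.5, 1.0, size=5) for i in range(4)}
        res = one_way_anova(groups)
        F, p = stats.f_oneway(*groups.values())
        assert res.F == pytest.approx(F, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_shift_and_scale_invariance(self, rng):
        groups = {f"g{i}": rng.normal(i, 1.0, size=5) for i in range(3)}
        res = one_way_anova(groups)
        shifted = {k: np.asarray(v) * 3.0 + 7.0 for k, v in groups.items()}
        assert one_way_anova(shifted).F == pytest.approx(res.F, rel=1e-10)

    def test_insufficient_replication(self):
        with pytest.raises(ValidationError):
            one_way_anova({"a": [1.0], "b": [2.0, 3.0]})


class TestAssumptionChecks:
    def test_bartlett_structure(self, rng):
        groups = {f"g{i}": rng.normal(size=8) for i in range(3)}
        stat, df, p = bartlett_test(groups)
        assert df == 2 and stat >= 0 and 0 <= p <= 1

    def test_bartlett_null_p_uniform(self, rng):
        pvals = [
            bartlett_test({k: rng.normal(size=10) for k in "abc"})[2] for _ in range(300)
        ]
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_shapiro_bounds_and_refusals(self, rng):
        w, p = shapiro_wilk(rng.normal(size=20))
        assert w <= 1.0
        with pytest.raises(ValidationError):
            shapiro_wilk([1.0, 1.0, 1.0])
        with pytest.raises(ValidationError):
            shapiro_wilk([1.0, 2.0])


class TestScottKnott:
    def test_all_equal_single_letter(self):
        groups = {k: [5.0, 5.1, 4.9] for k in "abcd"}
        res = scott_knott(groups)
        assert set(res.group_labels.values()) == {"a"}

    def test_two_well_separated_clusters(self, rng):
        groups = {
            "lo1": (1.0 + 0.01 * rng.normal(size=3)).tolist(),
            "lo2": (1.0 + 0.01 * rng.normal(size=3)).tolist(),
            "lo3": (1.0 + 0.01 * rng.normal(size=3)).tolist(),
            "hi1": (10.0 + 0.01 * rng.normal(size=3)).tolist(),
            "hi2": (10.0 + 0.01 * rng.normal(size=3)).tolist(),
            "hi3": (10.0 + 0.01 * rng.normal(size=3)).tolist(),
        }
        res = scott_knott(groups)
        letters = res.group_labels
        assert len(set(letters.values())) == 2
        assert letters["hi1"] == letters["hi2"] == letters["hi3"] == "a"
        assert letters["lo1"] == letters["lo2"] == letters["lo3"] == "b"

    def test_letters_form_partition(self, rng):
        groups = {f"g{i}": rng.normal(i * 0.8, 1.0, size=4) for i in range(5)}
        res = scott_knott(groups)
        assert set(res.group_labels) == set(groups)
        # one letter per treatment, contiguous in the mean ordering
        ordered = sorted(groups, key=lambda l: res.means[l], reverse=True)
        seq = [res.group_labels[l] for l in ordered]
        seen = []
        for letter in seq:
            if letter not in seen:
                seen.append(letter)
            assert letter == seen[-1], "letter blocks must be contiguous"

    def test_matches_independent_recursive_oracle(self, rng):
        from sk_oracle import scott_knott_oracle

        for _ in range(5):
            k = int(rng.integers(2, 7))
            groups = {
                f"g{i}": rng.normal(rng.uniform(0, 4), 1.0, size=4) for i in range(k)
            }
            res = scott_knott(groups)
            assert res.group_labels == scott_knott_oracle(groups)

    def test_single_group_trivial(self):
        res = scott_knott({"only": [1.0, 2.0, 3.0]})
        assert res.group_labels == {"only": "a"}
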