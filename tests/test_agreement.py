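from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffqkit import (
    AgreementError,
    PairedSeries,
    adjusted_comparison,
    bland_altman,
    correlations,
    cross_classify,
    group_ttest,
)


def pairs(x, y, label="v"):
    x = np.asarray(x, float)
    return PairedSeries(tuple(f"r{k}" for k in range(len(x))), x,
                        np.asarray(y, float), label)


class TestBlandAltman:
    def test_identical_methods_fixed_point(self):
        x = np.array([1.0, 5.0, 9.0, 2.0])
        res = bland_altman(pairs(x, x))
        assert res.mean_diff == 0.0 and res.sd_diff == 0.0
        assert res.pct_within == 100.0 and res.n_outside == 0

    def test_hand_oracle_on_four_points(self):
        # diffs {1,-1,1,-1}: bias 0, sample SD = sqrt(4/3)
        x = np.array([2.0, 2.0, 4.0, 4.0])
        y = x - np.array([1.0, -1.0, 1.0, -1.0])
        res = bland_altman(pairs(x, y))
        sd = math.sqrt(4.0 / 3.0)
        assert res.mean_diff == pytest.approx(0.0, abs=1e-12)
        assert res.sd_diff == pytest.approx(sd, abs=1e-12)
        assert res.loa_low == pytest.approx(-2 * sd, abs=1e-12)
        assert res.loa_high == pytest.approx(2 * sd, abs=1e-12)
        np.testing.assert_allclose(res.means, (x + y) / 2)

    def test_normal_differences_pct_within_near_closed_form(self):
        # P(|Z| < 2) = 0.9545 for normal differences
        rng = np.random.default_rng(123)
        x = rng.normal(100.0, 10.0, 10_000)
        y = x - rng.normal(0.0, 5.0, 10_000)
        res = bland_altman(pairs(x, y))
        assert res.pct_within == pytest.approx(95.45, abs=0.8)
        assert res.comparable

    def test_k_sd_configurable(self):
        x = np.array([1.0, 2.0, 3.0, 10.0])
        res1 = bland_altman(pairs(x, np.zeros(4)), k_sd=1.0)
        res2 = bland_altman(pairs(x, np.zeros(4)), k_sd=3.0)
        assert res2.loa_high - res2.loa_low == pytest.approx(
            3 * (res1.loa_high - res1.loa_low)
        )


class TestCrossClassify:
    def test_identity_ranking_100_pct_exact(self):
        x = np.arange(12.0)
        res = cross_classify(pairs(x, x))
        assert res.pct_exact == 100.0
        assert res.pct_disagreement_combined == 0.0

    def test_reversed_ranking_brute_force(self):
        # y = -x, n divisible by 4, no ties: quartile q maps to 5-q
        x = np.arange(1.0, 9.0)
        res = cross_classify(pairs(x, -x))
        # brute force over the reversed permutation of quartile labels
        qx = np.repeat([1, 2, 3, 4], 2)
        qy = 5 - qx
        delta = np.abs(qx - qy)
        assert res.pct_exact == pytest.approx(100 * np.mean(delta == 0))
        assert res.pct_adjacent_only == pytest.approx(100 * np.mean(delta == 1))
        assert res.pct_extreme == pytest.approx(100 * np.mean(delta == 3))
        assert res.pct_exact == 0.0 and res.pct_adjacent_only == 50.0

    def test_percentages_partition_to_100(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=101), rng.normal(size=101)
        res = cross_classify(pairs(x, y))
        total = (res.pct_exact + res.pct_adjacent_only + res.pct_two_apart
                 + res.pct_extreme)
        assert total == pytest.approx(100.0, abs=0.01)
        assert res.pct_exact_plus_adjacent >= res.pct_exact

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=40), rng.normal(size=40)
        base = cross_classify(pairs(x, y))
        warped = cross_classify(pairs(np.exp(x), y ** 3))
        assert base.pct_exact == warped.pct_exact
        assert base.pct_extreme == warped.pct_extreme

    def test_heavy_ties_error_names_variable(self):
        x = np.ones(8)
        with pytest.raises(AgreementError, match="salt"):
            cross_classify(pairs(x, np.arange(8.0), label="salt"))


class TestCorrelations:
    def test_identity_gives_one_both_kinds(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        for kind in ("pearson", "spearman"):
            r, p = correlations(pairs(x, x), kind)
            assert r == pytest.approx(1.0)

    def test_monotone_transform_property(self):
        x = np.array([0.1, 1.0, 2.0, 3.5, 5.0])
        rs, _ = correlations(pairs(x, np.exp(x)), "spearman")
        rp, _ = correlations(pairs(x, np.exp(x)), "pearson")
        assert rs == pytest.approx(1.0)
        assert rp < 1.0

    def test_pearson_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.0, 3.0, 3.0, 6.0, 8.0])
        r, _ = correlations(pairs(x, y), "pearson")
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r == pytest.approx(num / den, abs=1e-10)

    def test_zero_variance_errors(self):
        with pytest.raises(AgreementError):
            correlations(pairs(np.ones(5), np.arange(5.0)))


class TestGroupTtest:
    def test_identical_samples_t_zero_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, df, p = group_ttest(pairs(x, x.copy()))
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_welch_matches_hand_formula(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, 8.0])
        t, df, p = group_ttest(pairs(x, y))
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t_hand = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        df_hand = (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1))
        assert t == pytest.approx(t_hand, abs=1e-10)
        assert df == pytest.approx(df_hand, abs=1e-10)

    def test_swapping_sides_negates_t(self):
        x = np.array([1.0, 2.0, 5.0])
        y = np.array([2.0, 6.0, 9.0])
        t1, _, p1 = group_ttest(pairs(x, y))
        t2, _, p2 = group_ttest(pairs(y, x))
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)


def long_table(a, b, energy_a=None, energy_b=None):
    a, b = np.asarray(a, float), np.asarray(b, float)
    return pd.DataFrame(
        {
            "intake": np.concatenate([a, b]),
            "method": ["A"] * len(a) + ["B"] * len(b),
            "energy": np.concatenate(
                [
                    np.asarray(energy_a if energy_a is not None else np.ones(len(a))),
                    np.asarray(energy_b if energy_b is not None else np.ones(len(b))),
                ]
            ),
        }
    )


class TestAdjustedComparison:
    def test_null_effect_when_methods_identical(self):
        vals = [1.0, 2.0, 3.0, 7.0]
        energy = [10.0, 20.0, 30.0, 40.0]
        res = adjusted_comparison(long_table(vals, vals, energy, energy))
        assert res.method_effect == pytest.approx(0.0, abs=1e-10)

    def test_six_row_design_matches_normal_equations(self):
        a, b = [1.0, 2.0, 3.0], [2.5, 3.5, 5.0]
        ea, eb = [10.0, 12.0, 14.0], [11.0, 13.0, 15.0]
        res = adjusted_comparison(long_table(a, b, ea, eb))
        X = np.column_stack(
            [np.ones(6), [0, 0, 0, 1, 1, 1], np.concatenate([ea, eb])]
        )
        beta = np.linalg.lstsq(X, np.concatenate([a, b]), rcond=None)[0]
        assert res.method_effect == pytest.approx(beta[1], abs=1e-10)

    def test_constant_energy_reduces_to_mean_difference(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([3.0, 4.0, 5.0, 6.0])
        res = adjusted_comparison(long_table(a, b))  # energy all ones
        assert res.method_effect == pytest.approx(b.mean() - a.mean(), abs=1e-10)

    def test_collinear_design_errors(self):
        df = long_table([1.0, 2.0, 3.0], [2.0, 3.0, 4.0],
                        [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        df["energy2"] = 2.0 * df["energy"]
        with pytest.raises(AgreementError, match="collinear"):
            adjusted_comparison(df, covariates=("energy", "energy2"))

    def test_recovers_injected_method_effect_coverage(self):
        """95% CI for the method effect covers the truth in >= 93% of replicates."""
        rng = np.random.default_rng(2024)
        beta = 5.0
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            energy = rng.normal(2000.0, 300.0, 40)
            a = 0.01 * energy + rng.normal(0.0, 1.0, 40)
            b = 0.01 * energy + beta + rng.normal(0.0, 1.0, 40)
            res = adjusted_comparison(
                long_table(a, b, energy, energy), check_interactions=False
            )
            lo, hi = res.model.conf_int().loc["C(method)[T.B]"]
            hits += lo <= beta <= hi
        assert hits / n_rep >= 0.93
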