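"""Repeatability statistic, noninferiority test, power/sample-size, regression."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ablashape.profiles import ValidationError
from ablashape.stats import (
    RepeatabilitySet,
    SearchLimitError,
    estimated_power,
    hodges_lehmann,
    mann_whitney_noninferiority,
    repeatability_at_point,
    sample_size_search,
    speed_regression,
)


class TestRepeatability:
    def test_identical_widths_zero(self):
        assert repeatability_at_point([5.0, 5.0, 5.0]) == 0.0

    def test_small_example_enumeration(self):
        assert repeatability_at_point([1.0, 2.0, 4.0]) == 2.0  # pairs {1,3,2}

    def test_single_pair(self):
        assert repeatability_at_point([3.0, 5.0]) == 2.0

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValidationError):
            repeatability_at_point([1.0])

    def test_matches_bruteforce_on_all_small_subsets(self):
        """Exact agreement with pair enumeration on every subset ≤ 7."""
        rng = np.random.default_rng(2024)
        sample = rng.normal(20, 3, 9)
        for k in range(2, 8):
            for idx in itertools.combinations(range(9), k):
                w = sample[list(idx)]
                brute = np.median(
                    [abs(a - b) for a, b in itertools.combinations(w, 2)]
                )
                assert repeatability_at_point(w) == pytest.approx(brute, abs=0)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=12),
        st.floats(-50, 50),
        st.floats(-5, 5),
    )
    def test_translation_invariance_and_scale_equivariance(self, w, shift, scale):
        w = np.asarray(w)
        base = repeatability_at_point(w)
        assert repeatability_at_point(w + shift) == pytest.approx(base, abs=1e-9)
        assert repeatability_at_point(w * scale) == pytest.approx(
            abs(scale) * base, rel=1e-9, abs=1e-9
        )


class TestNoninferiority:
    def test_identical_groups_reject_with_full_margin(self):
        rng = np.random.default_rng(3)
        x = rng.normal(1.0, 0.3, 200)
        res = mann_whitney_noninferiority(x, x.copy(), margin=1.0)
        assert res.p_value < 0.001
        assert res.noninferior
        assert res.delta == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_identical_distributions_null_centered(self):
        """With no margin and exchangeable groups, p ≈ 0.5 on average."""
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(200):
            x = rng.normal(0, 1, 30)
            y = rng.normal(0, 1, 30)
            ps.append(mann_whitney_noninferiority(x, y, margin=0.0).p_value)
        assert np.mean(ps) == pytest.approx(0.5, abs=0.06)

    def test_exact_p_matches_rank_enumeration(self):
        """n=(4,5): compare to exhaustive C(9,4) rank-assignment oracle."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            x = rng.normal(0, 1, 4)
            y = rng.normal(0.3, 1, 5)
            res = mann_whitney_noninferiority(x, y, margin=0.0)
            # brute force: null distribution of U₁ = #(x > y) over all rank
            # splits; the one-sided 'less' p-value is P(U₁ ≤ u_obs)
            u_obs = sum(xi > yj for xi in x for yj in y)
            ranks = np.arange(9)
            us = []
            for comb in itertools.combinations(range(9), 4):
                xr = np.array(comb)
                u = sum((xr[:, None] > np.array(
                    [r for r in ranks if r not in comb])[None, :]).ravel())
                us.append(u)
            us = np.array(us)
            p_exact = np.mean(us <= u_obs)
            assert res.p_value == pytest.approx(p_exact, abs=1e-12)

    def test_type_i_error_at_noninferiority_boundary(self):
        """conf = std + margin exactly: rejection rate ≈ α.

        2000 replicates at n = 50/100; the tolerance is three Monte-Carlo
        standard errors of a 0.05 proportion.
        """
        alpha, reps = 0.05, 2000
        rate = estimated_power(
            n_std=50, n_conf=100, sd_std=1.0, sd_conf=1.0,
            margin=1.0, shift=1.0, alpha=alpha, reps=reps, seed=11,
        )
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) <= 3 * se

    def test_consistency_under_true_noninferiority(self):
        """Identically distributed groups: power grows toward 1 with n."""
        kw = dict(sd_std=0.5, sd_conf=1.1, margin=1.0, shift=0.0, reps=200, seed=5)
        p_small = estimated_power(n_std=5, n_conf=10, **kw)
        p_big = estimated_power(n_std=60, n_conf=120, **kw)
        assert p_big > p_small
        assert p_big > 0.95

    def test_ci_upper_consistent_with_decision(self):
        rng = np.random.default_rng(12)
        x = rng.normal(1.0, 0.4, 40)
        y = rng.normal(1.2, 0.4, 40)
        res = mann_whitney_noninferiority(x, y, margin=1.0)
        # noninferiority declared iff the upper shift bound is below the margin
        assert res.noninferior == (res.ci_upper < res.margin)

    def test_ci_upper_one_sided_coverage(self):
        """The 95% upper bound covers the true shift in ≥ ~95% of draws."""
        rng = np.random.default_rng(13)
        true_shift = 0.5
        cover = 0
        n_rep = 300
        for _ in range(n_rep):
            x = rng.normal(true_shift, 1.0, 25)
            y = rng.normal(0.0, 1.0, 25)
            res = mann_whitney_noninferiority(x, y, margin=1.0)
            cover += res.ci_upper >= true_shift
        assert cover / n_rep >= 0.92

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_noninferiority([], [1.0, 2.0])


def test_hodges_lehmann_known_value():
    assert hodges_lehmann([1, 2], [0, 0]) == pytest.approx(1.5)


class TestSampleSizeSearch:
    def test_huge_margin_minimal_n(self):
        n_std, n_conf = sample_size_search(
            sd_std=0.5, sd_conf=1.1, margin=50.0, reps=100, seed=1, power_target=0.99
        )
        assert n_conf <= 8

    def test_power_monotone_in_n(self):
        kw = dict(sd_std=0.5, sd_conf=1.1, margin=1.0, shift=0.0, reps=150, seed=2)
        rates = [
            estimated_power(n_std=max(2, n // 2), n_conf=n, **kw)
            for n in (10, 40, 120)
        ]
        assert rates[0] <= rates[1] + 0.02 and rates[1] <= rates[2] + 0.02

    def test_larger_sd_needs_no_fewer_samples(self):
        kw = dict(margin=1.0, ratio=0.5, reps=120, seed=3, power_target=0.9)
        _, n1 = sample_size_search(sd_std=0.5, sd_conf=0.8, **kw)
        _, n2 = sample_size_search(sd_std=0.5, sd_conf=1.6, **kw)
        assert n2 >= n1

    def test_unreachable_power_raises(self):
        with pytest.raises(SearchLimitError):
            sample_size_search(
                sd_std=0.5, sd_conf=1.1, margin=0.0, reps=100, seed=4,
                power_target=0.999, n_max=12,
            )

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            sample_size_search(sd_std=-1, sd_conf=1, reps=100)
        with pytest.raises(ValidationError):
            sample_size_search(sd_std=1, sd_conf=1, ratio=1.5, reps=100)
        with pytest.raises(ValidationError):
            sample_size_search(sd_std=1, sd_conf=1, reps=10)


class TestSpeedRegression:
    def test_perfect_line_exact(self):
        x = np.array([0.0, 0.1, 0.2, 0.3, 0.5])
        y = 2.0 - 1.5 * x
        out = speed_regression(y, x)
        assert out["slope"] == pytest.approx(-1.5, abs=1e-9)
        assert out["r_squared"] == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_five_points(self):
        """Closed-form OLS on a printed toy set."""
        x = np.array([0.0, 0.1, 0.2, 0.3, 0.4])
        y = np.array([1.2, 1.0, 1.1, 0.7, 0.6])
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        beta = sxy / sxx
        resid = y - (y.mean() + beta * (x - x.mean()))
        s2 = resid @ resid / (len(x) - 2)
        se = np.sqrt(s2 / sxx)
        tcrit = sps.t.ppf(0.975, len(x) - 2)
        out = speed_regression(y, x)
        assert out["slope"] == pytest.approx(beta, rel=1e-9)
        assert out["slope_ci"][0] == pytest.approx(beta - tcrit * se, rel=1e-6)
        assert out["slope_ci"][1] == pytest.approx(beta + tcrit * se, rel=1e-6)

    def test_permuted_response_ci_covers_zero(self):
        rng = np.random.default_rng(6)
        x = np.linspace(0, 0.5, 30)
        y = 1.5 - 1.0 * x + rng.normal(0, 0.2, 30)
        hits = 0
        for _ in range(50):
            lo, hi = speed_regression(rng.permutation(y), x)["slope_ci"]
            hits += lo <= 0 <= hi
        assert hits >= 45

    def test_constant_speed_rejected(self):
        with pytest.raises(ValidationError):
            speed_regression([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])


def test_repeatability_set_validation():
    with pytest.raises(ValidationError):
        RepeatabilitySet(values=[1.0], group="other")
    with pytest.raises(ValidationError):
        RepeatabilitySet(values=[-1.0], group="standard")
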