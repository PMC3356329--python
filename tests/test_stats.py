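"""Bootstrap, Mann-Whitney, 2D Kolmogorov-Smirnov, Hill fitting."""
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cardioafm.exceptions import UnidentifiableEC50Error
from cardioafm.stats import (
    HillModel,
    bootstrap_ci,
    fit_hill,
    ks2d_statistic,
    ks2d_test,
    mann_whitney,
)
from cardioafm.synthetic import DoseResponseConfig, simulate_dose_response


# ------------------------------------------------------------------ oracles
def ks2d_brute(a, b):
    """Direct-definition Fasano-Franceschini statistic (plain loops)."""
    def maxdiff(origins):
        best = 0.0
        for ox, oy in origins:
            for sx in (1, -1):
                for sy in (1, -1):
                    fa = np.mean([(sx * (x - ox) > 0) and (sy * (y - oy) > 0)
                                  for x, y in a])
                    fb = np.mean([(sx * (x - ox) > 0) and (sy * (y - oy) > 0)
                                  for x, y in b])
                    best = max(best, abs(fa - fb))
        return best
    return 0.5 * (maxdiff(a) + maxdiff(b))


def mw_enumeration_p(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of labelings."""
    pooled = np.concatenate([x, y])
    n, n1 = pooled.size, len(x)
    mu = n1 * (n - n1) / 2.0

    def ustat(ix):
        xs = pooled[list(ix)]
        ys = np.delete(pooled, list(ix))
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = ustat(range(n1))
    us = [ustat(ix) for ix in combinations(range(n), n1)]
    return float(np.mean([abs(u - mu) >= abs(u_obs - mu) - 1e-12 for u in us]))


class TestBootstrap:
    def test_degenerate_sample_gives_point_interval(self):
        b = bootstrap_ci(np.full(12, 2.5), seed=0)
        assert (b.ci_low, b.estimate, b.ci_high) == (2.5, 2.5, 2.5)

    def test_log_transform_reports_geometric_mean(self):
        b = bootstrap_ci([10.0, 1000.0], transform="log", seed=0)
        assert b.estimate == pytest.approx(100.0, rel=1e-9)

    def test_nonpositive_values_under_log_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            bootstrap_ci([1.0, -2.0], transform="log")

    def test_coverage_close_to_nominal(self):
        hits = 0
        for s in range(200):
            rng = np.random.default_rng(50_000 + s)
            b = bootstrap_ci(rng.standard_normal(200), B=1000, seed=s)
            hits += b.ci_low <= 0.0 <= b.ci_high
        # binomial 95% band around 0.95 coverage for 200 replicates
        assert 180 <= hits <= 199

    def test_ci_shrinks_with_sample_size(self, rng):
        big = rng.standard_normal(400)
        w100 = bootstrap_ci(big[:100], seed=1)
        w400 = bootstrap_ci(big, seed=1)
        assert (w400.ci_high - w400.ci_low) < (w100.ci_high - w100.ci_low)

    def test_estimate_inside_interval(self, rng):
        b = bootstrap_ci(rng.exponential(2.0, 50), seed=3)
        assert b.ci_low <= b.estimate <= b.ci_high


class TestMannWhitney:
    def test_textbook_example(self):
        res = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.U == 0.0
        assert res.p == pytest.approx(1.0 / 3.0)
        assert res.method == "exact"

    def test_identical_samples_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        res = mann_whitney(x, x + 10 ** -9 * 0)  # identical multisets -> ties
        assert res.p >= 0.99

    def test_exact_matches_enumeration_sweep(self):
        rng = np.random.default_rng(7)
        for n1 in range(1, 6):
            for n2 in range(n1, 11 - n1):
                x, y = rng.normal(size=n1), rng.normal(size=n2)
                res = mann_whitney(x, y)
                assert res.method == "exact"
                assert res.p == pytest.approx(mw_enumeration_p(x, y), abs=1e-12)

    def test_ties_dispatch_to_asymptotic(self):
        res = mann_whitney([1.0, 2.0, 2.0], [2.0, 3.0])
        assert res.method == "asymptotic"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKS2DStatistic:
    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(25):
            a = rng.normal(size=(10, 2))
            b = rng.normal(size=(10, 2)) + rng.normal(0, 0.5, 2)
            assert ks2d_statistic(a, b) == pytest.approx(ks2d_brute(a, b), abs=1e-12)

    def test_identical_samples_give_zero(self, rng):
        a = rng.normal(size=(15, 2))
        assert ks2d_statistic(a, a.copy()) == 0.0

    def test_separated_clouds_give_one(self, rng):
        a = rng.uniform(-0.5, 0.5, (20, 2))
        b = rng.uniform(9.5, 10.5, (20, 2))
        assert ks2d_statistic(a, b) == 1.0

    @given(st.integers(0, 10_000))
    def test_monotone_axiswise_rescaling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(8, 2))
        b = rng.normal(size=(9, 2))
        def warp(s):
            out = s.copy()
            out[:, 0] = np.exp(out[:, 0])
            out[:, 1] = out[:, 1] ** 3 + 2 * out[:, 1]
            return out
        assert ks2d_statistic(warp(a), warp(b)) == pytest.approx(
            ks2d_statistic(a, b), abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ks2d_statistic(np.zeros((2, 2)), np.ones((5, 2)))


class TestKS2DTest:
    def test_observed_statistic_matches_direct_computation(self, rng):
        a = rng.normal(size=(12, 2))
        b = rng.normal(0.5, 1.0, size=(14, 2))
        res = ks2d_test(a, b, n_perm=200, seed=0)
        assert res.D == pytest.approx(ks2d_statistic(a, b), abs=1e-12)

    def test_separated_clouds_reject(self, rng):
        a = rng.uniform(-0.5, 0.5, (20, 2))
        b = rng.uniform(9.5, 10.5, (20, 2))
        res = ks2d_test(a, b, n_perm=10000, seed=1)
        assert res.p <= 0.001
        assert res.H

    def test_H_definition(self, rng):
        a = rng.normal(size=(30, 2))
        b = rng.normal(size=(30, 2))
        res = ks2d_test(a, b, n_perm=300, seed=2)
        assert res.H == (res.p < 0.05)

    def test_asymptotic_and_permutation_agree_roughly(self, rng):
        a = rng.normal(size=(60, 2))
        b = rng.normal(0.8, 1.0, size=(60, 2))
        pp = ks2d_test(a, b, method="permutation", n_perm=2000, seed=3).p
        pa = ks2d_test(a, b, method="asymptotic").p
        assert (pp < 0.05) == (pa < 0.05)

    def test_insufficient_permutations_refused(self, rng):
        with pytest.raises(ValueError, match="n_perm"):
            ks2d_test(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)), n_perm=50)


class TestHillFit:
    def test_noiseless_recovery(self):
        cfg = DoseResponseConfig(noise_cv=0.0, beats_per_dose=5, seed=0)
        fit = fit_hill(simulate_dose_response(cfg), bootstrap_B=0)
        assert fit.ec50 == pytest.approx(260e-9, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)

    def test_response_at_ec50_is_midpoint(self):
        fit = fit_hill(simulate_dose_response(
            DoseResponseConfig(noise_cv=0.0, seed=1)), bootstrap_B=0)
        mid = fit.predict(fit.ec50)
        assert mid == pytest.approx((fit.baseline + fit.fmax) / 2, rel=1e-9)

    def test_dose_scale_equivariance(self):
        s = simulate_dose_response(DoseResponseConfig(noise_cv=0.0, seed=2))
        f1 = fit_hill(s, bootstrap_B=0)
        f2 = fit_hill((s.dose * 2.0, s.force), bootstrap_B=0)
        assert f2.ec50 / f1.ec50 == pytest.approx(2.0, rel=1e-9)

    def test_noisy_median_recovery(self):
        errs = []
        for s in range(20):
            series = simulate_dose_response(DoseResponseConfig(seed=s))
            f = fit_hill(series, bootstrap_B=0)
            errs.append(abs(f.ec50 - 260e-9) / 260e-9)
        assert np.median(errs) < 0.15

    def test_bootstrap_ci_brackets_truth(self):
        fit = fit_hill(simulate_dose_response(DoseResponseConfig(seed=6)),
                       bootstrap_B=200, seed=0)
        assert fit.ec50_ci_low < fit.ec50 < fit.ec50_ci_high

    def test_flat_response_unidentifiable(self, rng):
        doses = np.repeat(np.geomspace(1e-8, 3.2e-5, 8), 10)
        flat = 1e-9 * (1 + 0.03 * rng.standard_normal(doses.size))
        with pytest.raises(UnidentifiableEC50Error):
            fit_hill((doses, flat), bootstrap_B=0)

    def test_too_few_decades_rejected(self):
        doses = np.repeat([1e-7, 2e-7, 4e-7, 8e-7], 5)
        with pytest.raises(ValueError, match="decades"):
            HillModel(doses, np.ones_like(doses))
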