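"""Risk differences, chi-square, rank tests, logistic subgroups, power."""

import itertools
import math

import numpy as np
import pytest

from akialert.stats import (ContingencyCounts, PowerSpec, chi_square,
                            hodges_lehmann, incidence_per_100,
                            inflate_for_attrition, logistic_subgroup,
                            mann_whitney, risk_difference_ci, sample_size)


def exact_mw_p(x, y):
    """Oracle: enumerate all group relabelings, U by direct pair counting."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_of(a, b):
        return sum((ai > bi) + 0.5 * (ai == bi) for ai in a for bi in b)

    center = n1 * len(y) / 2
    obs = abs(u_of(x, y) - center)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in comb]
        b = [pooled[i] for i in range(len(pooled)) if i not in comb]
        total += 1
        if abs(u_of(a, b) - center) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestRiskDifference:
    # printed per-arm counts from the trial's outcome tables
    @pytest.mark.parametrize(
        "counts,diff,lo,hi",
        [
            ((927, 1123, 670, 1085), 20.8, 17.1, 24.4),   # IV fluids
            ((134, 1123, 112, 1085), 1.6, -1.0, 4.2),     # death within 7 d
            ((560, 1123, 296, 1085), 22.6, 18.6, 26.5),   # AKI documentation
            ((1039, 1123, 814, 1085), 17.5, 14.5, 20.5),  # SCr measurement
        ],
    )
    def test_reproduces_printed_rows(self, counts, diff, lo, hi):
        est = risk_difference_ci(ContingencyCounts(*counts))
        assert round(est.difference, 1) == diff
        assert round(est.ci_low, 1) == lo
        assert round(est.ci_high, 1) == hi

    def test_identical_proportions_symmetric_about_zero(self):
        est = risk_difference_ci(ContingencyCounts(50, 200, 50, 200))
        assert est.difference == 0.0
        assert est.ci_low == pytest.approx(-est.ci_high)

    def test_ci_width_shrinks_like_inverse_sqrt_n(self):
        w = []
        for n in (100, 400, 1600):
            est = risk_difference_ci(ContingencyCounts(n // 4, n, n // 4, n))
            w.append(est.ci_high - est.ci_low)
        assert w[0] / w[1] == pytest.approx(2.0, rel=1e-6)
        assert w[1] / w[2] == pytest.approx(2.0, rel=1e-6)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            ContingencyCounts(0, 0, 1, 10)


class TestChiSquare:
    def test_balanced_table_is_null(self):
        stat, p = chi_square(ContingencyCounts(30, 100, 30, 100))
        assert stat == 0.0 and p == 1.0

    def test_strong_effect_is_significant(self):
        _, p = chi_square(ContingencyCounts(927, 1123, 670, 1085))
        assert p < 0.001

    def test_matches_direct_formula_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n_a, n_b = rng.integers(5, 60, size=2)
            c = ContingencyCounts(
                int(rng.integers(1, n_a)), int(n_a),
                int(rng.integers(1, n_b)), int(n_b),
            )
            stat, _ = chi_square(c)
            # oracle: sum (O-E)^2/E over the four cells
            obs = c.table.astype(float)
            rows, cols = obs.sum(1), obs.sum(0)
            exp = np.outer(rows, cols) / obs.sum()
            oracle = ((obs - exp) ** 2 / exp).sum()
            assert stat == pytest.approx(oracle, rel=1e-10)

    def test_tiny_expected_cell_warns(self):
        with pytest.warns(UserWarning):
            chi_square(ContingencyCounts(1, 200, 0, 5))


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        u, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_complete_separation_u_max(self):
        x, y = [10, 11, 12], [1, 2, 3, 4]
        u, _ = mann_whitney(x, y)
        assert u == len(x) * len(y)

    def test_all_tied_values_p_one(self):
        _, p = mann_whitney([5, 5, 5] * 10, [5, 5] * 10, method="asymptotic")
        assert p == 1.0

    @pytest.mark.parametrize("n1,n2", [(1, 5), (2, 4), (3, 3), (4, 4), (2, 8)])
    def test_exact_path_matches_permutation_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            x = rng.integers(0, 6, size=n1).astype(float)  # ties likely
            y = rng.integers(0, 6, size=n2).astype(float)
            _, p = mann_whitney(x, y)  # auto -> exact for these sizes
            assert p == pytest.approx(exact_mw_p(x, y), abs=1e-12)

    def test_asymptotic_close_to_exact_at_moderate_n(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.5, 1, 10)
        _, p_exact = mann_whitney(x, y, method="exact")
        _, p_asym = mann_whitney(x, y, method="asymptotic")
        assert abs(p_exact - p_asym) < 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestHodgesLehmann:
    def test_pure_shift_recovered(self):
        x = [1.0, 2.0, 5.0, 9.0]
        y = [v + 2.5 for v in x]
        est, lo, hi = hodges_lehmann(x, y)
        assert est == pytest.approx(2.5)
        assert lo <= est <= hi

    def test_identical_samples_zero(self):
        x = [1.0, 4.0, 6.0]
        est, _, _ = hodges_lehmann(x, x)
        assert est == 0.0

    def test_matches_brute_force_median(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            x = rng.normal(0, 2, rng.integers(2, 9))
            y = rng.normal(1, 2, rng.integers(2, 9))
            est, _, _ = hodges_lehmann(x, y)
            diffs = sorted(yj - xi for xi in x for yj in y)
            assert est == pytest.approx(float(np.median(diffs)))

    def test_ci_covers_true_shift_on_seeded_sample(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 60)
        y = rng.normal(1.0, 1, 60)
        est, lo, hi = hodges_lehmann(x, y)
        assert lo < 1.0 < hi


class TestLogistic:
    def test_or_equals_cross_product_ratio(self):
        # single binary predictor: MLE odds ratio is ad/bc exactly
        counts = {(0, 0): 40, (0, 1): 25, (1, 0): 30, (1, 1): 45}
        arm, out = [], []
        for (a, o), n in counts.items():
            arm += [a] * n
            out += [o] * n
        # same 2x2 replicated in both subgroup levels
        res = logistic_subgroup(out + out, arm + arm,
                                [0] * len(arm) + [1] * len(arm))
        ad = counts[(1, 1)] * counts[(0, 0)]
        bc = counts[(1, 0)] * counts[(0, 1)]
        for lev in (0.0, 1.0):
            or_, lo, hi = res.odds_ratios[lev]
            assert or_ == pytest.approx(ad / bc, abs=1e-6)
            assert lo < or_ < hi

    def test_known_log_or_recovered_within_ci(self):
        rng = np.random.default_rng(42)
        n = 5000
        arm = rng.integers(0, 2, n)
        sub = rng.integers(0, 2, n)
        logit = -0.5 + 0.5 * arm  # true log-OR 0.5, no interaction
        p = 1 / (1 + np.exp(-logit))
        out = (rng.uniform(size=n) < p).astype(int)
        res = logistic_subgroup(out, arm, sub)
        for lev in (0.0, 1.0):
            or_, lo, hi = res.odds_ratios[lev]
            assert lo < math.exp(0.5) < hi
        assert res.interaction_p > 0.01  # no true interaction

    def test_separation_flagged(self):
        out = [0] * 20 + [1] * 20
        arm = [0] * 20 + [1] * 20
        sub = [0, 1] * 20
        res = logistic_subgroup(out, arm, sub)
        assert res.separation

    def test_single_arm_level_rejected(self):
        with pytest.raises(ValueError):
            logistic_subgroup([0, 1, 0, 1], [1, 1, 1, 1], [0, 0, 1, 1])


class TestSampleSize:
    def test_per_group_at_most_printed_value(self):
        n, total = sample_size(PowerSpec())
        assert n <= 1050
        assert n == 1046  # closed-form value for sd 13.4, delta 1.9

    def test_attrition_inflation_reproduces_total(self):
        assert inflate_for_attrition(2100, 0.30) == 3000

    def test_doubling_effect_quarters_n(self):
        n1, _ = sample_size(PowerSpec())
        n2, _ = sample_size(PowerSpec(mean_treat=19.0 - 2 * 1.9))
        assert n2 == pytest.approx(n1 / 4, rel=0.01)

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(mean_treat=19.0)


class TestIncidence:
    def test_trial_rate(self):
        assert incidence_per_100(2208, 158152) == 1.4

    def test_degenerate_rates(self):
        assert incidence_per_100(0, 500) == 0.0
        assert incidence_per_100(500, 500) == 100.0

    def test_zero_admissions_rejected(self):
        with pytest.raises(ValueError):
            incidence_per_100(1, 0)
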