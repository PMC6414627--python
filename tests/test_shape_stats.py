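"""PCA, broken stick, Hotelling/permutation tests, allometry, reliability."""

import itertools

import numpy as np
import pytest

from crestcurve import (
    allometry_anova,
    broken_stick_retain,
    generate_repeats,
    generate_study,
    hotelling_t2,
    measurement_error,
    pairwise_group_tests,
    pca_shapes,
    permutation_hotelling,
    permutation_mean_diff,
    resample_equidistant,
)
from crestcurve.errors import (
    InsufficientSampleError,
    InvalidParameterError,
)
from crestcurve.shape_stats import (
    DEFAULT_ALPHA,
    DEFAULT_PERMUTATIONS,
    DEFAULT_RELIABILITY_THRESHOLD,
    pairwise_scalar_tests,
)


class TestPCA:
    def test_rank_one_data_has_single_component(self, rng):
        base = rng.normal(size=(1, 60))
        shapes = (rng.normal(size=(8, 1)) @ base).reshape(8, 20, 3)
        model = pca_shapes(shapes)
        assert model.variance_fractions[0] == pytest.approx(1.0)
        assert len(model.eigenvalues) == 1

    def test_fractions_sum_to_one_scores_centered_loadings_orthonormal(self, rng):
        model = pca_shapes(rng.normal(size=(10, 20, 3)))
        assert model.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(model.scores.mean(axis=0), 0.0, atol=1e-9)
        g = model.loadings @ model.loadings.T
        np.testing.assert_allclose(g, np.eye(len(g)), atol=1e-8)

    def test_eigenvalues_match_covariance_eigendecomposition_oracle(self, rng):
        shapes = rng.normal(size=(10, 20, 3))
        model = pca_shapes(shapes)
        flat = shapes.reshape(10, -1)
        cov = np.cov(flat, rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1][: len(model.eigenvalues)]
        np.testing.assert_allclose(model.eigenvalues, evals, atol=1e-8)

    def test_deterministic_sign_convention(self, rng):
        shapes = rng.normal(size=(12, 20, 3))
        m1, m2 = pca_shapes(shapes), pca_shapes(shapes)
        np.testing.assert_array_equal(m1.loadings, m2.loadings)
        idx = np.abs(m1.loadings).argmax(axis=1)
        assert np.all(m1.loadings[np.arange(len(idx)), idx] > 0)

    def test_insufficient_sample(self, rng):
        with pytest.raises(InsufficientSampleError):
            pca_shapes(rng.normal(size=(2, 20, 3)))


class TestBrokenStick:
    @pytest.mark.parametrize(
        "fractions, expected",
        [
            # b = (0.6111, 0.2778, 0.1111): only the first fraction exceeds
            ((0.7, 0.2, 0.1), 1),
            # b = (0.75, 0.25)
            ((0.9, 0.1), 1),
            ((0.5, 0.5), 0),  # equal fractions never beat b_1
            ((0.25, 0.25, 0.25, 0.25), 0),
            ((0.65, 0.30, 0.05), 2),  # b_2 = 0.2778 < 0.30
        ],
    )
    def test_closed_form_cases(self, fractions, expected):
        assert broken_stick_retain(fractions) == expected

    def test_expectations_match_direct_summation(self):
        # independent evaluation of b_j for p = 5
        p = 5
        b = [sum(1.0 / i for i in range(j, p + 1)) / p for j in range(1, p + 1)]
        fr = np.array(b) + 1e-6  # just above every expectation
        fr /= fr.sum()
        # after normalization the leading fractions still exceed b_j
        assert broken_stick_retain(b) == 0  # equality is not enough
        assert broken_stick_retain([0.46, 0.26, 0.16, 0.08, 0.04]) == 3

    def test_empty_input_invalid(self):
        with pytest.raises(InvalidParameterError):
            broken_stick_retain([])


def _t2_oracle(x, y):
    """Textbook two-sample T-squared, written independently."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    d = x.mean(axis=0) - y.mean(axis=0)
    s1 = sum(np.outer(r - x.mean(0), r - x.mean(0)) for r in x) / (n1 - 1)
    s2 = sum(np.outer(r - y.mean(0), r - y.mean(0)) for r in y) / (n2 - 1)
    sp = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    return float(n1 * n2 / (n1 + n2) * d @ np.linalg.inv(sp) @ d)


class TestHotellingT2:
    def test_identical_groups_zero(self, rng):
        x = rng.normal(size=(6, 3))
        assert hotelling_t2(x, x.copy()) == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_common_linear_map(self, rng):
        x, y = rng.normal(size=(8, 3)), rng.normal(size=(7, 3)) + 0.5
        t = hotelling_t2(x, y)
        assert hotelling_t2(10 * x, 10 * y) == pytest.approx(t, abs=1e-9)
        a = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        assert hotelling_t2(x @ a, y @ a) == pytest.approx(t, rel=1e-9)

    def test_matches_direct_formula_oracle(self):
        x = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 4.0], [2.5, 2.5]])
        y = np.array([[4.0, 5.0], [5.0, 4.5], [6.0, 6.5], [5.5, 5.0]])
        assert hotelling_t2(x, y) == pytest.approx(_t2_oracle(x, y), rel=1e-12)

    def test_too_small_sample_rejected(self, rng):
        with pytest.raises(InsufficientSampleError):
            hotelling_t2(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))


class TestPermutationHotelling:
    def test_identical_rows_give_p_one(self):
        x = np.tile([[1.0, 2.0]], (5, 1))
        res = permutation_hotelling(x, x.copy(), 500, seed=0)
        assert res.p_value == 1.0
        assert res.statistic == 0.0

    def test_default_permutation_count(self):
        assert DEFAULT_PERMUTATIONS == 10_000

    def test_matches_exhaustive_enumeration_oracle(self, rng):
        x = rng.normal(size=(3, 2))
        y = rng.normal(size=(3, 2)) + 1.0
        z = np.vstack([x, y])
        obs = _t2_oracle(x, y)
        stats = []
        for comb in itertools.combinations(range(6), 3):
            rest = [i for i in range(6) if i not in comb]
            stats.append(_t2_oracle(z[list(comb)], z[rest]))
        p_exact = np.mean([s >= obs - 1e-12 for s in stats])
        b = 50_000
        res = permutation_hotelling(x, y, b, seed=1)
        se = np.sqrt(p_exact * (1 - p_exact) / b)
        assert abs(res.p_value - p_exact) <= 3 * se + 2 / b

    def test_statistic_matches_direct_formula(self, rng):
        x, y = rng.normal(size=(9, 3)), rng.normal(size=(7, 3)) + 0.4
        res = permutation_hotelling(x, y, 10, seed=0)
        assert res.statistic == pytest.approx(_t2_oracle(x, y), rel=1e-9)

    def test_reproducible_given_seed(self, rng):
        x, y = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))
        r1 = permutation_hotelling(x, y, 999, seed=42)
        r2 = permutation_hotelling(x, y, 999, seed=42)
        assert r1.p_value == r2.p_value

    def test_p_value_bounds(self, rng):
        x = rng.normal(size=(10, 2))
        y = rng.normal(size=(10, 2)) + 50.0  # overwhelming separation
        res = permutation_hotelling(x, y, 999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)


class TestPermutationMeanDiff:
    def test_equal_samples_give_p_one(self):
        a = [3.0, 4.0, 5.0]
        res = permutation_mean_diff(a, list(a), 500, seed=0)
        assert res.p_value == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        a = rng.normal(size=3)
        b = rng.normal(size=3) + 1.5
        z = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        stats = []
        for comb in itertools.combinations(range(6), 3):
            rest = [i for i in range(6) if i not in comb]
            stats.append(abs(z[list(comb)].mean() - z[rest].mean()))
        p_exact = np.mean([s >= obs - 1e-12 for s in stats])
        b_perm = 50_000
        res = permutation_mean_diff(a, b, b_perm, seed=3)
        se = np.sqrt(p_exact * (1 - p_exact) / b_perm)
        assert abs(res.p_value - p_exact) <= 3 * se + 2 / b_perm

    def test_default_replicates(self):
        a = np.arange(3.0)
        res = permutation_mean_diff(a, a + 10)
        assert res.n_permutations == 10_000


class TestPairwiseGroupTests:
    def test_seven_groups_give_21_cells(self, rng):
        scores = rng.normal(size=(70, 20, 3))
        model = pca_shapes(scores)
        groups = np.repeat([f"g{i}" for i in range(7)], 10)
        mat = pairwise_group_tests(model, groups, n_permutations=49, seed=0)
        assert len(mat.labels) == 7
        tri = mat.p_values[np.tril_indices(7, -1)]
        assert np.isfinite(tri).sum() == 21

    def test_saturated_significance_with_huge_offset(self, rng):
        shapes = rng.normal(size=(24, 20, 3)) * 0.01
        shapes[12:] += 5.0 * rng.normal(size=(20, 3))  # common large offset
        model = pca_shapes(shapes)
        groups = ["a"] * 12 + ["b"] * 12
        mat = pairwise_group_tests(model, groups, n_permutations=999, seed=0)
        assert mat.p_values[1, 0] == pytest.approx(1 / 1000)
        assert mat.significant("a", "b")

    def test_small_group_excluded_with_remaining_tested(self, rng):
        shapes = rng.normal(size=(14, 20, 3))
        model = pca_shapes(shapes)
        groups = ["a"] * 6 + ["b"] * 6 + ["c"] * 2
        mat = pairwise_group_tests(model, groups, n_permutations=49, seed=0)
        assert mat.labels == ["a", "b"]

    def test_cell_seeds_stable_under_group_addition(self, rng):
        shapes = rng.normal(size=(18, 20, 3))
        model2 = pca_shapes(shapes[:12])
        model3 = pca_shapes(shapes)
        g2 = ["a"] * 6 + ["b"] * 6
        g3 = g2 + ["c"] * 6
        m2 = pairwise_group_tests(model2, g2, n_permutations=199, seed=5)
        m3 = pairwise_group_tests(model3, g3, n_permutations=199, seed=5)
        assert m2.results[("a", "b")].seed == m3.results[("a", "b")].seed

    def test_alpha_default(self):
        assert DEFAULT_ALPHA == 0.05


class TestAllometry:
    def test_constant_scores_give_zero_f(self):
        class FakePCA:
            scores = np.zeros((8, 2))
            n_retained_broken_stick = 1
            n = 8

        res = allometry_anova(FakePCA(), np.linspace(300, 400, 8))
        assert res[0].f_stat == pytest.approx(0.0)

    def test_perfectly_linear_scores(self, rng):
        lengths = np.linspace(300.0, 400.0, 10)

        class FakePCA:
            scores = np.column_stack([2.0 * lengths - 1.0, rng.normal(size=10)])
            n_retained_broken_stick = 1
            n = 10

        res = allometry_anova(FakePCA(), lengths)
        assert res[0].r_squared == pytest.approx(1.0)
        assert res[0].p_value < 1e-12

    def test_hand_computed_anova_oracle(self):
        # 6-point dataset computed by hand via the ANOVA table:
        # x = 1..6, y = (2, 1, 4, 3, 6, 5): slope = 0.8857, SSreg/SSres -> F
        x = np.arange(1.0, 7.0)
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        ss_reg = sxy**2 / sxx
        ss_tot = np.sum((y - y.mean()) ** 2)
        f_oracle = ss_reg / ((ss_tot - ss_reg) / 4)

        class FakePCA:
            scores = y[:, None]
            n_retained_broken_stick = 1
            n = 6

        res = allometry_anova(FakePCA(), x)
        assert res[0].f_stat == pytest.approx(f_oracle, rel=1e-12)

    def test_zero_length_variance_reported_na(self):
        class FakePCA:
            scores = np.random.default_rng(0).normal(size=(6, 1))
            n_retained_broken_stick = 1
            n = 6

        res = allometry_anova(FakePCA(), np.full(6, 350.0))
        assert np.isnan(res[0].slope)


class TestMeasurementError:
    @staticmethod
    def _repeat_sets(noise, n_spec=8, n_rep=3, seed=0):
        rng = np.random.default_rng(seed)
        from crestcurve.synthetic import GroupParams, StudyDesign

        g = GroupParams(name="e", n=n_spec, ap_amplitude_mm=6.0,
                        ml_amplitude_mm=3.5, length_mm=354.0)
        d = StudyDesign(groups=[g], seed=seed, digitization_noise_mm=0.0,
                        points_min=600, points_max=700)
        specs = generate_study(d)
        return [
            [resample_equidistant(p)
             for p in generate_repeats(s, n_rep, noise_mm=noise, rng=rng)]
            for s in specs
        ]

    def test_identical_repeats_have_zero_error_full_reliability(self):
        sets = self._repeat_sets(noise=0.0)
        rep = measurement_error(sets)
        assert rep.overall_me < 1e-5  # chordal re-digitization error only
        assert rep.reliability > 0.999
        assert rep.acceptable

    def test_reliability_decreases_with_noise(self):
        r_small = measurement_error(self._repeat_sets(noise=0.05)).reliability
        r_large = measurement_error(self._repeat_sets(noise=1.5)).reliability
        assert r_small > r_large

    def test_default_threshold(self):
        assert DEFAULT_RELIABILITY_THRESHOLD == 0.95

    def test_matches_monte_carlo_variance_decomposition(self, rng):
        """On directly simulated aligned configurations (no superimposition),
        the reliability must equal an independently coded ME/SD decomposition."""
        n_spec, n_rep, k = 12, 3, 20
        sigma_t, sigma_e = 1.0, 0.2
        means = rng.normal(0.0, sigma_t, size=(n_spec, k, 3))
        reps = means[:, None] + rng.normal(0.0, sigma_e, size=(n_spec, n_rep, k, 3))

        from crestcurve.resampling import SemilandmarkCurve

        sets = [
            [SemilandmarkCurve(coords=reps[s, r], length_mm=1.0) for r in range(n_rep)]
            for s in range(n_spec)
        ]
        rep = measurement_error(sets, align=False)
        # independent oracle
        mu = reps.mean(axis=1)
        me = np.sqrt(((reps - mu[:, None]) ** 2).sum(-1).sum(1) / (n_rep - 1))
        me_l = me.mean(axis=0).mean()
        sd = np.sqrt(((mu - mu.mean(0)) ** 2).sum(-1).sum(0) / (n_spec - 1)).mean()
        expected = 1.0 - me_l**2 / sd**2
        assert rep.reliability == pytest.approx(expected, abs=1e-12)
        # and the decomposition tracks the generative variances
        assert rep.overall_me == pytest.approx(np.sqrt(3) * sigma_e, rel=0.15)
        assert rep.total_sd == pytest.approx(np.sqrt(3) * sigma_t, rel=0.15)

    def test_validation(self):
        with pytest.raises(InsufficientSampleError):
            measurement_error([self._repeat_sets(0.1)[0]])


class TestTypeIError:
    def test_rejection_rate_within_exact_binomial_bounds(self):
        """500 null two-group datasets (n=20 each) through the full pipeline:
        rejection rate at alpha = 0.05 within the exact binomial 99% interval."""
        from scipy.stats import binom

        from crestcurve.superimposition import gpa_with_sliding
        from crestcurve.synthetic import GroupParams, StudyDesign

        n_datasets, b = 500, 1000
        root = np.random.SeedSequence(20260925)
        rejections = 0
        for ss in root.spawn(n_datasets):
            seed = int(ss.generate_state(1)[0] % (2**31))
            g = GroupParams(name="null", n=40, ap_amplitude_mm=6.0,
                            ml_amplitude_mm=3.5, length_mm=354.0)
            d = StudyDesign(groups=[g], seed=seed)
            curves = [resample_equidistant(s.polyline) for s in generate_study(d)]
            aligned = gpa_with_sliding(curves)
            model = pca_shapes(aligned)
            r = max(1, model.n_retained_broken_stick)
            res = permutation_hotelling(
                model.scores[:20, :r], model.scores[20:, :r], b, seed=seed
            )
            rejections += res.p_value < 0.05
        lo = binom.ppf(0.005, n_datasets, 0.05)
        hi = binom.ppf(0.995, n_datasets, 0.05)
        assert lo <= rejections <= hi, f"{rejections}/{n_datasets} rejections"


def test_scalar_pairwise_matrix_labels(rng):
    vals = np.concatenate([rng.normal(350, 5, 10), rng.normal(380, 5, 10)])
    groups = ["a"] * 10 + ["b"] * 10
    mat = pairwise_scalar_tests(vals, groups, n_permutations=199, seed=0)
    assert mat.labels == ["a", "b"]
    assert mat.p_values[1, 0] < 0.05
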