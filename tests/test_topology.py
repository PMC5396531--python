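"""Path lengths, atrophy Z-transforms, residualization, correlation and the
subtype ANOVA, each checked against an independent closed-form or
brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connectolapse.simulate import SimulationConfig, generate_cohort
from connectolapse.topology import (
    anova_subtypes,
    compute_atrophy_table,
    fit_subject_slope,
    length_atrophy_correlation,
    residualize,
    shortest_paths,
    to_length_matrix,
    transform_score,
    tukey_kramer,
    zscore_cross,
    zscore_rate,
)


def floyd_warshall(lengths):
    """Triple-loop oracle for all-pairs shortest paths."""
    D = np.array(lengths, dtype=float)
    n = D.shape[0]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def random_symmetric(rng, n, density=0.4):
    A = rng.random((n, n)) * (rng.random((n, n)) < density)
    return np.triu(A, 1) + np.triu(A, 1).T


class TestLengthMatrix:
    def test_reciprocal_and_infinity(self):
        W = np.array([[0.0, 2.0, 0.0], [2.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        L = to_length_matrix(W)
        assert L[0, 1] == 0.5
        assert np.isinf(L[0, 2])
        assert np.all(np.diag(L) == 0.0)

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(0)
        W = random_symmetric(rng, 10)
        L = to_length_matrix(W)
        for i in range(10):
            for j in range(10):
                if i == j:
                    assert L[i, j] == 0.0
                elif W[i, j] > 0:
                    assert L[i, j] == 1.0 / W[i, j]
                else:
                    assert np.isinf(L[i, j])


class TestShortestPaths:
    def test_single_edge(self):
        W = np.array([[0.0, 4.0], [4.0, 0.0]])
        D = shortest_paths(to_length_matrix(W))
        assert D[0, 1] == pytest.approx(0.25)

    def test_triangle_detour_beats_weak_direct_edge(self):
        # AB=1, BC=1, AC=0.25: direct length 4, via B length 2
        W = np.array([[0.0, 1.0, 0.25], [1.0, 0.0, 1.0], [0.25, 1.0, 0.0]])
        D = shortest_paths(to_length_matrix(W))
        oracle = floyd_warshall(to_length_matrix(W))
        assert D[0, 2] == pytest.approx(2.0)
        assert np.allclose(D, oracle)

    def test_dijkstra_equals_floyd_warshall_on_random_graphs(self):
        # equality up to float summation order, which differs between the
        # two algorithms' path-sum accumulation
        for seed in range(20):
            rng = np.random.default_rng(seed)
            W = random_symmetric(rng, 20)
            Lm = to_length_matrix(W)
            assert np.allclose(shortest_paths(Lm), floyd_warshall(Lm), rtol=1e-12, atol=0.0)

    def test_triangle_inequality_and_symmetry(self):
        rng = np.random.default_rng(42)
        W = random_symmetric(rng, 15, density=0.6)
        D = shortest_paths(to_length_matrix(W))
        assert np.allclose(D, D.T)
        finite = np.isfinite(D)
        for k in range(15):
            lhs = D
            rhs = D[:, [k]] + D[[k], :]
            assert np.all(lhs[finite] <= rhs[finite] + 1e-12)


class TestZScores:
    def test_control_mean_maps_to_zero(self):
        assert zscore_cross(5.0, [3.0, 5.0, 7.0]) == pytest.approx(0.0)

    def test_one_sd_below(self):
        assert zscore_cross(3.0, [3.0, 5.0, 7.0]) == pytest.approx(-1.0)

    def test_hand_computed_sample_moments(self):
        # controls (3,5,7): mean 5, sample SD 2 -> (6-5)/2 = 0.5
        assert zscore_cross(6.0, (3.0, 5.0, 7.0)) == pytest.approx(0.5)
        assert zscore_rate(6.0, (3.0, 5.0, 7.0)) == pytest.approx(0.5)

    def test_degenerate_controls_rejected(self):
        with pytest.raises(ValueError, match="zero control variance"):
            zscore_cross(1.0, [2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="2 control"):
            zscore_cross(1.0, [2.0])


class TestTransform:
    @pytest.mark.parametrize("variant", ["logistic", "literal"])
    def test_zero_maps_to_half(self, variant):
        assert transform_score(0.0, variant) == pytest.approx(0.5)

    def test_logistic_closed_form(self):
        assert transform_score(np.log(3.0)) == pytest.approx(0.25)
        assert transform_score(-np.log(3.0)) == pytest.approx(0.75)

    def test_literal_is_sech_over_two(self):
        z = 1.3
        assert transform_score(z, "literal") == pytest.approx(1.0 / (np.exp(-z) + np.exp(z)))
        # the literal variant is symmetric, hence non-monotone
        assert transform_score(z, "literal") == pytest.approx(transform_score(-z, "literal"))

    @settings(max_examples=100, derandomize=True)
    @given(z=st.floats(-30, 30), dz=st.floats(1e-6, 10))
    def test_logistic_bounded_decreasing_and_complementary(self, z, dz):
        s = transform_score(z)
        assert 0.0 < s < 1.0
        assert transform_score(z + dz) < s
        assert s + transform_score(-z) == pytest.approx(1.0, abs=1e-12)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            transform_score(0.0, "probit")


class TestSubjectSlope:
    def test_exact_line(self):
        assert fit_subject_slope([0, 1, 2], [3, 2, 1]) == pytest.approx(-1.0)

    def test_constant_values(self):
        assert fit_subject_slope([0, 1, 2], [4, 4, 4]) == pytest.approx(0.0)

    def test_closed_form_sum_formula(self):
        # sum((t-tbar)(y-ybar)) / sum((t-tbar)^2) = 3/2
        assert fit_subject_slope([0, 1, 2], [1, 1, 4]) == pytest.approx(1.5)

    def test_needs_two_distinct_times(self):
        with pytest.raises(ValueError):
            fit_subject_slope([1.0], [2.0])
        with pytest.raises(ValueError):
            fit_subject_slope([1.0, 1.0], [2.0, 3.0])


class TestResidualize:
    def test_values_linear_in_age_go_to_zero(self):
        age = np.array([30.0, 40.0, 50.0, 60.0])
        sex = np.array(["M", "F", "M", "F"])
        values = 2.0 * age + 1.0
        res = residualize(values, age, sex)
        assert np.allclose(res, 0.0, atol=1e-10)

    def test_constant_covariates_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            residualize(np.array([1.0, 2.0, 3.0]), [40, 40, 40], ["M", "M", "M"])

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(8)
        n = 30
        age = rng.normal(45, 8, n)
        sex = rng.integers(0, 2, n).astype(float)
        values = rng.normal(size=(n, 5))
        res = residualize(values, age, sex)
        assert np.max(np.abs(age @ res)) < 1e-8
        assert np.max(np.abs(sex @ res)) < 1e-8
        assert np.max(np.abs(res.sum(axis=0))) < 1e-8


def spearman_oracle(x, y):
    """Rank-and-Pearson oracle with explicit average-rank tie handling."""

    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), dtype=float)
        i = 0
        sv = np.array(v)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestCorrelation:
    def test_perfectly_monotone(self):
        res = length_atrophy_correlation([1, 2, 3, 4], [0.1, 0.2, 0.3, 0.4])
        assert res.rho == pytest.approx(1.0)
        assert res.df == 2

    def test_reversed(self):
        res = length_atrophy_correlation([1, 2, 3, 4], [0.4, 0.3, 0.2, 0.1])
        assert res.rho == pytest.approx(-1.0)

    def test_tied_values_match_rank_oracle(self):
        L = [1.0, 1.0, 2.0, 3.0, 3.0, 4.0]
        s = [0.2, 0.3, 0.3, 0.5, 0.4, 0.6]
        res = length_atrophy_correlation(L, s)
        assert res.rho == pytest.approx(spearman_oracle(L, s))

    def test_infinite_lengths_excluded_and_counted(self):
        L = [1.0, 2.0, np.inf, 3.0, 4.0]
        s = [0.1, 0.2, 0.3, 0.4, 0.5]
        res = length_atrophy_correlation(L, s)
        assert res.n_excluded == 1
        assert res.n == 4
        assert res.df == 2


class TestAnovaTukey:
    def test_sum_of_squares_oracle(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0, 8.0], "c": [10.0, 12.0]}
        F, df1, df2, p = anova_subtypes(groups)
        # textbook decomposition by explicit sums
        allv = np.concatenate([np.asarray(v) for v in groups.values()])
        grand = allv.mean()
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_within = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        F_oracle = (ss_between / 2) / (ss_within / (len(allv) - 3))
        assert F == pytest.approx(F_oracle)
        assert (df1, df2) == (2, len(allv) - 3)

    def test_identical_groups_give_f_near_zero(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        F, *_ = anova_subtypes(groups)
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_tukey_kramer_flags_separated_groups(self):
        rng = np.random.default_rng(3)
        groups = {
            "low": rng.normal(0.0, 0.1, 20),
            "mid": rng.normal(1.0, 0.1, 15),
            "high": rng.normal(2.0, 0.1, 25),
        }
        table = tukey_kramer(groups)
        assert len(table) == 3
        assert (table["p_adj"] < 0.01).all()

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_subtypes({"a": [1.0, 2.0]})


class TestAtrophyTable:
    def test_null_cohort_scores_near_half(self):
        cfg = SimulationConfig(
            n_controls=15, n_preHD=15, modules_per_hemisphere=1, cortical_per_module=3,
            n_striatal=2, baseline_deficit=0.0, rate_intercept=0.0, rate_slope=0.0,
            noise_sd=0.05, subject_intercept_sd=0.0, subject_slope_sd=0.0,
            covariate_effects={}, seed=5,
        )
        dataset, truth = generate_cohort(cfg)
        table = compute_atrophy_table(dataset, truth.true_partition, truth.path_lengths)
        assert abs(table["score_cross"].mean() - 0.5) < 0.05
        assert abs(table["score_long"].mean() - 0.5) < 0.05

    def test_degeneration_shifts_scores_above_half(self, tiny_cohort):
        dataset, truth = tiny_cohort
        table = compute_atrophy_table(dataset, truth.true_partition, truth.path_lengths)
        # cortico-striatal connections are the longest and decline fastest
        cs = table[table["subtype"] == "cortico_striatal"]
        im = table[table["subtype"] == "intramodular"]
        assert cs["score_cross"].mean() > im["score_cross"].mean() > 0.45
        assert cs["score_long"].mean() > im["score_long"].mean()
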