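"""Pointwise ANCOVA/partial-correlation and cluster-based permutation
correction, checked against independent brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from alongtract.stats import (
    DEFAULT_F_THRESHOLD,
    DesignMatrix,
    encode_covariates,
    find_clusters,
    permutation_cbs,
    pointwise_ancova_f,
    pointwise_partial_r,
    r_threshold_from_f,
)


def anova_oracle(y, groups):
    """Closed-form one-way ANOVA F from between/within sums of squares."""
    y = np.asarray(y, dtype=float)
    labels = np.unique(groups)
    grand = y.mean()
    ssb = sum(
        (groups == g).sum() * (y[groups == g].mean() - grand) ** 2 for g in labels
    )
    ssw = sum(((y[groups == g] - y[groups == g].mean()) ** 2).sum() for g in labels)
    df_b = len(labels) - 1
    df_w = len(y) - len(labels)
    return (ssb / df_b) / (ssw / df_w)


def partial_r_oracle(y, m, Z):
    """Two-stage regression: residualise both on [1, Z], then correlate."""
    X = np.column_stack([np.ones(len(y)), Z])
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    rm = m - X @ np.linalg.lstsq(X, m, rcond=None)[0]
    return float(ry @ rm / (np.linalg.norm(ry) * np.linalg.norm(rm)))


def _design(group, covs=None, n=None):
    n = n or len(group)
    Z = np.empty((n, 0)) if covs is None else np.asarray(covs, float).reshape(n, -1)
    return DesignMatrix(group=np.asarray(group, float), covariates=Z)


class TestAncovaF:
    def test_toy_groups_reduce_to_one_way_anova(self):
        """{1,2,3} vs {4,5,6} with no covariates gives F = 13.5."""
        Y = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        stat = pointwise_ancova_f(Y, _design([1, 1, 1, 0, 0, 0]))
        assert stat.values[0] == pytest.approx(13.5, abs=1e-10)
        groups = np.array(["a"] * 3 + ["b"] * 3)
        assert stat.values[0] == pytest.approx(anova_oracle(Y[:, 0], groups))

    def test_identical_group_means_with_null_covariate_give_zero(self):
        Y = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
        stat = pointwise_ancova_f(Y, _design([1, 1, 1, 0, 0, 0],
                                             covs=np.zeros((6, 0))))
        assert stat.values[0] == pytest.approx(0.0, abs=1e-10)

    def test_row_duplication_changes_f_per_closed_form(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=8)
        g = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        labels = np.where(g == 1, "a", "b")
        base = pointwise_ancova_f(y[:, None], _design(g)).values[0]
        y2, g2 = np.tile(y, 2), np.tile(g, 2)
        doubled = pointwise_ancova_f(y2[:, None], _design(g2)).values[0]
        assert base == pytest.approx(anova_oracle(y, labels))
        assert doubled == pytest.approx(anova_oracle(y2, np.tile(labels, 2)))
        assert doubled > base  # same means, more df

    def test_matches_explicit_nested_regression_with_covariates(self):
        rng = np.random.default_rng(1)
        n, P = 20, 5
        Y = rng.normal(size=(n, P))
        g = np.array([1.0] * 10 + [0.0] * 10)
        Z = rng.normal(size=(n, 2))
        stat = pointwise_ancova_f(Y, _design(g, covs=Z))
        Xr = np.column_stack([np.ones(n), Z])
        Xf = np.column_stack([Xr, g])
        for j in range(P):
            rss_r = np.sum((Y[:, j] - Xr @ np.linalg.lstsq(Xr, Y[:, j], rcond=None)[0]) ** 2)
            rss_f = np.sum((Y[:, j] - Xf @ np.linalg.lstsq(Xf, Y[:, j], rcond=None)[0]) ** 2)
            expected = (rss_r - rss_f) / (rss_f / (n - Xf.shape[1]))
            assert stat.values[j] == pytest.approx(expected, rel=1e-9)

    def test_rank_deficient_design_rejected_with_column_names(self):
        Y = np.random.default_rng(2).normal(size=(8, 3))
        g = np.array([1.0] * 4 + [0.0] * 4)
        with pytest.raises(ValueError, match="group"):
            pointwise_ancova_f(Y, DesignMatrix(group=g, covariates=g[:, None],
                                               covariate_names=("copy_of_group",)))

    def test_too_few_subjects_per_group_rejected(self):
        Y = np.zeros((3, 2))
        with pytest.raises(ValueError, match="2 subjects"):
            pointwise_ancova_f(Y, _design([1, 0, 0]))


class TestPartialR:
    def test_measure_equal_to_fa_gives_unit_correlation(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=10)
        stat = pointwise_partial_r(y[:, None], y, np.empty((10, 0)))
        assert stat.values[0] == pytest.approx(1.0, abs=1e-10)

    def test_measure_equal_to_covariate_partials_to_zero(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(12, 3))
        cov = rng.normal(size=12)
        stat = pointwise_partial_r(Y, cov, cov[:, None])
        assert np.all(stat.flags)  # residual measure has zero variance
        assert np.allclose(stat.values, 0.0)

    def test_six_subject_toy_matches_two_stage_oracle(self):
        Y = np.array(
            [[0.41, 0.52], [0.44, 0.50], [0.39, 0.55],
             [0.47, 0.48], [0.42, 0.53], [0.45, 0.51]]
        )
        measure = np.array([21.0, 17.0, 25.0, 12.0, 19.0, 15.0])
        Z = np.array([[46.0, 0], [51.0, 1], [39.0, 0],
                      [58.0, 1], [44.0, 0], [49.0, 1]])
        stat = pointwise_partial_r(Y, measure, Z)
        for j in range(2):
            assert stat.values[j] == pytest.approx(
                partial_r_oracle(Y[:, j], measure, Z), abs=1e-10
            )

    def test_zero_variance_point_flagged_as_zero(self):
        Y = np.column_stack([np.full(8, 0.5), np.random.default_rng(5).normal(size=8)])
        m = np.arange(8, dtype=float)
        stat = pointwise_partial_r(Y, m, np.empty((8, 0)))
        assert stat.flags[0] and not stat.flags[1]
        assert stat.values[0] == 0.0


class TestFindClusters:
    @pytest.mark.parametrize(
        "values, threshold, expected",
        [
            ([1, 3, 3, 1, 3], 2.5, [(1, 2, 2), (4, 4, 1)]),
            ([1, 2, 1], 2.5, []),
            ([3] * 100, 2.5, [(0, 99, 100)]),
            ([2.5, 2.5], 2.5, []),  # strictly greater than the threshold
        ],
    )
    def test_examples(self, values, threshold, expected):
        assert find_clusters(np.asarray(values, float), threshold) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            find_clusters(np.array([1.0, np.nan]), 2.5)


def exact_cbs_oracle(Y, group, threshold):
    """Independent exhaustive enumeration of the label-permutation null.

    Recomputes the one-way F profile per arrangement with explicit
    regression and counts cluster sizes with its own run-length scan.
    """

    def f_profile(g):
        return np.array([anova_oracle(Y[:, j], np.where(np.asarray(g) == 1, "a", "b"))
                         for j in range(Y.shape[1])])

    def max_run(vals):
        best = cur = 0
        for v in vals:
            cur = cur + 1 if v > threshold else 0
            best = max(best, cur)
        return best

    arrangements = sorted(set(itertools.permutations(group.tolist())))
    null = [max_run(f_profile(np.asarray(a))) for a in arrangements]
    observed = f_profile(group)
    clusters = []
    j = 0
    while j < len(observed):
        if observed[j] > threshold:
            k = j
            while k < len(observed) and observed[k] > threshold:
                k += 1
            clusters.append((j, k - 1, k - j))
            j = k
        else:
            j += 1
    p = [sum(m >= size for m in null) / len(null) for _, _, size in clusters]
    return clusters, np.array(p)


class TestPermutationCBS:
    def test_exact_enumeration_matches_independent_oracle(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(4, 12))
        Y[:2] += 1.4  # push a real difference into the cases
        g = np.array([1.0, 1.0, 0.0, 0.0])
        result = permutation_cbs(Y, design=_design(g), test="ancova_f",
                                 threshold=2.5, exact=True)
        clusters, p = exact_cbs_oracle(Y, g, 2.5)
        assert result.clusters == clusters
        assert np.allclose(result.corrected_p, p)

    def test_formula_floor_when_observed_beats_every_permutation(self):
        rng = np.random.default_rng(7)
        n_per = 15
        Y = rng.normal(scale=0.3, size=(2 * n_per, 10))
        Y[:n_per] += 1.0  # overwhelming group effect on all 10 points
        g = np.array([1.0] * n_per + [0.0] * n_per)
        # a cluster-forming threshold far above anything label shuffles reach
        result = permutation_cbs(Y, design=_design(g), test="ancova_f",
                                 threshold=50.0, n_permutations=200, seed=11)
        (start, end, size) = result.clusters[0]
        assert size == 10
        assert result.null_max_sizes.max() < size
        assert result.corrected_p[0] == pytest.approx(1 / 201)

    def test_corrected_p_consistent_with_null_distribution(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(20, 40))
        Y[:10, 5:15] += 0.9
        Y[:10, 30:33] += 0.9
        g = np.array([1.0] * 10 + [0.0] * 10)
        result = permutation_cbs(Y, design=_design(g), test="ancova_f",
                                 n_permutations=300, seed=12)
        assert len(result.clusters) >= 2
        for (s, e, size), p in zip(result.clusters, result.corrected_p):
            expected = (1 + (result.null_max_sizes >= size).sum()) / 301
            assert p == pytest.approx(expected)
        # monotone: larger clusters never get larger p
        sizes = [c[2] for c in result.clusters]
        order = np.argsort(sizes)
        assert np.all(np.diff(np.asarray(result.corrected_p)[order]) <= 1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        Y = rng.normal(size=(16, 30))
        Y[:8, 10:20] += 0.8
        g = np.array([1.0] * 8 + [0.0] * 8)
        cov = rng.normal(size=(16, 2))
        a = permutation_cbs(Y, design=_design(g, covs=cov), n_permutations=150, seed=3)
        b = permutation_cbs(Y, design=_design(g, covs=cov), n_permutations=150, seed=3)
        assert np.array_equal(a.corrected_p, b.corrected_p)
        assert np.array_equal(a.null_max_sizes, b.null_max_sizes)

    def test_no_observed_clusters_returns_note(self):
        Y = np.random.default_rng(10).normal(scale=1e-3, size=(10, 8))
        g = np.array([1.0] * 5 + [0.0] * 5)
        result = permutation_cbs(Y, design=_design(g), threshold=1e6,
                                 n_permutations=100, seed=0)
        assert result.clusters == [] and "no supra-threshold" in result.note

    def test_partial_r_permutation_runs_and_detects_strong_coupling(self):
        rng = np.random.default_rng(13)
        n = 24
        latent = rng.normal(size=n)
        Y = rng.normal(scale=0.1, size=(n, 30))
        Y[:, 10:20] += latent[:, None]
        measure = latent * 2.0 + rng.normal(scale=0.1, size=n)
        covs = rng.normal(size=(n, 2))
        result = permutation_cbs(Y, measure=measure, covariates=covs,
                                 test="partial_r", n_permutations=200, seed=4)
        # the planted block is found as the dominant cluster; its corrected p
        # is bounded below by the chance of the permuted measure correlating
        # with the shared latent factor, so ~0.1 is the attainable floor here
        best = min(zip(result.corrected_p, result.clusters))
        (p_best, (s, e, size)) = best
        assert size >= 8 and s >= 9 and e <= 20
        assert p_best < 0.15
        assert all(p > 0.5 for p, c in zip(result.corrected_p, result.clusters)
                   if c[2] == 1)

    def test_too_few_permutations_rejected(self):
        Y = np.random.default_rng(14).normal(size=(8, 5))
        g = np.array([1.0] * 4 + [0.0] * 4)
        with pytest.raises(ValueError, match="100"):
            permutation_cbs(Y, design=_design(g), n_permutations=50, seed=0)


def test_r_threshold_matches_f_threshold_relation():
    # t^2 = F at one numerator df; r = t / sqrt(t^2 + df)
    n, c = 30, 2
    r_th = r_threshold_from_f(DEFAULT_F_THRESHOLD, n, c)
    df = n - 2 - c
    t = r_th * np.sqrt(df / (1 - r_th**2))
    assert t**2 == pytest.approx(DEFAULT_F_THRESHOLD, rel=1e-12)


def test_encode_covariates_sex_and_missing():
    table = pd.DataFrame({"age": [40.0, 50.0], "sex": ["F", "M"]})
    Z = encode_covariates(table, ("age", "sex"))
    assert Z.shape == (2, 2)
    assert list(Z[:, 1]) == [0.0, 1.0]  # F is the dropped reference level
    table.loc[0, "age"] = np.nan
    with pytest.raises(ValueError, match="missing"):
        encode_covariates(table, ("age",))


def test_design_from_table():
    table = pd.DataFrame(
        {"group": ["case", "control", "case", "control"],
         "age": [40.0, 45, 50, 55], "bmi": [22.0, 23, 24, 25]}
    )
    d = DesignMatrix.from_table(table)
    assert list(d.group) == [1.0, 0.0, 1.0, 0.0]
    assert d.covariates.shape == (4, 2)
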