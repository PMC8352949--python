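"""Tract Diffusion Profiles: density maps, representatives, point matching,
FA projection, group-wise selection and resampling."""

import itertools

import numpy as np
import pytest

from alongtract.bundles import LabeledTract
from alongtract.profiles import (
    GROUP_PROFILE_POINTS,
    TractDiffusionProfile,
    density_sum,
    fiber_density_map,
    groupwise_representative,
    match_and_project,
    optimal_point_match,
    project_fa,
    resample_profile,
    resample_points,
    select_representative,
    subject_profiles_on_group,
)
from alongtract.synthetic import default_bundle_specs, generate_cohort


def line(y=0.0, z=0.0, n=10, length=9.0, x0=0.0):
    x = np.linspace(x0, x0 + length, n)
    return np.column_stack([x, np.full(n, y), np.full(n, z)])


GRID = ((12, 5, 5), np.eye(4))


class TestDensityMap:
    def test_single_straight_streamline_counts_one_per_voxel(self):
        s = line(y=2, z=2, n=10, length=9.0)
        dm = fiber_density_map([s], *GRID)
        assert dm.counts.sum() == 10
        assert set(np.unique(dm.counts)) == {0, 1}

    def test_identical_streamlines_stack_counts(self):
        s = line(y=2, z=2)
        dm = fiber_density_map([s.copy() for _ in range(4)], *GRID)
        assert set(np.unique(dm.counts)) == {0, 4}

    def test_crossing_streamlines_overlap_in_one_voxel(self):
        a = line(y=2, z=2)
        b = np.column_stack([np.full(5, 4.0), np.linspace(0, 4, 5), np.full(5, 2.0)])
        dm = fiber_density_map([a, b], *GRID)
        assert dm.counts[4, 2, 2] == 2
        assert (dm.counts == 2).sum() == 1

    def test_duplicate_points_in_voxel_count_once(self):
        s = np.array([[2.0, 2, 2], [2.2, 2, 2], [2.4, 2, 2]])
        dm = fiber_density_map([s], *GRID)
        assert dm.counts.max() == 1

    def test_total_invariant_to_streamline_order(self):
        rng = np.random.default_rng(1)
        lines = [line(y=rng.uniform(0, 4), z=2) for _ in range(6)]
        a = fiber_density_map(lines, *GRID).counts
        b = fiber_density_map(lines[::-1], *GRID).counts
        assert np.array_equal(a, b)

    def test_points_outside_grid_ignored_with_warning(self):
        s = np.column_stack([np.linspace(-5, 5, 11), np.full(11, 2.0), np.full(11, 2.0)])
        with pytest.warns(UserWarning, match="outside"):
            dm = fiber_density_map([s], *GRID)
        assert dm.counts.sum() == 6  # only x in [0, 5] with x >= 0 voxels


class TestRepresentative:
    def _brute_force_best(self, tract, dm):
        sums = [density_sum(s, dm) for s in tract.streamlines]
        best = max(sums)
        return sums.index(best), best

    def test_single_member_is_selected(self):
        tract = LabeledTract("CST", "left", [line(y=2, z=2)])
        dm = fiber_density_map(tract.streamlines, *GRID)
        rep = select_representative(tract, dm)
        assert rep.index == 0

    def test_central_member_wins_by_shared_voxels(self):
        # middle streamline zigzags through both neighbours' voxel rows
        a = line(y=1, z=2)
        b = line(y=3, z=2)
        mid_y = np.tile([1.0, 3.0], 5)
        mid = np.column_stack([np.linspace(0, 9, 10), mid_y, np.full(10, 2.0)])
        tract = LabeledTract("CST", "left", [a, mid, b])
        dm = fiber_density_map(tract.streamlines, *GRID)
        rep = select_representative(tract, dm)
        oracle_idx, oracle_sum = self._brute_force_best(tract, dm)
        assert rep.index == oracle_idx == 1
        assert rep.density_sum == oracle_sum

    def test_exact_tie_goes_to_lowest_index(self):
        tract = LabeledTract("CST", "left", [line(y=1, z=2), line(y=3, z=2)])
        dm = fiber_density_map(tract.streamlines, *GRID)
        assert select_representative(tract, dm).index == 0

    def test_matches_brute_force_on_random_bundles(self):
        rng = np.random.default_rng(3)
        lines = [line(y=2 + rng.uniform(-1.5, 1.5), z=2) for _ in range(7)]
        tract = LabeledTract("CST", "left", lines)
        dm = fiber_density_map(lines, *GRID)
        rep = select_representative(tract, dm)
        oracle_idx, _ = self._brute_force_best(tract, dm)
        assert rep.index == oracle_idx


def oracle_best_monotone_cost(rep, mem):
    """Exhaustive enumeration over all monotone total maps (tiny inputs)."""
    m, r = len(mem), len(rep)
    d = np.linalg.norm(mem[:, None, :] - rep[None, :, :], axis=2)
    best = np.inf
    for assign in itertools.combinations_with_replacement(range(r), m):
        cost = sum(d[i, j] for i, j in enumerate(assign))
        best = min(best, cost)
    return best


class TestOptimalPointMatch:
    def test_identical_inputs_identity_mapping(self):
        s = line(n=8)
        corr = optimal_point_match(s, s)
        assert np.array_equal(corr.indices, np.arange(8))
        assert corr.cost == 0.0 and not corr.flipped

    def test_collinear_different_point_counts_proportional(self):
        rep = line(n=11, length=10.0)
        mem = line(n=5, length=10.0)
        corr = optimal_point_match(rep, mem)
        # arc-length proportional mapping: member point k sits at x=2.5k
        assert np.all(np.diff(corr.indices) >= 0)
        assert corr.indices[0] == 0 and corr.indices[-1] == 10
        expected_x = np.array([0.0, 2.5, 5.0, 7.5, 10.0])
        matched_x = rep[corr.indices, 0]
        assert np.all(np.abs(matched_x - expected_x) <= 0.5)

    def test_reversed_member_flip_detected_same_mapping(self):
        rng = np.random.default_rng(4)
        rep = np.cumsum(rng.normal(size=(9, 3)) + [1, 0, 0], axis=0)
        mem = rep + rng.normal(scale=0.1, size=rep.shape)
        fwd = optimal_point_match(rep, mem)
        rev = optimal_point_match(rep, mem[::-1])
        assert not fwd.flipped and rev.flipped
        assert np.array_equal(fwd.indices, rev.indices)
        assert fwd.cost == pytest.approx(rev.cost, abs=1e-12)

    def test_matches_exhaustive_oracle_on_small_streamlines(self):
        rng = np.random.default_rng(5)
        for m, r in [(4, 6), (6, 6), (7, 5), (5, 10)]:
            rep = np.cumsum(rng.normal(size=(r, 3)) + [1, 0, 0], axis=0)
            mem = np.cumsum(rng.normal(size=(m, 3)) + [1, 0, 0], axis=0)
            corr = optimal_point_match(rep, mem)
            mem_oriented = mem[::-1] if corr.flipped else mem
            assert corr.cost == pytest.approx(
                oracle_best_monotone_cost(rep, mem_oriented), abs=1e-10
            )
            d = np.linalg.norm(mem_oriented[:, None] - rep[None], axis=2)
            assert sum(d[i, j] for i, j in enumerate(corr.indices)) == pytest.approx(
                corr.cost, abs=1e-10
            )

    def test_mapping_is_monotone(self):
        rng = np.random.default_rng(6)
        rep = np.cumsum(rng.normal(size=(20, 3)) + [1, 0, 0], axis=0)
        mem = np.cumsum(rng.normal(size=(30, 3)) + [1, 0, 0], axis=0)
        corr = optimal_point_match(rep, mem)
        assert np.all(np.diff(corr.indices) >= 0)
        assert len(corr.indices) == 30


class TestProjection:
    def test_constant_fa_projects_to_constant(self):
        rep = line(n=6)
        members = [rep + [0, dy, 0] for dy in (-1, 0, 1, 2)]
        fa = [np.full(6, 0.43) for _ in members]
        corrs = [optimal_point_match(rep, m) for m in members]
        profile = project_fa(members, fa, corrs, rep)
        assert np.allclose(profile.values, 0.43)

    def test_single_member_maps_its_fa(self):
        rep = line(n=6)
        fa = np.linspace(0.2, 0.7, 6)
        corr = optimal_point_match(rep, rep)
        profile = project_fa([rep], [fa], [corr], rep)
        assert np.allclose(profile.values, fa)

    def test_weighted_mean_matches_hand_computation(self):
        """Three parallel members: hand-evaluate the Mahalanobis weights."""
        rep = line(n=5)
        offsets = [-1.0, 0.0, 2.0]
        members = [rep + [0, dy, 0] for dy in offsets]
        fa_vals = [0.2, 0.5, 0.8]
        fa = [np.full(5, v) for v in fa_vals]
        corrs = [optimal_point_match(rep, m) for m in members]
        profile = project_fa(members, fa, corrs, rep)
        # hand computation at any point: contributors at y=-1,0,2 (1-D spread)
        y = np.array(offsets)
        centered = y - y.mean()
        # rank-1 covariance in 3-D -> documented fallback to uniform weights
        expected = np.mean(fa_vals)
        assert np.allclose(profile.values, expected)

    def test_weights_decrease_with_mahalanobis_distance(self):
        rng = np.random.default_rng(7)
        rep = line(n=5)
        members = [rep + rng.normal(scale=0.5, size=rep.shape) for _ in range(6)]
        fa = [np.full(5, 0.5) for _ in members]
        fa[0] = np.full(5, 0.9)  # outlying FA on the first member
        corrs = [optimal_point_match(rep, m) for m in members]
        profile = project_fa(members, fa, corrs, rep)
        # convex combination: bounded by contributing member FA range
        assert np.all(profile.values >= 0.5 - 1e-12)
        assert np.all(profile.values <= 0.9 + 1e-12)

    def test_unmatched_representative_point_flagged_with_own_fa(self):
        rep = line(n=10)
        short = line(n=2, length=1.0)  # maps onto few rep points
        corr = optimal_point_match(rep, short)
        rep_fa = np.linspace(0.3, 0.6, 10)
        profile = project_fa([short], [np.array([0.5, 0.5])], [corr], rep,
                             representative_fa=rep_fa)
        assert profile.flags.sum() >= 7
        for j in np.flatnonzero(profile.flags):
            assert profile.values[j] == pytest.approx(rep_fa[j])

    def test_profile_bounded_by_member_fa_range(self):
        rng = np.random.default_rng(8)
        rep = line(n=12)
        members = [rep + rng.normal(scale=0.3, size=rep.shape) for _ in range(5)]
        fa = [rng.uniform(0.3, 0.7, size=12) for _ in members]
        corrs = [optimal_point_match(rep, m) for m in members]
        profile = project_fa(members, fa, corrs, rep)
        lo, hi = min(f.min() for f in fa), max(f.max() for f in fa)
        assert np.all(profile.values >= lo - 1e-12)
        assert np.all(profile.values <= hi + 1e-12)


class TestGroupwise:
    def _reps(self, n_present, n_total):
        reps = {}
        for i in range(n_total):
            sid = f"sub-{i:02d}"
            reps[sid] = line(y=0.1 * i) if i < n_present else None
        return reps

    def test_tract_present_in_all_subjects_retained(self):
        sel = groupwise_representative(self._reps(10, 10))
        assert sel is not None
        assert len(sel[2]) == 10

    def test_strictly_more_than_60_percent_support(self):
        assert groupwise_representative(self._reps(6, 10)) is None  # 60% fails
        sel = groupwise_representative(self._reps(7, 10))  # 70% passes
        assert sel is not None

    def test_shared_geometry_recovers_common_centerline(self):
        specs = [s for s in default_bundle_specs(n_streamlines=6)
                 if s.key == ("CST", "left")]
        cohort = generate_cohort(2, 2, bundle_specs=specs, seed=9, noise_sd=0.0)
        reps = {}
        for subj in cohort.subjects:
            lines = cohort.streamlines[subj.subject_id][("CST", "left")]
            reps[subj.subject_id] = lines[0]
        sel = groupwise_representative(reps)
        assert sel is not None
        centerline = np.asarray(specs[0].centerline(np.linspace(0, 1, 50)))
        from alongtract.bundles import streamline_distance

        assert streamline_distance(sel[1], centerline) < 3.0

    def test_absent_everywhere_returns_none(self):
        assert groupwise_representative({"a": None, "b": None}) is None


class TestResampling:
    def _profile(self, values):
        return TractDiffusionProfile(np.asarray(values), "CST", "left", "group")

    def test_constant_profile_stays_constant_at_100_points(self):
        out = resample_profile(self._profile(np.full(37, 0.5)))
        assert out.n_points == GROUP_PROFILE_POINTS == 100
        assert np.allclose(out.values, 0.5)

    def test_linear_ramp_reproduced_exactly(self):
        ramp = np.linspace(0.2, 0.8, 25)
        out = resample_profile(self._profile(ramp))
        assert np.allclose(out.values, np.linspace(0.2, 0.8, 100), atol=1e-10)

    def test_short_profile_linear_fallback(self):
        out = resample_profile(self._profile([0.2, 0.4, 0.6]), n_points=10)
        assert np.allclose(out.values, np.linspace(0.2, 0.6, 10), atol=1e-12)

    def test_points_resampling_preserves_endpoints(self):
        s = line(n=9, length=30.0)
        out = resample_points(s, 100)
        assert out.shape == (100, 3)
        assert np.allclose(out[0], s[0], atol=1e-9)
        assert np.allclose(out[-1], s[-1], atol=1e-9)


def test_match_and_project_end_to_end_single_tract():
    specs = [s for s in default_bundle_specs(n_streamlines=8)
             if s.key == ("SLF", "right")]
    cohort = generate_cohort(1, 1, bundle_specs=specs, seed=11, noise_sd=0.0)
    sid = cohort.subjects[0].subject_id
    tract = LabeledTract("SLF", "right",
                         cohort.streamlines[sid][("SLF", "right")],
                         fa=cohort.fa[sid][("SLF", "right")])
    from alongtract.profiles import make_grid

    shape, affine = make_grid(tract.streamlines)
    dm = fiber_density_map(tract.streamlines, shape, affine)
    rep = select_representative(tract, dm)
    profile = match_and_project(tract, rep, subject_id=sid)
    target = np.asarray(specs[0].baseline_fa_profile(np.linspace(0, 1, len(profile.values))))
    assert np.sqrt(np.mean((profile.values - target) ** 2)) < 0.02


def test_subject_profiles_on_group_alignment():
    group_pts = line(n=20, length=40.0)
    subj = {
        "a": (line(n=15, length=40.0), np.full(15, 0.4)),
        "b": (line(n=25, length=40.0), np.full(25, 0.6)),
    }
    Y, order = subject_profiles_on_group(group_pts, subj)
    assert order == ["a", "b"]
    assert np.allclose(Y[0], 0.4) and np.allclose(Y[1], 0.6)
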