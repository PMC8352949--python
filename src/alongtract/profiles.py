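"""Tract Diffusion Profiles: along-tract FA sampled on representative
streamlines.

For each labeled tract the member streamline with the largest fiber-density
sum is selected as the representative; every other member is matched to it
point-by-point with a monotone optimal-matching dynamic program; member FA
values are projected onto the representative with Mahalanobis-distance
weights; a group-wise representative is selected across subjects by the
same density rule (subject to a >60% support constraint) and resampled to
100 equidistant arc-length sample points with a cubic spline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .bundles import LabeledTract, streamline_distance
from .geometry import as_streamline

logger = logging.getLogger(__name__)

GROUP_PROFILE_POINTS = 100  # group-wise profiles are resampled to this
SUPPORT_FRACTION = 0.60  # a group tract needs strictly more support


# ---------------------------------------------------------------------------
# fiber density


@dataclass
class FiberDensityMap:
    """Per-voxel streamline visit counts on a subject grid."""

    counts: np.ndarray  # (X, Y, Z) int
    affine: np.ndarray  # voxel -> world mm


def make_grid(streamlines, voxel_size: float = 2.0, pad: int = 2):
    """A voxel grid (shape, affine) bounding a set of streamlines."""
    pts = np.concatenate([np.asarray(s) for s in streamlines])
    lo = pts.min(axis=0) - pad * voxel_size
    hi = pts.max(axis=0) + pad * voxel_size
    shape = tuple(np.ceil((hi - lo) / voxel_size).astype(int) + 1)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    affine[:3, 3] = lo
    return shape, affine


def _world_to_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    return np.round(points @ inv[:3, :3].T + inv[:3, 3]).astype(int)


def fiber_density_map(streamlines, shape, affine) -> FiberDensityMap:
    """Count, per voxel, how many distinct streamlines pass through it.

    A streamline increments a voxel at most once however many of its points
    fall inside. Points outside the grid are ignored with a warning.
    """
    counts = np.zeros(shape, dtype=int)
    outside = False
    for sl in streamlines:
        vox = _world_to_voxel(np.asarray(sl, dtype=float), affine)
        inside = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
        if not inside.all():
            outside = True
        vox = np.unique(vox[inside], axis=0)
        counts[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
    if outside:
        warnings.warn("streamline points outside the density grid were ignored")
    return FiberDensityMap(counts=counts, affine=affine)


@dataclass
class RepresentativeStreamline:
    """The density-maximal member of a tract."""

    index: int
    points: np.ndarray
    density_sum: float


def density_sum(streamline, density: FiberDensityMap) -> float:
    """Sum of density counts over the distinct voxels a streamline visits."""
    shape = np.array(density.counts.shape)
    vox = _world_to_voxel(np.asarray(streamline, dtype=float), density.affine)
    vox = vox[np.all((vox >= 0) & (vox < shape), axis=1)]
    vox = np.unique(vox, axis=0)
    return float(density.counts[vox[:, 0], vox[:, 1], vox[:, 2]].sum())


def select_representative(
    tract: LabeledTract, density: FiberDensityMap
) -> RepresentativeStreamline:
    """Pick the member with maximal summed fiber density along its path.

    A long streamline through the core of the bundle accumulates the most
    counts, so the winner is a long, central fiber. Exact ties go to the
    lowest member index.
    """
    sums = np.array([density_sum(s, density) for s in tract.streamlines])
    idx = int(np.argmax(sums))  # argmax returns the first maximum
    return RepresentativeStreamline(
        index=idx,
        points=np.asarray(tract.streamlines[idx], dtype=float),
        density_sum=float(sums[idx]),
    )


# ---------------------------------------------------------------------------
# optimal point matching


@dataclass
class Correspondence:
    """Monotone total mapping from member points to representative indices.

    ``indices[i]`` is the representative point matched to the i-th point of
    the orientation-normalised member (reversed first when ``flipped``);
    ``cost`` is the summed Euclidean distance of all matched pairs.
    """

    indices: np.ndarray
    flipped: bool
    cost: float


def _should_flip(rep: np.ndarray, member: np.ndarray) -> bool:
    direct = np.linalg.norm(member[0] - rep[0]) + np.linalg.norm(member[-1] - rep[-1])
    crossed = np.linalg.norm(member[0] - rep[-1]) + np.linalg.norm(member[-1] - rep[0])
    return crossed < direct


def optimal_point_match(representative, member) -> Correspondence:
    """Monotone minimum-cost point correspondence (dynamic programming).

    Finds the non-decreasing map f from member points to representative
    point indices minimising the total Euclidean distance of matched
    pairs, robust to the members being longer, shorter or unevenly sampled
    relative to the representative. The member is reversed first if its
    endpoint distances favour the opposite orientation. Identical inputs
    yield the identity mapping at zero cost. Ties are broken toward the
    smallest representative index.
    """
    rep = as_streamline(representative)
    mem = as_streamline(member)
    flipped = _should_flip(rep, mem)
    if flipped:
        mem = mem[::-1]
    m, r = len(mem), len(rep)
    d = np.linalg.norm(mem[:, None, :] - rep[None, :, :], axis=2)

    def _prefix_argmin(row: np.ndarray) -> np.ndarray:
        # first index attaining the running minimum (ties -> smallest j)
        best = np.minimum.accumulate(row)
        new = np.empty(r, dtype=bool)
        new[0] = True
        new[1:] = row[1:] < best[:-1]
        mark = np.where(new, np.arange(r), 0)
        return np.maximum.accumulate(mark)

    # C[i, j]: min cost mapping member[0..i] with f(i) = j
    C = np.empty((m, r))
    prefix_arg = np.empty((m, r), dtype=int)  # argmin_{j'<=j} C[i, j']
    C[0] = d[0]
    prefix_arg[0] = _prefix_argmin(C[0])
    best = np.minimum.accumulate(C[0])
    for i in range(1, m):
        C[i] = d[i] + best
        prefix_arg[i] = _prefix_argmin(C[i])
        best = np.minimum.accumulate(C[i])

    indices = np.empty(m, dtype=int)
    indices[-1] = prefix_arg[-1, -1]
    for i in range(m - 1, 0, -1):
        indices[i - 1] = prefix_arg[i - 1, indices[i]]
    return Correspondence(indices=indices, flipped=flipped, cost=float(C[m - 1, indices[-1]]))


# ---------------------------------------------------------------------------
# FA projection


@dataclass
class TractDiffusionProfile:
    """FA per arc-length sample point along a representative streamline."""

    values: np.ndarray
    tract_label: str
    hemisphere: str
    subject_id: str  # "group" for the group-wise profile
    flags: np.ndarray | None = None  # True where no member point mapped

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("profile FA values must lie in [0, 1]")
        self.values = v

    @property
    def n_points(self) -> int:
        return len(self.values)


def _mahalanobis_weights(positions: np.ndarray) -> np.ndarray:
    """Weights 1 / (1 + d_M^2) around the contributors' spatial mean.

    Falls back to uniform weights for fewer than 3 contributors or a
    rank-deficient covariance, where the Mahalanobis distance is undefined.
    """
    k = len(positions)
    if k < 3:
        return np.full(k, 1.0 / k)
    mu = positions.mean(axis=0)
    centered = positions - mu
    cov = centered.T @ centered / (k - 1)
    if np.linalg.matrix_rank(cov) < 3:
        return np.full(k, 1.0 / k)
    d2 = np.einsum("ij,ij->i", centered @ np.linalg.inv(cov), centered)
    w = 1.0 / (1.0 + d2)
    return w / w.sum()


def project_fa(
    member_points: list,
    member_fa: list,
    correspondences: list,
    representative_points: np.ndarray,
    representative_fa: np.ndarray | None = None,
    tract_label: str = "",
    hemisphere: str = "",
    subject_id: str = "",
) -> TractDiffusionProfile:
    """Project member FA values onto the representative streamline.

    At each representative point the profile value is the weighted mean of
    every member FA value mapped there, weights decreasing in each
    contributing point's Mahalanobis distance to the spatial distribution
    of points mapped to that representative point (normalised to sum 1).
    Member point arrays must already be in the orientation recorded by
    their correspondence (see ``match_and_project`` for the handled path).
    Representative points left with no contributors take the
    representative's own FA and are flagged.
    """
    n_rep = len(representative_points)
    positions: list[list] = [[] for _ in range(n_rep)]
    values: list[list] = [[] for _ in range(n_rep)]
    for pts, fa, corr in zip(member_points, member_fa, correspondences):
        for i, j in enumerate(corr.indices):
            positions[j].append(pts[i])
            values[j].append(fa[i])
    out = np.empty(n_rep)
    flags = np.zeros(n_rep, dtype=bool)
    for j in range(n_rep):
        if not values[j]:
            flags[j] = True
            if representative_fa is None:
                raise ValueError(
                    f"representative point {j} has no mapped member points and "
                    "no representative FA to fall back on"
                )
            out[j] = representative_fa[j]
            continue
        w = _mahalanobis_weights(np.asarray(positions[j]))
        out[j] = float(w @ np.asarray(values[j]))
    return TractDiffusionProfile(
        values=np.clip(out, 0.0, 1.0),
        tract_label=tract_label,
        hemisphere=hemisphere,
        subject_id=subject_id,
        flags=flags,
    )


def match_and_project(
    tract: LabeledTract, representative: RepresentativeStreamline, subject_id: str = ""
) -> TractDiffusionProfile:
    """Subject-level Tract Diffusion Profile for one labeled tract.

    Matches every member (including the representative itself, which maps
    identically) to the representative and projects FA.
    """
    if tract.fa is None:
        raise ValueError("tract carries no per-point FA samples")
    rep_pts = representative.points
    member_points, member_fa, corrs = [], [], []
    for pts, fa in zip(tract.streamlines, tract.fa):
        pts = np.asarray(pts, dtype=float)
        fa = np.asarray(fa, dtype=float)
        corr = optimal_point_match(rep_pts, pts)
        if corr.flipped:
            pts, fa = pts[::-1], fa[::-1]
        member_points.append(pts)
        member_fa.append(fa)
        corrs.append(corr)
    rep_fa = np.asarray(tract.fa[representative.index], dtype=float)
    return project_fa(
        member_points,
        member_fa,
        corrs,
        rep_pts,
        representative_fa=rep_fa,
        tract_label=tract.tract_label,
        hemisphere=tract.hemisphere,
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# group-wise representative and resampling


def groupwise_representative(
    subject_representatives: dict,
    support_fraction: float = SUPPORT_FRACTION,
    voxel_size: float = 2.0,
    support_distance: float | None = None,
):
    """Select a group representative across subjects by the density rule.

    ``subject_representatives`` maps subject id to that subject's
    representative streamline for the tract (``None`` where the tract was
    not found). Pooled representatives form a fiber density map; the one
    with maximal density sum is the candidate. The tract is retained only
    if strictly more than ``support_fraction`` of all subjects support it —
    a subject supports the tract when it was found for them and (when
    ``support_distance`` is given) their representative lies within that
    distance of the candidate.

    Returns ``(subject_id, points, supporting_ids)`` or ``None`` when the
    support constraint fails (reason logged).
    """
    n_subjects = len(subject_representatives)
    if n_subjects < 2:
        raise ValueError("group-wise selection needs at least 2 subjects")
    present = {
        sid: np.asarray(pts, dtype=float)
        for sid, pts in subject_representatives.items()
        if pts is not None
    }
    if not present:
        logger.warning("tract absent in every subject; excluded")
        return None
    order = sorted(present)
    pooled = [present[sid] for sid in order]
    shape, affine = make_grid(pooled, voxel_size=voxel_size)
    density = fiber_density_map(pooled, shape, affine)
    sums = np.array([density_sum(p, density) for p in pooled])
    winner = int(np.argmax(sums))
    rep_sid, rep_pts = order[winner], pooled[winner]

    if support_distance is None:
        supporting = list(order)
    else:
        supporting = [
            sid for sid in order if streamline_distance(present[sid], rep_pts) <= support_distance
        ]
    if len(supporting) <= support_fraction * n_subjects:
        logger.warning(
            "tract excluded: supported by %d of %d subjects "
            "(requires strictly more than %.0f%%)",
            len(supporting),
            n_subjects,
            100 * support_fraction,
        )
        return None
    return rep_sid, rep_pts, supporting


def resample_profile(
    profile: TractDiffusionProfile, n_points: int = GROUP_PROFILE_POINTS
) -> TractDiffusionProfile:
    """Spline-resample a profile to ``n_points`` equidistant arc fractions.

    Natural cubic spline over arc-length fraction (so a linear ramp is
    reproduced exactly); inputs with fewer than 4 points fall back to
    linear interpolation, logged. Values are clipped to [0, 1] against
    spline overshoot.
    """
    v = np.asarray(profile.values, dtype=float)
    x = np.linspace(0.0, 1.0, len(v))
    target = np.linspace(0.0, 1.0, n_points)
    if len(v) >= 4:
        out = CubicSpline(x, v, bc_type="natural")(target)
    else:
        logger.info("profile has %d < 4 points: linear interpolation fallback", len(v))
        out = np.interp(target, x, v)
    return TractDiffusionProfile(
        values=np.clip(out, 0.0, 1.0),
        tract_label=profile.tract_label,
        hemisphere=profile.hemisphere,
        subject_id=profile.subject_id,
    )


def resample_points(points: np.ndarray, n_points: int) -> np.ndarray:
    """Cubic-spline resampling of a streamline to equidistant fractions."""
    from .geometry import arc_fractions

    pts = np.asarray(points, dtype=float)
    frac = arc_fractions(pts)
    target = np.linspace(0.0, 1.0, n_points)
    if len(pts) >= 4:
        return CubicSpline(frac, pts, axis=0, bc_type="natural")(target)
    out = np.empty((n_points, 3))
    for k in range(3):
        out[:, k] = np.interp(target, frac, pts[:, k])
    return out


def subject_profiles_on_group(
    group_points: np.ndarray,
    subject_profiles: dict,
) -> tuple[np.ndarray, list]:
    """Sample each subject's profile onto the group representative's points.

    ``subject_profiles`` maps subject id to ``(rep_points, profile_values)``
    on that subject's own representative. Each subject representative is
    matched to the group representative with the optimal-point-matching
    operator; values landing on the same group point are averaged and gaps
    filled by linear interpolation over the point index.

    Returns the (n_subjects, n_group_points) matrix and the subject order.
    """
    order = sorted(subject_profiles)
    P = len(group_points)
    Y = np.empty((len(order), P))
    for row, sid in enumerate(order):
        pts, vals = subject_profiles[sid]
        pts = np.asarray(pts, dtype=float)
        vals = np.asarray(vals, dtype=float)
        corr = optimal_point_match(group_points, pts)
        if corr.flipped:
            pts, vals = pts[::-1], vals[::-1]
        acc = np.zeros(P)
        cnt = np.zeros(P)
        for i, j in enumerate(corr.indices):
            acc[j] += vals[i]
            cnt[j] += 1
        filled = cnt > 0
        y = np.empty(P)
        y[filled] = acc[filled] / cnt[filled]
        if not filled.all():
            idx = np.arange(P)
            y[~filled] = np.interp(idx[~filled], idx[filled], y[filled])
        Y[row] = y
    return Y, order
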