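"""Streamline shape similarity, clustering, and multi-atlas bundle labeling.

Whole-brain streamlines are grouped by shape similarity, each group is
scored against the labeled bundles of several example-subject atlases, and
the group's final tract label is the majority vote across atlases. Outlier
streamlines far from a bundle's summary streamline are then removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import as_streamline, resample_streamline
from .synthetic import HEMISPHERES, TRACT_LABELS

#: the fixed 14-label set: 7 tract types x 2 hemispheres
LABEL_SET = tuple((t, h) for t in TRACT_LABELS for h in HEMISPHERES)

UNLABELED = "unlabeled"

_N_RESAMPLE = 20  # fixed point count used by the shape distance


def _resample_for_distance(points: np.ndarray) -> np.ndarray:
    return resample_streamline(as_streamline(points), _N_RESAMPLE)


def streamline_distance(a, b) -> float:
    """Symmetric mean-of-closest-point distance between two streamlines, mm.

    Both streamlines are resampled to a fixed point count; the distance is
    the average over both directions of each point's distance to its
    closest point on the other streamline. Zero iff the resampled point
    sets coincide, and invariant to streamline orientation (reversing a
    streamline leaves its point set, hence closest-point distances,
    unchanged), so no explicit flip minimisation is needed.
    """
    pa = _resample_for_distance(a)
    pb = _resample_for_distance(b)
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    return float(0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean()))


def _pairwise_mcp(res_a: np.ndarray, res_b: np.ndarray) -> np.ndarray:
    """Vectorised symmetric MCP between two stacks of resampled streamlines.

    ``res_a`` (na, K, 3), ``res_b`` (nb, K, 3) -> (na, nb) distance matrix.
    """
    diff = res_a[:, None, :, None, :] - res_b[None, :, None, :, :]
    d = np.linalg.norm(diff, axis=-1)  # (na, nb, K, K)
    return 0.5 * (d.min(axis=3).mean(axis=2) + d.min(axis=2).mean(axis=2))


@dataclass
class StreamlineCluster:
    """A shape-similarity group of streamlines.

    ``members`` indexes into the input streamline list; ``summary`` is the
    medoid member's index (minimal summed distance to the rest).
    """

    members: list[int]
    summary: int


def cluster_streamlines(
    streamlines: list, distance_threshold: float
) -> list[StreamlineCluster]:
    """Greedy shape-similarity clustering of whole-brain streamlines.

    Streamlines are visited in input order; each is assigned to the nearest
    existing cluster whose summary streamline lies within
    ``distance_threshold`` (mm), else it founds a new cluster. Summaries
    are updated to the cluster medoid after each assignment, making the
    result a deterministic partition of the input.
    """
    if len(streamlines) == 0:
        raise ValueError("no streamlines to cluster")
    res = np.stack([_resample_for_distance(s) for s in streamlines])
    n = len(streamlines)
    clusters: list[list[int]] = []
    summaries: list[int] = []
    # cache of pairwise distances, filled lazily
    dmat = np.full((n, n), np.nan)

    def dist(i: int, j: int) -> float:
        if np.isnan(dmat[i, j]):
            d = _pairwise_mcp(res[i : i + 1], res[j : j + 1])[0, 0]
            dmat[i, j] = dmat[j, i] = d
        return dmat[i, j]

    for i in range(n):
        best, best_d = -1, np.inf
        for ci, s in enumerate(summaries):
            d = dist(i, s)
            if d < best_d:
                best, best_d = ci, d
        if best >= 0 and best_d <= distance_threshold:
            clusters[best].append(i)
            members = clusters[best]
            # medoid update
            sums = [sum(dist(m, o) for o in members) for m in members]
            summaries[best] = members[int(np.argmin(sums))]
        else:
            clusters.append([i])
            summaries.append(i)
    return [
        StreamlineCluster(members=m, summary=s) for m, s in zip(clusters, summaries)
    ]


@dataclass
class BundleAtlas:
    """Labeled exemplar bundles of one example subject in reference space.

    ``bundles`` maps each of the 14 (tract, hemisphere) labels to a list of
    exemplar streamlines; ``transform`` carries this atlas's own affine to
    the common reference space (identity in synthetic space).
    """

    atlas_id: str
    bundles: dict
    transform: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        for key, lines in self.bundles.items():
            if tuple(key) not in LABEL_SET:
                raise ValueError(f"unknown bundle label {key}")
            if len(lines) == 0:
                raise ValueError(f"atlas bundle {key} has no exemplars")


def _apply_affine(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    return points @ affine[:3, :3].T + affine[:3, 3]


def label_by_atlas_vote(
    clusters: list[StreamlineCluster],
    streamlines: list,
    atlases: list[BundleAtlas],
    subject_to_reference: np.ndarray | None = None,
    similarity_cutoff: float = 15.0,
):
    """Assign a tract label to each cluster by multi-atlas majority voting.

    Each cluster's summary streamline is transformed to the reference
    space and scored against every bundle of every atlas; the score is the
    minimum shape distance to the bundle's exemplars. Per atlas the
    best-scoring label is that atlas's vote, withheld if the best score
    exceeds ``similarity_cutoff`` (mm). The cluster label is the majority
    vote; a cluster no atlas votes for is ``"unlabeled"``. Ties are broken
    by smallest mean similarity distance across voting atlases, then by
    lexicographic label order, so the result is independent of atlas order.
    """
    if len(atlases) == 0:
        raise ValueError("at least one atlas is required")
    if subject_to_reference is None:
        subject_to_reference = np.eye(4)
    if len(clusters) == 0:
        return []

    atlas_res = []  # per atlas: {label: (n_exemplars, K, 3)}
    for atlas in atlases:
        to_ref = atlas.transform
        atlas_res.append(
            {
                tuple(key): np.stack(
                    [_resample_for_distance(_apply_affine(np.asarray(s), to_ref)) for s in lines]
                )
                for key, lines in atlas.bundles.items()
            }
        )

    labels = []
    for cluster in clusters:
        summary = _apply_affine(
            np.asarray(streamlines[cluster.summary], dtype=float), subject_to_reference
        )
        res_sum = _resample_for_distance(summary)[None]
        votes: dict[tuple, list[float]] = {}
        for bundles in atlas_res:
            best_label, best_d = None, np.inf
            for key, exemplars in bundles.items():
                d = float(_pairwise_mcp(res_sum, exemplars).min())
                if d < best_d:
                    best_label, best_d = key, d
            if best_d <= similarity_cutoff:
                votes.setdefault(best_label, []).append(best_d)
        if not votes:
            labels.append(UNLABELED)
            continue
        ranked = sorted(
            votes.items(),
            key=lambda kv: (-len(kv[1]), float(np.mean(kv[1])), kv[0]),
        )
        labels.append(ranked[0][0])
    return labels


@dataclass
class LabeledTract:
    """One labeled bundle of one subject after outlier removal."""

    tract_label: str
    hemisphere: str
    streamlines: list
    fa: list | None = None  # per-point FA arrays aligned with streamlines

    def __post_init__(self):
        if len(self.streamlines) == 0:
            raise ValueError("a labeled tract must contain streamlines")

    @property
    def key(self) -> tuple[str, str]:
        return (self.tract_label, self.hemisphere)


def remove_outliers(tract: LabeledTract, bound: float) -> LabeledTract:
    """Drop streamlines farther than ``bound`` mm from the tract summary.

    The summary is the medoid member (which trivially lies within any
    bound of itself). Raises when the bound strips every other member of a
    multi-streamline tract — the bound is then smaller than the bundle's
    own spread and no meaningful bundle remains.
    """
    res = np.stack([_resample_for_distance(s) for s in tract.streamlines])
    dmat = _pairwise_mcp(res, res)
    medoid = int(np.argmin(dmat.sum(axis=1)))
    keep = np.flatnonzero(dmat[medoid] <= bound)
    if keep.size <= 1 and len(tract.streamlines) > 1:
        raise ValueError(
            f"outlier bound {bound} mm removed every streamline of "
            f"{tract.key}; increase the bound"
        )
    return LabeledTract(
        tract_label=tract.tract_label,
        hemisphere=tract.hemisphere,
        streamlines=[tract.streamlines[i] for i in keep],
        fa=None if tract.fa is None else [tract.fa[i] for i in keep],
    )


def generate_atlases(
    n_atlases: int = 3,
    bundle_specs=None,
    seed: int = 1000,
    n_points_per_streamline: int = 50,
) -> list[BundleAtlas]:
    """Synthetic example-subject atlases for the voting ensemble.

    Each atlas is one generated single-subject phantom whose ground-truth
    bundle labels become the exemplar bundles; distinct seeds give each
    atlas its own shape variability, mimicking expert-labeled example data
    from different subjects. Transforms are identity (synthetic space is
    the reference space).
    """
    from .synthetic import generate_cohort

    atlases = []
    for k in range(n_atlases):
        cohort = generate_cohort(
            1,
            1,
            bundle_specs=bundle_specs,
            seed=seed + k,
            n_points_per_streamline=n_points_per_streamline,
            noise_sd=0.0,
        )
        sid = cohort.subjects[0].subject_id
        atlases.append(
            BundleAtlas(
                atlas_id=f"atlas-{k + 1}",
                bundles={key: lines for key, lines in cohort.streamlines[sid].items()},
            )
        )
    return atlases


def label_cohort_subject(
    streamlines: list,
    fa: list,
    atlases: list[BundleAtlas],
    distance_threshold: float = 5.0,
    similarity_cutoff: float = 15.0,
    outlier_bound: float = 8.0,
    subject_to_reference: np.ndarray | None = None,
) -> dict:
    """Cluster, vote-label and outlier-filter one subject's streamlines.

    Returns ``{(tract, hemisphere): LabeledTract}``; unlabeled clusters are
    dropped. Convenience wrapper chaining the three labeling stages.
    """
    clusters = cluster_streamlines(streamlines, distance_threshold)
    labels = label_by_atlas_vote(
        clusters, streamlines, atlases, subject_to_reference, similarity_cutoff
    )
    grouped: dict[tuple, list[int]] = {}
    for cluster, label in zip(clusters, labels):
        if label == UNLABELED:
            continue
        grouped.setdefault(tuple(label), []).extend(cluster.members)
    out = {}
    for key, idx in grouped.items():
        tract = LabeledTract(
            tract_label=key[0],
            hemisphere=key[1],
            streamlines=[streamlines[i] for i in idx],
            fa=[fa[i] for i in idx] if fa is not None else None,
        )
        out[key] = remove_outliers(tract, outlier_bound)
    return out
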