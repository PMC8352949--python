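"""Simulation studies calibrating the pipeline's statistical behaviour.

These are the package's own validity checks, run on cohorts drawn from the
synthetic generator: family-wise type-I error of the cluster-based
permutation test on null cohorts, detection power for a planted segmental
FA deficit, streamline-labeling accuracy on clean phantoms, and noiseless
end-to-end recovery of the generator's baseline FA profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bundles, profiles, synthetic
from .stats import DesignMatrix, permutation_cbs


def _derived_seed(seed: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt) % (2**31 - 1))


@dataclass
class ErrorRateResult:
    rate: float
    n_replicates: int
    ci_low: float
    ci_high: float


def _wilson_interval(k: int, n: int, z: float = 1.959964) -> tuple[float, float]:
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


def type_i_error_study(
    n_replicates: int = 200,
    n_permutations: int = 500,
    n_cases: int = 30,
    n_controls: int = 31,
    noise_sd: float = 0.03,
    alpha: float = 0.05,
    seed: int = 0,
) -> ErrorRateResult:
    """Family-wise false-positive rate of permutation CBS on null cohorts.

    Each replicate draws a null cohort profile matrix (no group effect, no
    couplings) from the generator's FA model and runs the full
    covariate-adjusted cluster-based permutation test; a replicate counts
    as a false positive if any cluster reaches corrected p < alpha. For a
    valid test the rate should sit near alpha.
    """
    hits = 0
    for rep in range(n_replicates):
        rs = _derived_seed(seed, rep)
        Y, table = synthetic.simulate_profiles(
            n_cases, n_controls, noise_sd=noise_sd, fa_delta=0.0, seed=rs
        )
        design = DesignMatrix.from_table(table, covariates=("age", "bmi"))
        result = permutation_cbs(
            Y, design=design, test="ancova_f",
            n_permutations=n_permutations, seed=rs + 1,
        )
        if result.significant(alpha):
            hits += 1
    lo, hi = _wilson_interval(hits, n_replicates)
    return ErrorRateResult(hits / n_replicates, n_replicates, lo, hi)


def power_study(
    n_replicates: int = 50,
    n_permutations: int = 500,
    n_cases: int = 30,
    n_controls: int = 31,
    fa_delta: float = -0.05,
    segment: tuple[float, float] = (0.4, 0.6),
    noise_sd: float = 0.03,
    alpha: float = 0.05,
    seed: int = 0,
) -> ErrorRateResult:
    """Detection rate for a planted contiguous segmental FA deficit.

    The default deficit (-0.05 FA over the 20 sample points in the
    [0.4, 0.6] arc-length segment, per-point noise SD 0.03, 30 vs 31
    subjects) is the generator's reference alternative; a replicate counts
    as detected when any cluster reaches corrected p < alpha.
    """
    hits = 0
    for rep in range(n_replicates):
        rs = _derived_seed(seed, 7_000 + rep)
        Y, table = synthetic.simulate_profiles(
            n_cases, n_controls, fa_delta=fa_delta, segment=segment,
            noise_sd=noise_sd, seed=rs,
        )
        design = DesignMatrix.from_table(table, covariates=("age", "bmi"))
        result = permutation_cbs(
            Y, design=design, test="ancova_f",
            n_permutations=n_permutations, seed=rs + 1,
        )
        if result.significant(alpha):
            hits += 1
    lo, hi = _wilson_interval(hits, n_replicates)
    return ErrorRateResult(hits / n_replicates, n_replicates, lo, hi)


def labeling_accuracy_study(
    seed: int = 0,
    n_streamlines: int = 20,
    n_atlases: int = 3,
    distance_threshold: float = 5.0,
    similarity_cutoff: float = 15.0,
) -> float:
    """Fraction of a clean phantom's streamlines receiving their true label.

    One generated test subject (default jitter only, no FA noise needed)
    is clustered and vote-labeled against a fresh multi-atlas ensemble;
    accuracy is measured per streamline against the generator's
    ground-truth bundle assignment.
    """
    specs = synthetic.default_bundle_specs(n_streamlines=n_streamlines)
    cohort = synthetic.generate_cohort(
        1, 1, bundle_specs=specs, seed=_derived_seed(seed, 11), noise_sd=0.0
    )
    sid = cohort.subjects[0].subject_id
    atlases = bundles.generate_atlases(
        n_atlases=n_atlases, bundle_specs=specs, seed=_derived_seed(seed, 13)
    )
    lines, truth = [], []
    for key in sorted(cohort.streamlines[sid]):
        for s in cohort.streamlines[sid][key]:
            lines.append(s)
            truth.append(key)
    clusters = bundles.cluster_streamlines(lines, distance_threshold)
    labels = bundles.label_by_atlas_vote(
        clusters, lines, atlases, similarity_cutoff=similarity_cutoff
    )
    correct = 0
    for cluster, label in zip(clusters, labels):
        for idx in cluster.members:
            if label != bundles.UNLABELED and tuple(label) == truth[idx]:
                correct += 1
    return correct / len(lines)


def profile_recovery_study(
    seed: int = 0,
    n_subjects_per_group: int = 3,
    n_streamlines: int = 15,
    tract_keys=(("CST", "left"), ("ATR", "right"), ("CG", "left"), ("IFO", "right")),
) -> dict:
    """Noiseless end-to-end recovery of the baseline FA profile.

    Generates a noiseless cohort, runs density-based representative
    selection, optimal point matching, Mahalanobis-weighted projection,
    group-wise selection and 100-point resampling using the generator's
    ground-truth labels, and reports the RMSE between each recovered
    group-mean profile and the bundle's baseline FA profile.
    """
    specs = synthetic.default_bundle_specs(n_streamlines=n_streamlines)
    spec_by_key = {s.key: s for s in specs}
    cohort = synthetic.generate_cohort(
        n_subjects_per_group,
        n_subjects_per_group,
        bundle_specs=[spec_by_key[k] for k in tract_keys],
        seed=_derived_seed(seed, 17),
        noise_sd=0.0,
    )
    rmse = {}
    for key in tract_keys:
        subject_reps, subject_profiles = {}, {}
        for subj in cohort.subjects:
            sid = subj.subject_id
            tract = bundles.LabeledTract(
                tract_label=key[0],
                hemisphere=key[1],
                streamlines=cohort.streamlines[sid][key],
                fa=cohort.fa[sid][key],
            )
            shape, affine = profiles.make_grid(tract.streamlines)
            density = profiles.fiber_density_map(tract.streamlines, shape, affine)
            rep = profiles.select_representative(tract, density)
            tdp = profiles.match_and_project(tract, rep, subject_id=sid)
            subject_reps[sid] = rep.points
            subject_profiles[sid] = (rep.points, tdp.values)
        selection = profiles.groupwise_representative(subject_reps)
        assert selection is not None
        group_points = profiles.resample_points(selection[1], 100)
        Y, _ = profiles.subject_profiles_on_group(group_points, subject_profiles)
        target = np.asarray(
            spec_by_key[key].baseline_fa_profile(np.linspace(0, 1, 100))
        )
        recovered = Y.mean(axis=0)
        if np.corrcoef(recovered, target)[0, 1] < 0:  # orientation is arbitrary
            recovered = recovered[::-1]
        rmse[key] = float(np.sqrt(np.mean((recovered - target) ** 2)))
    return rmse
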