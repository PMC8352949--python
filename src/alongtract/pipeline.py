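"""End-to-end pipeline driver: simulate, label, profile, stats.

Given a :class:`~alongtract.io.PipelineConfig`, runs every stage on a
synthetic cohort and writes profiles, cluster tables, per-tract plots and
a log to the configured output directory. Identical config and seed yield
byte-identical tabular outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bundles, profiles, stats, synthetic
from .io import PipelineConfig, save_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """In-memory results of one pipeline run."""

    cohort: synthetic.Cohort
    labeled: dict  # subject_id -> {(tract, hemi): LabeledTract}
    profile_matrices: dict  # (tract, hemi) -> (Y, subject_order)
    group_representatives: dict  # (tract, hemi) -> (sid, points)
    cluster_table: pd.DataFrame
    excluded: list = field(default_factory=list)


def _simulate_stage(config: PipelineConfig):
    sim = config.simulate
    specs = synthetic.default_bundle_specs(n_streamlines=sim["n_streamlines"])
    effects = [synthetic.EffectSpec(**_coerce_effect(e)) for e in sim["effects"]]
    cohort = synthetic.generate_cohort(
        sim["n_cases"],
        sim["n_controls"],
        bundle_specs=specs,
        effects=effects,
        seed=config.seed,
        n_points_per_streamline=sim["n_points_per_streamline"],
        noise_sd=sim["noise_sd"],
    )
    logger.info(
        "simulate: %d cases + %d controls, %d bundles, %d streamlines each",
        sim["n_cases"], sim["n_controls"], len(specs), sim["n_streamlines"],
    )
    return cohort, specs


def _coerce_effect(e: dict) -> dict:
    e = dict(e)
    e["target_tract"] = tuple(e["target_tract"])
    if "segment" in e:
        e["segment"] = tuple(e["segment"])
    return e


def _label_stage(config: PipelineConfig, cohort, specs):
    lab = config.labeling
    atlases = bundles.generate_atlases(
        n_atlases=lab["n_atlases"],
        bundle_specs=specs,
        seed=config.seed + 10_000,
        n_points_per_streamline=config.simulate["n_points_per_streamline"],
    )
    labeled = {}
    for subj in cohort.subjects:
        sid = subj.subject_id
        pooled_lines, pooled_fa = [], []
        for key in sorted(cohort.streamlines[sid]):
            pooled_lines.extend(cohort.streamlines[sid][key])
            pooled_fa.extend(cohort.fa[sid][key])
        labeled[sid] = bundles.label_cohort_subject(
            pooled_lines,
            pooled_fa,
            atlases,
            distance_threshold=lab["distance_threshold"],
            similarity_cutoff=lab["similarity_cutoff"],
            outlier_bound=lab["outlier_bound"],
        )
        logger.info("label: %s -> %d bundles", sid, len(labeled[sid]))
    return labeled


def _profile_stage(config: PipelineConfig, cohort, labeled):
    prof = config.profiling
    n_points = prof["n_points"]
    all_ids = [s.subject_id for s in cohort.subjects]
    matrices, group_reps, excluded = {}, {}, []
    for key in bundles.LABEL_SET:
        subject_reps: dict = {}
        subject_profiles: dict = {}
        for sid in all_ids:
            tract = labeled[sid].get(key)
            if tract is None:
                subject_reps[sid] = None
                continue
            shape, affine = profiles.make_grid(
                tract.streamlines, voxel_size=prof["voxel_size"]
            )
            density = profiles.fiber_density_map(tract.streamlines, shape, affine)
            rep = profiles.select_representative(tract, density)
            tdp = profiles.match_and_project(tract, rep, subject_id=sid)
            subject_reps[sid] = rep.points
            subject_profiles[sid] = (rep.points, tdp.values)
        selection = profiles.groupwise_representative(
            subject_reps, support_fraction=prof["support_fraction"],
            voxel_size=prof["voxel_size"],
        )
        if selection is None:
            excluded.append(key)
            logger.info("profile: %s excluded (insufficient support)", key)
            continue
        _, rep_pts, _ = selection
        group_points = profiles.resample_points(rep_pts, n_points)
        Y, order = profiles.subject_profiles_on_group(group_points, subject_profiles)
        matrices[key] = (np.clip(Y, 0.0, 1.0), order)
        group_reps[key] = selection[:2]
        logger.info("profile: %s -> %d subjects x %d points", key, *Y.shape)
    return matrices, group_reps, excluded


def _stats_stage(config: PipelineConfig, cohort, matrices):
    st = config.stats
    table = cohort.table.set_index("subject_id")
    rows = []
    for key, (Y, order) in sorted(matrices.items()):
        sub = table.loc[order].reset_index()
        design = stats.DesignMatrix.from_table(sub, covariates=st["covariates"])
        result = stats.permutation_cbs(
            Y,
            design=design,
            test="ancova_f",
            threshold=st["threshold"],
            n_permutations=st["n_permutations"],
            seed=config.seed + 20_000,
            scheme=st["scheme"],
        )
        for (start, end, size), p in zip(result.clusters, result.corrected_p):
            rows.append(
                {
                    "tract": key[0],
                    "hemisphere": key[1],
                    "test": "group_ancova",
                    "measure": "",
                    "start": start,
                    "end": end,
                    "size": size,
                    "corrected_p": float(p),
                    "significant": bool(p < st["alpha"]),
                }
            )
        for measure in st["measures"]:
            case_mask = sub["group"] == "case"
            case_sub = sub[case_mask]
            covs = stats.encode_covariates(case_sub, st["corr_covariates"])
            result_r = stats.permutation_cbs(
                Y[case_mask.to_numpy()],
                measure=case_sub[measure].to_numpy(dtype=float),
                covariates=covs,
                test="partial_r",
                n_permutations=st["n_permutations"],
                seed=config.seed + 30_000,
                scheme=st["scheme"],
            )
            for (start, end, size), p in zip(result_r.clusters, result_r.corrected_p):
                rows.append(
                    {
                        "tract": key[0],
                        "hemisphere": key[1],
                        "test": "partial_r",
                        "measure": measure,
                        "start": start,
                        "end": end,
                        "size": size,
                        "corrected_p": float(p),
                        "significant": bool(p < st["alpha"]),
                    }
                )
    columns = [
        "tract", "hemisphere", "test", "measure",
        "start", "end", "size", "corrected_p", "significant",
    ]
    return pd.DataFrame(rows, columns=columns)


def _write_outputs(config: PipelineConfig, cohort, matrices, cluster_table):
    out = Path(config.output_dir)
    (out / "profiles").mkdir(parents=True, exist_ok=True)
    save_table(out / "subjects.tsv", cohort.table)
    for key, (Y, order) in sorted(matrices.items()):
        df = pd.DataFrame(
            Y, index=pd.Index(order, name="subject_id"),
            columns=[f"p{j:03d}" for j in range(Y.shape[1])],
        )
        df.reset_index().to_csv(
            out / "profiles" / f"{key[0]}_{key[1]}.tsv", sep="\t", index=False
        )
    save_table(out / "clusters.tsv", cluster_table)
    config.to_yaml(out / "config_used.yaml")
    if config.plots:
        _write_plots(out, cohort, matrices, cluster_table, config.stats["alpha"])


def _write_plots(out: Path, cohort, matrices, cluster_table, alpha: float):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    (out / "plots").mkdir(exist_ok=True)
    groups = cohort.table.set_index("subject_id")["group"]
    for key, (Y, order) in sorted(matrices.items()):
        is_case = (groups.loc[order] == "case").to_numpy()
        fig, ax = plt.subplots(figsize=(6, 3.2))
        x = np.arange(Y.shape[1])
        for mask, label, color in ((is_case, "case", "C3"), (~is_case, "control", "C0")):
            if mask.any():
                mean = Y[mask].mean(axis=0)
                sd = Y[mask].std(axis=0)
                ax.plot(x, mean, color=color, label=label)
                ax.fill_between(x, mean - sd, mean + sd, color=color, alpha=0.2)
        sig = cluster_table[
            (cluster_table["tract"] == key[0])
            & (cluster_table["hemisphere"] == key[1])
            & (cluster_table["test"] == "group_ancova")
            & (cluster_table["corrected_p"] < alpha)
        ]
        for _, row in sig.iterrows():
            ax.axvspan(row["start"], row["end"], color="gold", alpha=0.3)
        ax.set_xlabel("sample point along tract")
        ax.set_ylabel("FA")
        ax.set_title(f"{key[0]} ({key[1]})")
        ax.legend(loc="best", fontsize=8)
        fig.tight_layout()
        fig.savefig(out / "plots" / f"{key[0]}_{key[1]}.png", dpi=100)
        plt.close(fig)


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Run simulate -> label -> profile -> stats and write all outputs.

    Any stage failure aborts with the stage name prepended to the cause.
    """
    if config is None:
        config = PipelineConfig()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("alongtract")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        stage = "simulate"
        cohort, specs = _simulate_stage(config)
        stage = "label"
        labeled = _label_stage(config, cohort, specs)
        stage = "profile"
        matrices, group_reps, excluded = _profile_stage(config, cohort, labeled)
        stage = "stats"
        cluster_table = _stats_stage(config, cohort, matrices)
        stage = "write"
        _write_outputs(config, cohort, matrices, cluster_table)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return PipelineResult(
        cohort=cohort,
        labeled=labeled,
        profile_matrices=matrices,
        group_representatives=group_reps,
        cluster_table=cluster_table,
        excluded=excluded,
    )
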