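"""Standard-format I/O and pipeline configuration.

Streamlines are stored as TrackVis ``.trk`` (with per-point FA as a
scalar channel), scalar volumes as NIfTI-1, tables as TSV, and the full
pipeline configuration (including every seed) as YAML, so a run is fully
reconstructable from its output directory.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml


# ---------------------------------------------------------------------------
# TrackVis .trk


def save_trk(
    path,
    streamlines,
    fa=None,
    affine: np.ndarray | None = None,
    dimensions=(100, 120, 100),
    voxel_sizes=(1.0, 1.0, 1.0),
) -> None:
    """Write streamlines (world mm, RAS) to a TrackVis file.

    ``fa``, if given, is a per-streamline list of per-point values stored
    as the ``fa`` scalar channel. The header's voxel grid fields are
    populated from ``affine``/``dimensions`` so standard viewers accept
    the file.
    """
    if affine is None:
        affine = np.diag([*voxel_sizes, 1.0])
    data_per_point = None
    if fa is not None:
        data_per_point = {
            "fa": [np.asarray(v, dtype=np.float32)[:, None] for v in fa]
        }
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in streamlines],
        data_per_point=data_per_point,
        affine_to_rasmm=np.eye(4),
    )
    header = {
        "dimensions": np.asarray(dimensions, dtype=np.int16),
        "voxel_sizes": np.asarray(voxel_sizes, dtype=np.float32),
        "voxel_to_rasmm": np.asarray(affine, dtype=np.float32),
        "voxel_order": "RAS",
    }
    nib.streamlines.save(nib.streamlines.trk.TrkFile(tractogram, header), str(path))


def load_trk(path):
    """Read a TrackVis file; returns (streamlines, fa-or-None).

    Coordinates come back in world mm (RAS); the ``fa`` scalar channel is
    returned when present. Malformed headers raise nibabel's header error.
    """
    trk = nib.streamlines.load(str(path))
    streamlines = [np.asarray(s, dtype=float) for s in trk.streamlines]
    fa = None
    if "fa" in trk.tractogram.data_per_point:
        fa = [
            np.asarray(v, dtype=float).ravel()
            for v in trk.tractogram.data_per_point["fa"]
        ]
    return streamlines, fa


# ---------------------------------------------------------------------------
# NIfTI and tables


def save_nifti(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# pipeline configuration


def _default_simulate() -> dict:
    return {
        "n_cases": 4,
        "n_controls": 4,
        "n_streamlines": 10,
        "n_points_per_streamline": 50,
        "noise_sd": 0.03,
        "effects": [],
    }


def _default_scheme() -> dict:
    return {"n_directions": 45, "b_value": 600.0, "n_b0": 1}


def _default_tracking() -> dict:
    return {
        "fa_stop_threshold": 0.2,
        "max_turn_angle": 35.0,
        "step_size": 1.0,
        "min_length": 10.0,
        "seed_density": 1,
    }


def _default_labeling() -> dict:
    return {
        "n_atlases": 3,
        "distance_threshold": 5.0,
        "similarity_cutoff": 15.0,
        "outlier_bound": 8.0,
    }


def _default_profiling() -> dict:
    return {"n_points": 100, "support_fraction": 0.60, "voxel_size": 2.0}


def _default_stats() -> dict:
    return {
        "threshold": 2.5,
        "n_permutations": 10000,
        "covariates": ["age", "bmi"],
        "corr_covariates": ["age", "sex"],
        "measures": [],
        "scheme": "freedman_lane",
        "alpha": 0.05,
    }


@dataclass
class PipelineConfig:
    """Every stage parameter of the pipeline, YAML-round-trippable.

    Defaults encode the analysis conventions: 100 profile sample points,
    strictly-more-than-60% group-representative support, cluster-forming F
    threshold 2.5 with 10,000 permutations, and a 45-direction b=600
    s/mm**2 synthetic acquisition.
    """

    seed: int = 0
    output_dir: str = "alongtract_out"
    plots: bool = True
    simulate: dict = field(default_factory=_default_simulate)
    scheme: dict = field(default_factory=_default_scheme)
    tracking: dict = field(default_factory=_default_tracking)
    labeling: dict = field(default_factory=_default_labeling)
    profiling: dict = field(default_factory=_default_profiling)
    stats: dict = field(default_factory=_default_stats)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        text = str(source)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        data = yaml.safe_load(text)
        base = cls()
        for key in ("simulate", "scheme", "tracking", "labeling", "profiling", "stats"):
            merged = dict(getattr(base, key))
            merged.update(data.get(key, {}))
            data[key] = merged
        return cls(**data)
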