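"""Deterministic FACT-style tractography.

Fiber Assignment by Continuous Tracking: from each seed, a streamline is
propagated bidirectionally, at every step following the principal diffusion
direction of the voxel currently occupied, until the local FA drops below a
threshold, the trajectory bends more than a maximum turning angle per step,
or the volume is exited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import arc_length


@dataclass(frozen=True)
class TrackingConfig:
    """Stopping rules and stepping parameters for FACT tracking.

    All distances in mm, angles in degrees. Defaults are conventional
    deterministic-tractography values: stop below FA 0.2, reject turns
    above 35 degrees, step half a voxel, discard streamlines under 10 mm.
    """

    fa_stop_threshold: float = 0.2
    max_turn_angle: float = 35.0
    step_size: float = 1.0
    min_length: float = 10.0
    seed_density: int = 1
    max_steps: int = 2000

    def __post_init__(self):
        if min(self.fa_stop_threshold, self.max_turn_angle, self.step_size,
               self.min_length, self.seed_density) <= 0:
            raise ValueError("all TrackingConfig parameters must be positive")
        if self.max_turn_angle >= 90:
            raise ValueError("max_turn_angle must be < 90 degrees")


def _seed_points(seed_mask: np.ndarray, density: int) -> np.ndarray:
    """Voxel-index seed coordinates, ``density`` per masked voxel.

    Seeds are laid on a deterministic sub-grid inside each voxel; order is
    sorted by voxel index so tracking is independent of mask layout.
    """
    idx = np.argwhere(seed_mask)
    idx = idx[np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))]
    if density == 1:
        offsets = np.zeros((1, 3))
    else:
        # evenly spaced fractional offsets along the leading axis
        f = (np.arange(density) + 0.5) / density - 0.5
        offsets = np.column_stack([f, np.zeros(density), np.zeros(density)])
    return (idx[:, None, :] + offsets[None, :, :]).reshape(-1, 3)


def _track_one_direction(
    pos_vox: np.ndarray,
    direction: np.ndarray,
    peaks: np.ndarray,
    fa: np.ndarray,
    step_vox: float,
    cos_max: float,
    fa_stop: float,
    max_steps: int,
) -> list[np.ndarray]:
    """Propagate from ``pos_vox`` (voxel coords) along ``direction``."""
    shape = np.array(fa.shape)
    points = []
    pos = pos_vox.astype(float)
    prev = direction / np.linalg.norm(direction)
    for _ in range(max_steps):
        vox = np.round(pos).astype(int)
        if np.any(vox < 0) or np.any(vox >= shape):
            break
        if fa[tuple(vox)] < fa_stop:
            break
        d = peaks[tuple(vox)]
        norm = np.linalg.norm(d)
        if norm == 0:
            break
        d = d / norm
        if np.dot(d, prev) < 0:  # principal directions are sign-ambiguous
            d = -d
        if np.dot(d, prev) < cos_max:
            break
        pos = pos + step_vox * d
        points.append(pos.copy())
        prev = d
    return points


def fact_track(
    peaks: np.ndarray,
    fa: np.ndarray,
    config: TrackingConfig,
    seed_mask: np.ndarray,
    affine: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Whole-volume deterministic FACT tracking.

    Parameters
    ----------
    peaks : ndarray (X, Y, Z, 3)
        Per-voxel principal diffusion direction (sign-ambiguous; need not
        be normalised but must be nonzero where FA exceeds the threshold).
    fa : ndarray (X, Y, Z)
        FA volume sharing the grid of ``peaks``.
    config : TrackingConfig
    seed_mask : ndarray (X, Y, Z) of bool
        One bidirectional streamline is started per seed point.
    affine : ndarray (4, 4), optional
        Voxel-to-world (mm) transform; identity if omitted. Output points
        are world mm. Isotropic voxel scaling is assumed when converting
        the mm step size to voxel units.

    Returns
    -------
    list of (N, 3) float arrays, world mm, length >= ``min_length``,
    deterministic and independent of seed-mask iteration order.
    """
    if peaks.shape[:3] != fa.shape or peaks.shape[3] != 3:
        raise ValueError("peaks and fa must share a (X, Y, Z) grid")
    if seed_mask.shape != fa.shape:
        raise ValueError("seed_mask must share the FA grid")
    if affine is None:
        affine = np.eye(4)
    voxel_size = float(np.cbrt(abs(np.linalg.det(affine[:3, :3]))))
    step_vox = config.step_size / voxel_size
    cos_max = np.cos(np.deg2rad(config.max_turn_angle))

    seeds = _seed_points(seed_mask.astype(bool), config.seed_density)
    if len(seeds) == 0:
        warnings.warn("empty seed mask: no streamlines produced")
        return []

    out = []
    for seed in seeds:
        vox = np.round(seed).astype(int)
        if fa[tuple(vox)] < config.fa_stop_threshold:
            continue
        d0 = peaks[tuple(vox)]
        if np.linalg.norm(d0) == 0:
            continue
        fwd = _track_one_direction(seed, d0, peaks, fa, step_vox, cos_max,
                                   config.fa_stop_threshold, config.max_steps)
        bwd = _track_one_direction(seed, -d0, peaks, fa, step_vox, cos_max,
                                   config.fa_stop_threshold, config.max_steps)
        pts = bwd[::-1] + [seed.astype(float)] + fwd
        if len(pts) < 2:
            continue
        vox_pts = np.asarray(pts)
        world = vox_pts @ affine[:3, :3].T + affine[:3, 3]
        if arc_length(world) >= config.min_length:
            out.append(world)
    return out
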