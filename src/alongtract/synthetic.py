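"""Synthetic diffusion cohorts for exercising the along-tract pipeline.

The generator emulates the structure the analysis assumes, with no real
scans required: seven bilateral white-matter bundle archetypes (ATR, CG,
CST, IFO, ILF, SLF, UNC) as analytic centerline curves, per-subject shape
variability (small affine warp plus radial jitter), a smooth baseline FA
profile along each bundle's arc length, an optional group FA deficit on a
contiguous arc-length segment, linear covariate effects (age, BMI), and
clinical measures linearly coupled to segmental FA plus noise.

Default acquisition parameters mirror a conventional single-shell clinical
protocol: 45 gradient directions at b = 600 s/mm**2 with one b=0 volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .geometry import arc_length
from .scheme import AcquisitionScheme, default_scheme

TRACT_LABELS = ("ATR", "CG", "CST", "IFO", "ILF", "SLF", "UNC")
HEMISPHERES = ("left", "right")

# Analytic centerline control points (mm) for the right hemisphere of each
# archetype; the left hemisphere mirrors x -> -x. Shapes are stylised but
# evoke each tract: CST a near-vertical arc, CG a C-shaped arc, UNC a hook,
# the association bundles long anterior-posterior arcs at distinct depths.
_CONTROL_POINTS: dict[str, np.ndarray] = {
    "ATR": np.array([[12, -10, 5], [14, 5, 12], [16, 20, 16], [18, 35, 15]], float),
    "CG": np.array(
        [[8, 30, 10], [8, 18, 26], [8, -5, 32], [8, -28, 27], [8, -42, 12]], float
    ),
    "CST": np.array(
        [[28, -20, -40], [26, -18, -12], [22, -14, 18], [20, -12, 45]], float
    ),
    "IFO": np.array(
        [[30, -55, -5], [32, -22, 2], [33, 10, 4], [31, 40, 0], [28, 52, -4]], float
    ),
    "ILF": np.array(
        [[38, -50, -12], [40, -28, -16], [41, -5, -20], [40, 20, -24]], float
    ),
    "SLF": np.array(
        [[36, 30, 22], [38, 8, 30], [38, -18, 32], [36, -40, 24]], float
    ),
    "UNC": np.array(
        [[32, 8, -26], [35, 18, -20], [33, 26, -10], [28, 29, 0], [24, 22, 8]], float
    ),
}


def _centerline_from_controls(controls: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Natural cubic spline through control points, arc-length parameterised.

    The raw spline parameter is not proportional to arc length when control
    points are unevenly spaced, so the curve is densely sampled and
    re-indexed by cumulative arc-length fraction: ``curve(s)`` returns the
    point a fraction ``s`` of the total length along the curve.
    """
    from .geometry import arc_fractions

    t = np.linspace(0.0, 1.0, len(controls))
    spline = CubicSpline(t, controls, axis=0, bc_type="natural")
    dense = spline(np.linspace(0.0, 1.0, 512))
    frac = arc_fractions(dense)

    def curve(s):
        s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, 1.0)
        out = np.empty((len(s), 3))
        for k in range(3):
            out[:, k] = np.interp(s, frac, dense[:, k])
        return out

    return curve


def default_fa_profile(label: str) -> Callable[[np.ndarray], np.ndarray]:
    """Smooth stylised baseline FA profile for a tract, values in [0, 1].

    A mid-tract bump over a tract-specific floor, the common pattern of
    deep-white-matter FA rising away from the grey-matter terminations.
    """
    floor = 0.35 + 0.02 * TRACT_LABELS.index(label)
    amp = 0.15

    def profile(s):
        s = np.asarray(s, dtype=float)
        return floor + amp * np.sin(np.pi * np.clip(s, 0.0, 1.0))

    return profile


@dataclass(frozen=True)
class BundleSpec:
    """Geometry and FA model of one bundle in one hemisphere.

    ``centerline`` maps arc-length fractions in [0, 1] to (N, 3) mm points;
    ``baseline_fa_profile`` maps fractions to FA in [0, 1].
    """

    tract_label: str
    hemisphere: str
    centerline: Callable[[np.ndarray], np.ndarray]
    radius: float = 2.0
    n_streamlines: int = 20
    baseline_fa_profile: Callable[[np.ndarray], np.ndarray] = None

    def __post_init__(self):
        if self.tract_label not in TRACT_LABELS:
            raise ValueError(f"tract_label must be one of {TRACT_LABELS}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError("hemisphere must be 'left' or 'right'")
        if self.baseline_fa_profile is None:
            object.__setattr__(
                self, "baseline_fa_profile", default_fa_profile(self.tract_label)
            )
        grid = np.linspace(0, 1, 101)
        fa = np.asarray(self.baseline_fa_profile(grid), dtype=float)
        if np.any(fa < 0) or np.any(fa > 1):
            raise ValueError("baseline_fa_profile must lie in [0, 1]")
        if arc_length(np.asarray(self.centerline(grid))) <= 0:
            raise ValueError("centerline must have positive arc length")

    @property
    def key(self) -> tuple[str, str]:
        return (self.tract_label, self.hemisphere)


def default_bundle_specs(
    n_streamlines: int = 20, radius: float = 2.0
) -> list[BundleSpec]:
    """The 14 default bundles: 7 archetypes mirrored across x = 0."""
    specs = []
    for label in TRACT_LABELS:
        for hemi in HEMISPHERES:
            controls = _CONTROL_POINTS[label].copy()
            if hemi == "left":
                controls[:, 0] *= -1
            specs.append(
                BundleSpec(
                    tract_label=label,
                    hemisphere=hemi,
                    centerline=_centerline_from_controls(controls),
                    radius=radius,
                    n_streamlines=n_streamlines,
                )
            )
    return specs


@dataclass(frozen=True)
class EffectSpec:
    """A planted group/covariate/clinical effect on one bundle.

    ``fa_delta`` is added to case-group FA inside the arc-length
    ``segment``; ``covariate_slopes`` (per year of age / unit of BMI) act
    on every point of the target bundle in all subjects; the clinical
    coupling generates ``clinical_measure`` as
    ``beta * mean(FA over segment) + N(0, sd)`` per subject.
    """

    target_tract: tuple[str, str]
    segment: tuple[float, float] = (0.4, 0.6)
    fa_delta: float = 0.0
    covariate_slopes: dict = field(default_factory=dict)
    clinical_measure: str | None = None
    clinical_beta: float = 0.0
    clinical_noise_sd: float = 0.0

    def __post_init__(self):
        a, b = self.segment
        if not (0 <= a < b <= 1):
            raise ValueError("segment must satisfy 0 <= a < b <= 1")
        if abs(self.fa_delta) >= 1:
            raise ValueError("|fa_delta| must be < 1")


@dataclass
class SubjectRecord:
    """Demographics, group membership and clinical measures of one subject."""

    subject_id: str
    group: str  # "case" or "control"
    age: float
    sex: str  # "M" or "F"
    bmi: float
    measures: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in ("case", "control"):
            raise ValueError("group must be 'case' or 'control'")
        if not (np.isfinite(self.age) and np.isfinite(self.bmi)):
            raise ValueError("covariates must be finite")


@dataclass
class Cohort:
    """A generated cohort: per-subject labeled streamlines with FA samples.

    ``streamlines[sid][(label, hemi)]`` is a list of (N, 3) point arrays and
    ``fa[sid][(label, hemi)]`` the matching list of (N,) FA arrays. The
    bundle key is the generator's ground-truth label, available to tests.
    """

    subjects: list[SubjectRecord]
    streamlines: dict
    fa: dict
    bundle_specs: list[BundleSpec]
    effects: list[EffectSpec]
    seed: int

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
                "bmi": s.bmi,
            }
            row.update(s.measures)
            rows.append(row)
        return pd.DataFrame(rows)


def _random_subject_affine(rng: np.random.Generator) -> np.ndarray:
    """Small rigid-ish warp: rotation <= 5 degrees, isotropic scale +-5%."""
    angles = np.deg2rad(rng.uniform(-5, 5, size=3))
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    scale = rng.uniform(0.95, 1.05)
    return scale * (rz @ ry @ rx)


def _perpendicular_frame(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit normal/binormal fields perpendicular to per-point tangents."""
    t = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
    ref = np.array([0.0, 0.0, 1.0])
    n = np.cross(t, ref)
    bad = np.linalg.norm(n, axis=1) < 1e-8
    n[bad] = np.cross(t[bad], np.array([0.0, 1.0, 0.0]))
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    b = np.cross(t, n)
    return n, b


def _bundle_streamlines(
    spec: BundleSpec,
    warp: np.ndarray,
    rng: np.random.Generator,
    n_points: int,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Streamlines of one bundle for one subject, plus their arc fractions."""
    t = np.linspace(0.0, 1.0, n_points)
    center = np.asarray(spec.centerline(t))
    tangents = np.gradient(center, axis=0)
    normal, binormal = _perpendicular_frame(tangents)
    centroid = center.mean(axis=0)
    lines = []
    for _ in range(spec.n_streamlines):
        # constant radial offset -> parallel tube fill; bounded by radius
        r = min(abs(rng.normal(0.0, spec.radius / 2.0)), spec.radius)
        phi = rng.uniform(0, 2 * np.pi)
        offset = r * (np.cos(phi) * normal + np.sin(phi) * binormal)
        # smooth low-frequency wobble along the curve
        amp = 0.15 * spec.radius
        wob_phase = rng.uniform(0, 2 * np.pi)
        wobble = amp * np.sin(2 * np.pi * t + wob_phase)[:, None] * normal
        pts = center + offset + wobble
        pts = (pts - centroid) @ warp.T + centroid
        lines.append(pts)
    return lines, t


def generate_cohort(
    n_cases: int,
    n_controls: int,
    bundle_specs: list[BundleSpec] | None = None,
    effects: list[EffectSpec] = (),
    seed: int = 0,
    n_points_per_streamline: int = 50,
    noise_sd: float = 0.03,
) -> Cohort:
    """Generate a full synthetic cohort.

    Per subject, each bundle's streamlines are the spec centerline plus a
    constant radial offset, a smooth wobble, and a small per-subject affine
    warp. FA at each streamline point is the baseline profile at that
    point's arc fraction, plus the planted group effect (cases only, inside
    the effect segment), linear covariate terms, and i.i.d. Gaussian noise,
    clipped to [0, 1]. Identical seeds yield bit-identical cohorts.

    With all effects null (``fa_delta=0``, couplings 0) the two groups are
    exchangeable: nothing generated depends on the group label.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("n_cases and n_controls must both be >= 1")
    if bundle_specs is None:
        bundle_specs = default_bundle_specs()
    if len(bundle_specs) == 0:
        raise ValueError("bundle_specs must not be empty")
    effects = list(effects)
    rng = np.random.default_rng(seed)

    subjects = []
    for i in range(n_cases + n_controls):
        group = "case" if i < n_cases else "control"
        subjects.append(
            SubjectRecord(
                subject_id=f"sub-{i + 1:03d}",
                group=group,
                age=float(np.clip(rng.normal(45.0, 12.0), 20.0, 75.0)),
                sex="M" if rng.uniform() < 0.26 else "F",
                bmi=float(np.clip(rng.normal(23.0, 3.0), 16.0, 35.0)),
            )
        )

    effect_by_tract = {}
    for e in effects:
        effect_by_tract.setdefault(tuple(e.target_tract), []).append(e)

    streamlines: dict = {}
    fa: dict = {}
    seg_mean_fa: dict = {e.clinical_measure: {} for e in effects if e.clinical_measure}
    clipped = False
    for subj in subjects:
        warp = _random_subject_affine(rng)
        streamlines[subj.subject_id] = {}
        fa[subj.subject_id] = {}
        for spec in bundle_specs:
            lines, t = _bundle_streamlines(spec, warp, rng, n_points_per_streamline)
            base = np.asarray(spec.baseline_fa_profile(t), dtype=float)
            fa_lines = []
            for pts in lines:
                values = base.copy()
                for e in effect_by_tract.get(spec.key, []):
                    a, b = e.segment
                    in_seg = (t >= a) & (t <= b)
                    if subj.group == "case" and e.fa_delta != 0.0:
                        values = values + np.where(in_seg, e.fa_delta, 0.0)
                    for cov, slope in e.covariate_slopes.items():
                        center = {"age": 45.0, "bmi": 23.0}.get(cov, 0.0)
                        values = values + slope * (getattr(subj, cov) - center)
                if noise_sd > 0:
                    values = values + rng.normal(0.0, noise_sd, size=values.shape)
                if np.any(values < 0) or np.any(values > 1):
                    clipped = True
                fa_lines.append(np.clip(values, 0.0, 1.0))
            streamlines[subj.subject_id][spec.key] = lines
            fa[subj.subject_id][spec.key] = fa_lines
            for e in effect_by_tract.get(spec.key, []):
                if e.clinical_measure:
                    a, b = e.segment
                    in_seg = (t >= a) & (t <= b)
                    mean_fa = float(np.mean([f[in_seg].mean() for f in fa_lines]))
                    seg_mean_fa[e.clinical_measure][subj.subject_id] = mean_fa
    if clipped:
        warnings.warn("FA values outside [0, 1] were clipped")

    # default clinical panel: group-independent draws (structure comes only
    # from explicit couplings, preserving null-cohort exchangeability)
    default_measures = {
        "IRLS": (15.0, 10.0, 0.0, 40.0),
        "PLM_index": (8.0, 8.0, 0.0, 80.0),
        "MAI": (2.0, 2.0, 0.0, 20.0),
        "attention_executive": (0.0, 0.7, -3.0, 3.0),
        "BAI": (6.0, 5.0, 0.0, 40.0),
        "BDI": (9.0, 7.0, 0.0, 50.0),
    }
    coupled = {e.clinical_measure for e in effects if e.clinical_measure}
    for subj in subjects:
        for name, (mu, sd, lo, hi) in default_measures.items():
            if name not in coupled:
                subj.measures[name] = float(np.clip(rng.normal(mu, sd), lo, hi))
    for e in effects:
        if not e.clinical_measure:
            continue
        for subj in subjects:
            val = e.clinical_beta * seg_mean_fa[e.clinical_measure][subj.subject_id]
            if e.clinical_noise_sd > 0:
                val += rng.normal(0.0, e.clinical_noise_sd)
            subj.measures[e.clinical_measure] = float(val)

    return Cohort(
        subjects=subjects,
        streamlines=streamlines,
        fa=fa,
        bundle_specs=list(bundle_specs),
        effects=effects,
        seed=seed,
    )


def simulate_profiles(
    n_cases: int,
    n_controls: int,
    n_points: int = 100,
    fa_delta: float = 0.0,
    segment: tuple[float, float] = (0.4, 0.6),
    noise_sd: float = 0.03,
    age_slope: float = 0.0,
    bmi_slope: float = 0.0,
    baseline: Callable[[np.ndarray], np.ndarray] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw subject x point FA profile matrices directly from the FA model.

    Skips the geometric stages (streamlines, labeling, projection) and
    samples each subject's along-tract profile as baseline + covariate
    terms + group deficit + i.i.d. noise. This is the cohort model the
    full generator embeds, exposed directly for statistical calibration
    studies where thousands of cohorts are needed.

    Returns the (n_subjects, n_points) matrix and the subject table.
    """
    if baseline is None:
        baseline = default_fa_profile("CST")
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    t = np.linspace(0.0, 1.0, n_points)
    base = np.asarray(baseline(t), dtype=float)
    a, b = segment
    in_seg = (t >= a) & (t <= b)

    group = np.array(["case"] * n_cases + ["control"] * n_controls)
    age = np.clip(rng.normal(45.0, 12.0, size=n), 20.0, 75.0)
    sex = np.where(rng.uniform(size=n) < 0.26, "M", "F")
    bmi = np.clip(rng.normal(23.0, 3.0, size=n), 16.0, 35.0)

    Y = np.tile(base, (n, 1))
    Y[:n_cases, in_seg] += fa_delta
    Y += age_slope * (age - 45.0)[:, None] + bmi_slope * (bmi - 23.0)[:, None]
    Y += rng.normal(0.0, noise_sd, size=Y.shape)
    Y = np.clip(Y, 0.0, 1.0)

    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "group": group,
            "age": age,
            "sex": sex,
            "bmi": bmi,
        }
    )
    return Y, table


def simulate_dwi(
    tensor_field: np.ndarray,
    scheme: AcquisitionScheme | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    s0: float = 100.0,
    noise_model: str = "rician",
) -> np.ndarray:
    """Forward-simulate single-tensor DWI volumes.

    ``S(g) = S0 * exp(-b g^T D g)`` per voxel and direction. Output shape
    is ``(X, Y, Z, n_b0 + n_directions)`` with the b=0 volumes first.

    Noise: with ``noise_model='rician'`` (default) independent Gaussian
    noise of SD ``noise_sd`` is added to the real and imaginary channels
    and the magnitude taken — the physically correct MR magnitude noise.
    ``'gaussian'`` adds plain Gaussian noise, a fast approximation valid at
    high SNR. ``noise_sd=0`` yields the noiseless signals exactly.
    """
    if scheme is None:
        scheme = default_scheme()
    field = np.asarray(tensor_field, dtype=float)
    if field.shape[-2:] != (3, 3):
        raise ValueError("tensor_field must have shape (..., 3, 3)")
    shape = field.shape[:-2]
    flat = field.reshape(-1, 3, 3)
    evals = np.linalg.eigvalsh(flat)
    bad = np.flatnonzero(evals[:, 0] < -1e-12)
    if bad.size:
        vox = np.unravel_index(bad[0], shape)
        raise ValueError(f"tensor at voxel {tuple(int(v) for v in vox)} is not positive semidefinite")

    g = scheme.directions
    # per voxel, per direction: g^T D g
    quad = np.einsum("mi,vij,mj->vm", g, flat, g)
    dwi = s0 * np.exp(-scheme.b_value * quad)
    b0 = np.full((flat.shape[0], scheme.n_b0), s0)
    signals = np.concatenate([b0, dwi], axis=1)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        if noise_model == "rician":
            re = signals + rng.normal(0.0, noise_sd, signals.shape)
            im = rng.normal(0.0, noise_sd, signals.shape)
            signals = np.hypot(re, im)
        elif noise_model == "gaussian":
            signals = signals + rng.normal(0.0, noise_sd, signals.shape)
        else:
            raise ValueError("noise_model must be 'rician' or 'gaussian'")
    return signals.reshape(shape + (scheme.n_volumes,))
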