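"""Build a Tract Diffusion Profile for one bundle of one subject.

Fiber-density-based representative selection, optimal point matching of
every member to the representative, Mahalanobis-weighted FA projection,
and 100-point spline resampling — then compares the recovered profile to
the generator's known baseline.
"""

import numpy as np

from alongtract import (
    LabeledTract,
    default_bundle_specs,
    fiber_density_map,
    generate_cohort,
    match_and_project,
    resample_profile,
    select_representative,
)
from alongtract.profiles import make_grid

specs = [s for s in default_bundle_specs(n_streamlines=15)
         if s.key == ("ATR", "right")]
cohort = generate_cohort(1, 1, bundle_specs=specs, seed=0, noise_sd=0.0)
sid = cohort.subjects[0].subject_id
tract = LabeledTract("ATR", "right",
                     cohort.streamlines[sid][("ATR", "right")],
                     fa=cohort.fa[sid][("ATR", "right")])

shape, affine = make_grid(tract.streamlines)
density = fiber_density_map(tract.streamlines, shape, affine)
rep = select_representative(tract, density)
profile = match_and_project(tract, rep, subject_id=sid)
resampled = resample_profile(profile, n_points=100)

baseline = np.asarray(specs[0].baseline_fa_profile(np.linspace(0, 1, 100)))
rmse = np.sqrt(np.mean((resampled.values - baseline) ** 2))
print(f"representative: member {rep.index} with density sum {rep.density_sum:.0f}")
print(f"profile points: {resampled.n_points}")
print(f"FA range along tract: {resampled.values.min():.3f} - "
      f"{resampled.values.max():.3f}")
print(f"RMSE vs generator baseline: {rmse:.4f}")
print("With no FA noise, projection onto the representative reproduces the "
      "bundle's baseline arc-length FA profile almost exactly.")
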