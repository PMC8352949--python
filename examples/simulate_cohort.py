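"""Generate a small synthetic cohort and inspect its structure.

Builds 3 patients and 3 controls with all 14 bundle archetypes, a planted
FA deficit in the left corticospinal tract, and a clinical measure coupled
to FA over the affected segment.
"""

import numpy as np

from alongtract import EffectSpec, default_bundle_specs, generate_cohort

effect = EffectSpec(
    target_tract=("CST", "left"),
    segment=(0.4, 0.6),
    fa_delta=-0.05,
    clinical_measure="IRLS",
    clinical_beta=-60.0,
    clinical_noise_sd=2.0,
)
cohort = generate_cohort(
    n_cases=3,
    n_controls=3,
    bundle_specs=default_bundle_specs(n_streamlines=10),
    effects=[effect],
    seed=0,
)

print(cohort.table[["subject_id", "group", "age", "sex", "bmi", "IRLS"]])
sid = cohort.subjects[0].subject_id
key = ("CST", "left")
lines = cohort.streamlines[sid][key]
print(f"\n{sid} {key}: {len(lines)} streamlines, "
      f"{lines[0].shape[0]} points each")
case_fa = np.mean([np.mean(cohort.fa[s.subject_id][key], axis=0)
                   for s in cohort.subjects if s.group == "case"], axis=0)
ctrl_fa = np.mean([np.mean(cohort.fa[s.subject_id][key], axis=0)
                   for s in cohort.subjects if s.group == "control"], axis=0)
mid = slice(20, 30)  # arc fractions 0.4-0.6 of the 50-point sampling
print(f"mean FA over the deficit segment: cases {case_fa[mid].mean():.3f} "
      f"vs controls {ctrl_fa[mid].mean():.3f}")
print("The planted -0.05 FA deficit appears in the case group only; the "
      "IRLS scores above are linear in each subject's segmental FA.")
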