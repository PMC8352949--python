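"""Along-tract group inference with cluster-based permutation correction.

Simulates 30 patients vs 31 controls with a -0.05 FA deficit over the
[0.4, 0.6] arc-length segment (20 of 100 points), runs the pointwise
permutation ANCOVA adjusting for age and BMI, and corrects family-wise
error with the maximum-cluster-size null distribution.
"""

from alongtract import DesignMatrix, permutation_cbs, simulate_profiles

Y, table = simulate_profiles(
    n_cases=30, n_controls=31,
    fa_delta=-0.05, segment=(0.4, 0.6), noise_sd=0.03, seed=0,
)
design = DesignMatrix.from_table(table, covariates=("age", "bmi"))
result = permutation_cbs(
    Y, design=design, test="ancova_f",
    threshold=2.5, n_permutations=2000, seed=1,
)

print(f"cluster-forming F threshold: {result.threshold}")
print(f"permutations: {result.n_permutations}")
for (start, end, size), p in zip(result.clusters, result.corrected_p):
    flag = " *" if p < 0.05 else ""
    print(f"  cluster points {start}-{end} (size {size}): corrected p = {p:.4f}{flag}")
print("The planted 20-point deficit should surface as a large cluster with "
      "corrected p < 0.05; stray single-point crossings stay nonsignificant.")
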