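# Methods

This note records the models, numerical choices and known limitations of
the package, in the spirit of a statistical software methods appendix.

## Diffusion model and tractography

The signal model is the single diffusion tensor,
S(g) = S₀ exp(−b gᵀ D g), fitted per voxel by ordinary log-linear least
squares on log(S/S₀) (weighted least squares, weighting each equation by
its signal magnitude, is available by flag; the two coincide on noiseless
data). S₀ is the mean of the b=0 volumes. The fit requires at least six
gradient directions of full rank and strictly positive signals. FA is
computed from the eigenvalues as √(3/2)·‖λ−λ̄‖₂/‖λ‖₂; the all-zero
eigenvalue triple is defined as FA = 0, and negative eigenvalues from
noisy fits are clamped to zero before FA (both documented conventions).

Tractography is deterministic FACT: from each seed, bidirectional
propagation at a fixed step, at every step following the principal
direction of the voxel currently occupied, with sign chosen for
continuity. Defaults — FA stop threshold 0.2, maximum turn 35° per step,
step half a voxel, minimum length 10 mm, one seed per voxel — are
conventional values for this family of algorithms and are configurable;
the method description the pipeline follows leaves them open. Tracking is
exactly deterministic and independent of seed-mask iteration order (seeds
are visited in sorted voxel order).

DWI simulation adds noise on the complex channels and takes the magnitude
(Rician), the physically correct model for MR magnitude data; plain
Gaussian noise is available as a fast high-SNR approximation.

## Synthetic cohort generator

The generator emulates the *structure* the analysis assumes, not the
appearance of real scans:

- **Geometry.** Seven analytic centerline archetypes (CST a near-vertical
  arc, CG a C-shaped arc, UNC a hook, ATR/IFO/ILF/SLF long arcs at
  distinct depths), mirrored across x = 0 for the two hemispheres. Curves
  are natural cubic splines through fixed control points, re-indexed by
  cumulative arc length so the parameter is the arc-length fraction. The
  shapes are stylised but fixed; inter-bundle shape distances are large
  relative to intra-bundle spread so labeling is solvable yet nontrivial.
- **Per-subject variability.** A small affine (rotation ≤ 5° per axis,
  isotropic scale ±5%) about the bundle centroid, a constant radial tube
  offset per streamline (|N(0, r/2)| capped at the bundle radius r = 2 mm)
  and a smooth low-frequency wobble.
- **FA model.** FA at a streamline point is the bundle's baseline profile
  at that point's arc fraction (default: a mid-tract bump,
  floor + 0.15·sin(πs), floors 0.35–0.47 by tract), plus the planted group
  deficit (cases only, inside the effect segment), plus linear covariate
  terms centred at age 45 / BMI 23, plus i.i.d. Gaussian noise (default SD
  0.03), clipped to [0, 1] with a warning.
- **Clinical panel.** Default measures (IRLS, PLM index, MAI, a composite
  cognitive score, BAI, BDI) are drawn from group-*independent*
  distributions so that a cohort with no planted effects is fully
  exchangeable between groups — the property the permutation test's
  validity rests on. Structure enters only through explicit couplings:
  measure = β · (mean FA over the effect segment) + N(0, σ).
- **Cohort size.** The reference conditions are 30 cases vs 31 controls,
  45 gradient directions at b = 600 s/mm² with one b0 — a typical
  single-shell clinical protocol.
- `simulate_profiles` exposes the same FA model directly at the
  100-point profile level, skipping the geometric stages; it exists for
  calibration studies that need thousands of cohorts.

What the generator does **not** emulate: crossing or kissing fibers,
partial-volume and susceptibility artefacts, realistic FA spatial texture,
registration error between subjects, or group differences in bundle
geometry. Passing tests therefore demonstrate the pipeline's correctness
and calibration under its own assumptions, not robustness to every
property of real data.

## Bundle labeling

The shape distance is the symmetric mean-of-closest-point distance after
resampling both streamlines to 20 equidistant points. Because
closest-point distances ignore point order, the metric is inherently
orientation-invariant (an explicit flip minimisation would be a no-op).
Clustering is greedy: streamlines are visited in input order and assigned
to the nearest existing cluster whose summary lies within the threshold
(default 5 mm), else they found a new cluster; summaries are maintained as
cluster medoids. The result is a deterministic partition.

Voting: each cluster summary is scored against every atlas bundle (minimum
distance to the bundle's exemplars); per atlas the best label is a vote,
withheld above the similarity cutoff (default 15 mm); the majority label
wins, with ties broken by smallest mean distance then lexicographic label
order, making the result independent of atlas order. Registration between
subject and atlas spaces is accepted as a user-supplied affine (identity
in synthetic space); no image registration is implemented. Outlier
removal drops members farther than a bound (default 8 mm) from the tract
medoid and raises when only the medoid itself would survive in a
multi-member tract, since no meaningful bundle remains at that bound.

## Tract Diffusion Profiles

The fiber density map counts distinct streamlines per voxel (a streamline
increments a voxel once, however many points fall in it; the default grid
has 2 mm voxels bounding the tract). The representative is the member
with the maximal summed density over its visited voxels — a long, central
fiber — with exact ties going to the lowest member index.

Point correspondence is the monotone total map f from member points to
representative indices minimising the summed Euclidean distance of
matched pairs, found by dynamic programming over the alignment lattice
with ties broken toward the smallest representative index; members are
re-oriented first when endpoint distances favour the flip. This is
deliberately *not* constrained to be surjective: representative points
left unmatched take the representative's own FA and are flagged.

FA projection at each representative point averages the member FA values
mapped there with weights wᵢ = 1/(1 + d²_M(i)), where d_M is the
Mahalanobis distance of the contributing point to the spatial mean and
covariance of all contributors at that representative point, normalised
to sum to one — bounded, decreasing, and exactly uniform under symmetric
configurations. With fewer than three contributors or a rank-deficient
covariance the weights fall back to uniform (logged). Profile values are
therefore convex combinations of member FA.

The group-wise representative applies the same density rule to the pooled
subject representatives and is retained only when strictly more than 60%
of subjects support it (support = the tract was found for the subject;
an optional distance gate can tighten this); failing tracts are excluded
from statistics with a logged reason. The group representative geometry
is spline-resampled to 100 equidistant arc-length points, and each
subject's profile is carried onto those points by the same
optimal-point-matching operator (values landing on one group point are
averaged; gaps are linearly interpolated over the point index). Profile
resampling uses a natural cubic spline over arc-length fraction (exact on
linear ramps), falling back to linear interpolation below 4 points, with
values clipped to [0, 1] against spline overshoot.

## Statistics

Per sample point, the group test is the ANCOVA F for the group factor:
full model (intercept + covariates + group) vs covariates-only, computed
via the partitioned-regression identity on QR-orthonormalised designs.
With no covariates this reduces exactly to one-way ANOVA. Clinical
association uses the partial correlation (Pearson correlation of the
residuals of FA and of the measure after regressing out the covariates);
zero-variance residuals yield r = 0 with a flag. Sex is encoded 0/1
(reference level dropped); any categorical covariate is one-hot encoded
the same way.

Cluster-based correction: clusters are maximal runs of points with the
statistic *strictly* greater than the threshold (F > 2.5 by default; for
correlations the default |r| threshold is the value whose t statistic
matches F = 2.5 at the sample's residual df, so both tests form clusters
at an equivalent pointwise severity). The null distribution of the
maximum cluster size is built by permutation — by default Freedman–Lane,
permuting residuals of the covariates-only model so covariate structure
is respected; plain label permutation is available by flag. The corrected
p of an observed cluster is (1 + #{null max ≥ size})/(1 + n_permutations):
the +1/+1 convention keeps p positive and includes the identity
arrangement, at the price of a conservative bias of order 1/n_perm. An
exact mode enumerates all distinct label arrangements (small n) and
reports the plain fraction. Corrected p is monotone non-increasing in
cluster size by construction.

## Calibration studies and problem sizes

The packaged studies (also recomputed by `scripts/acceptance.py`) use
sizes chosen to give stable estimates at desk scale: family-wise type-I
error on 200 null cohorts of 30 vs 31 subjects at 500 permutations each
(observed ≈ 0.025–0.03 — slightly conservative, as expected from cluster
discreteness and the +1/+1 estimator, and within the 95% binomial band
around 0.05); power ≈ 1.0 over 50 replicates for the reference deficit
(−0.05 FA over 20 of 100 points, noise SD 0.03); labeling accuracy 100%
on the clean 280-streamline phantom against 3 atlases; noiseless
end-to-end profile recovery RMSE < 0.005 for all 14 bundles. The
calibration studies draw profile matrices from the generator's FA model
directly (`simulate_profiles`); the recovery study runs the full
geometric pipeline.

## Known limitations

- FACT uses nearest-voxel direction lookup and an isotropic-voxel
  conversion of the mm step size; strongly anisotropic voxels would need
  a finer treatment.
- The mean-closest-point distance can under-separate bundles that overlap
  over most of their length; the synthetic archetypes are built apart, and
  real crossing-bundle confusions would require a richer metric.
- Group-representative support uses tract presence by default; with very
  heterogeneous geometry a distance-gated support is the safer choice.
- Exact permutation enumeration is implemented for the group test only
  and is limited to n ≤ 10.
- The correlation analysis inherits its cluster-forming threshold from
  the F threshold via the t–r relation; there is no separate calibration
  of that choice.
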