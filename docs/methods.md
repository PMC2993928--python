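# Methods

This note documents the statistical procedures `fagap` implements, the
choices made where the design was open, and what the synthetic-data tests
do and do not establish.

## Voxel contrast

The group comparison is a mass-univariate two-sample t test on registered
FA volumes sharing one grid, with the sign convention *positive t =
patients elevated*. The default is the classic pooled-variance (Student)
test with df = n₁ + n₂ − 2, the standard choice in voxel-based packages of
the era this analysis style comes from; Welch's unequal-variance test is
available behind the `variance="welch"` option and is recorded in output
provenance. Voxels are excluded from the search set if any subject has
missing FA there (only voxels valid in every subject after registration
are comparable) or if the pooled variance is zero (a degenerate voxel
would otherwise produce an infinite t). No spatial smoothing is applied to
the FA maps before the contrast. Implementation is a vectorized closed
form over the whole grid; unit tests compare 100 random voxels per run
against `scipy.stats.ttest_ind` to 1e-10 relative tolerance.

## Cluster inference

**Connectivity.** Suprathreshold voxels (two-tailed p below the per-voxel
threshold, 0.05 by default) are grouped into maximal connected components
separately for positive and negative t, so each cluster has one direction
of effect. The contiguity rule "sharing a face or an edge, but never only
a corner" is 18-connectivity in 3-D and is the default; 6- and
26-connectivity are selectable and recorded. Detection uses
`scipy.ndimage.label`; the test suite checks all three settings against an
independently written breadth-first flood fill on random fields.

**Tier assignment.** A cluster is evaluated at the tier of the evaluation
area (AOE) containing a strict majority (> 50%) of its voxels; exactly
half is not enough, and failing any majority the cluster falls to the
whole-brain tier. If masks of different tiers both hold a majority
(possible only across tiers, since same-configuration hypothesis masks
must be disjoint), the more lenient tier wins.

**Correction.** The peak-voxel threshold is α · k / N_search, where k is
the tier's cluster-extent requirement (9 / 27 / 81 voxels by default) and
N_search the total evaluated-voxel count of *all* AOE masks of that tier
combined — the area being considered, not the single matched mask. For
the whole-brain tier N_search defaults to the evaluated search-mask size;
fixed published constants (e.g. 418 / 9,308 / 200,000) can be supplied as
config overrides. A peak within one order of magnitude of its threshold
(trend factor 10) is classified a trend. Components smaller than their
tier's k are retained in output, flagged not significant, so sub-extent
structure stays visible to follow-up analyses.

**Peak definition.** The peak is the member voxel with smallest p (ties
broken by |t|, then index order), reported at the uninterpolated voxel
centre in mm through the grid affine. Published peak tables in this
analysis style often carry sub-voxel coordinates from display
interpolation; this package reports voxel centres only.

**A calibration caveat, measured by the test suite.** The α/(N/k) rule
treats the search volume as N/k independent cluster-sized comparisons.
Under spatially *smooth* noise this under-corrects: a single smooth peak
that crosses the corrected threshold almost always brings ≥ k
suprathreshold neighbours with it, so the effective number of independent
comparisons is governed by the noise smoothness (resel count), not by
N/k. The null-calibration acceptance test runs 100 no-effect cohorts
through the full pipeline and measures the family-wise significant-cluster
rate at the primary tier; under the generator's default smoothness (FWHM
2 voxels) that rate exceeds the nominal α = 0.05, and the test fails by
design rather than being weakened. Users who need exact family-wise
control should prefer the permutation route (below) or an explicitly
smoothness-aware correction, which is out of scope here.

**Permutation validation.** For a detected cluster, per-subject cluster
means can be referred to an unrestricted group-label permutation test,
two-sided via the absolute difference of group means. When the requested
number of permutations covers all C(n, n₁) label assignments the test is
exhaustive and exact; otherwise Monte-Carlo assignments are drawn with the
identity permutation included, and p is the plain proportion of
assignments at least as extreme. The seed is mandatory.

**Laterality.** Per subject, the index (R − L)/(R + L) is computed over
homologous left/right region means (equal voxel counts required); each
group's indices are tested against zero with a one-sample t and compared
between groups with a pooled two-sample t. Degenerate all-zero index sets
report t = 0, p = 1 rather than NaN.

## Gapping analysis

Per-subject cluster-mean FA values are sorted; the lowest and highest
floor(0.25 · n) order statistics are discarded (5 from each end at
n = 22, retaining 12 values and 11 gaps — "middle 50%" with floor
rounding at non-divisible n; the alternative keep-11 reading moves the
retained window but not the decisive boundary on the packaged reference
data). Each gap between consecutive retained values is divided by the mean
retained gap, so the ratios average to one; the statistic is the largest
ratio, and its boundary splits all n subjects — including the trimmed
ones — into below-gap and above-gap subgroups. Equal adjacent values give
zero gaps; if every retained gap is zero the statistic is undefined and
reported as an error.

The null probability is the proportion of Monte-Carlo samples of size n
from a single-population reference family — standard Gaussian or Student
t(df), df = 4 by default — whose own maximal middle-gap ratio, computed by
the identical trim rule, is at least the observed one (≥, plain
proportion, no +1 correction). The statistic is location- and
scale-invariant, so simulating from unit-scale distributions is valid for
data on any scale, and the scaling of the t null (raw vs standardized to
unit variance) is immaterial — a property test verifies this directly.
The same invariance means the Gaussian and t(4) nulls give very similar
probabilities for the same observed ratio: the normalized middle-spacing
profile of a sample is nearly family-independent at these tail weights.
A calibration test feeds 200 null samples through the full procedure and
checks the resulting p-values are uniform up to Monte-Carlo discreteness.

Multi-gap (three-or-more subgroup) segmentation and mixture-model or
dip-test alternatives are out of scope.

## Subgroup follow-up

Cluster means are arithmetic means over cluster voxels, excluding each
subject's missing voxels. Follow-up screening includes primary-tier
clusters that met the extent but not the Bonferroni threshold, because a
heterogeneous cohort can dilute a subgroup-specific effect below full
significance in the pooled contrast. The gapping analysis runs per
follow-up cluster; the cluster with the largest maximal gap ratio defines
the subgroup labels.

Each subgroup is re-contrasted against exactly its own members' matched
controls (equal group sizes by construction), under the identical tier
configuration including N_search values. A subgroup equal to the full
cohort reproduces the full-cohort output exactly; a singleton subgroup is
rejected since no t statistic exists.

Symptom comparisons are pooled two-tailed t tests per measure between the
two subgroups, on available cases per measure (so df can differ across
measures when scores are missing), flagged significant at α / 5 = 0.01
across the five measures (total depression severity, anhedonia, sadness,
psychomotor symptoms, trait anxiety).

## Synthetic cohorts

The generator emulates what the analysis assumes about real registered FA
data, with these defaults chosen once as the study conditions:

- **Grid** 32×32×32 at 2 mm (a "desk-scale" grid that keeps the full
  pipeline in seconds; the voxel-level statistics are grid-size
  agnostic), affine centred on the origin.
- **Baseline FA** 0.45 with iid Gaussian voxel noise, sd 0.06, smoothed
  by an isotropic Gaussian kernel of FWHM 2 voxels — the minimal
  structure mimicking the spatial correlation of registered FA maps.
  Values are clamped to [0, 1].
- **Planted effects** are box regions where patient volumes are shifted
  by `effect_size` standard deviations; with `subgroup_fraction` < 1 the
  `separation` (in sd units) is added only for a random carrier subgroup,
  producing a bimodal region-mean distribution. Shifts are standardized
  against the *post-smoothing* voxel sd, computed exactly from the
  squared-kernel sum, so planted Cohen's d is calibrated at the voxel
  level (verified empirically by a generator test). An effect can be
  planted in the complement of another effect's carriers to build
  double-dissociation designs.
- **Masks**: one primary AOE per planted region (the region dilated by
  one voxel), a disjoint secondary box, and a whole-brain mask.
- **Symptoms**: trait anxiety is drawn per latent subgroup
  (control 35 ± 8, normal subgroup 51.3 ± 8.9, abnormal subgroup
  61.8 ± 7.3 — the separation magnitude a subgroup-resolving cohort
  exhibits), while the depression measures share one distribution across
  subgroups (total 36 ± 9.6; item scores ~1–2 ± 1), so a correct
  analysis flags trait anxiety and nothing else.

Generation is bit-reproducible for a fixed seed; the pipeline expands one
top-level seed deterministically per stage.

What passing synthetic tests show: the machinery detects what it is
pointed at — planted clusters are recovered with the correct sign, a
4-sd bimodal structure carried by 10 of 22 patients is split with at most
one misassignment, and subgroup re-contrasts dissociate cleanly. What
they do not show: performance on real FA data, whose noise is
non-Gaussian, non-stationary, and registration-dependent, whose effect
sizes are far smaller, and whose anatomy is not a box. The generator's
variance and smoothness defaults were chosen for test power, not fidelity
to any particular scanner or cohort.

## Numerical details

- FA from tensor eigenvalues: FA = √(3/2) · √(Σ(λᵢ − λ̄)² / Σλᵢ²),
  undefined for an all-zero triple, rejecting negative eigenvalues,
  clipped against rounding at the anisotropic limit.
- FA volumes tolerate bound violations up to 1e-6 (clamped with a
  warning); larger violations are errors, since they indicate the input
  is not an FA map.
- Cohort tables enforce one-to-one patient/control pairing and, for
  matched designs, the |age| ≤ 5 and |education| ≤ 5 year windows.
- Voxel indices are 0-based; mm coordinates go through the NIfTI affine.
- All Monte-Carlo routines take explicit seeds and are deterministic
  given them.
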