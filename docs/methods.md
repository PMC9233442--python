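# Methods

This note documents the statistical model behind `varconn`, the design
of its synthetic-study generator, the numerical conventions, and the
known limitations — what passing tests do and do not establish about
real resting-state data.

## The analysis model

Each subject contributes a 4D BOLD-like volume with a repetition time TR
and a 6-column motion table. The per-subject connectivity map is built
as follows:

1. the first two volumes are dropped (non-steady-state magnetization in
   the emulated acquisitions);
2. all brain voxels are bandpass filtered to 0.01–0.1 Hz with a
   zero-phase frequency-domain filter whose transitions are raised
   cosines of width 0.005 Hz (the band edges are the conventional
   resting-state analysis band; no filter design was prescribed, so a
   sharp linear-phase-free design was chosen for testability — a pure
   in-band sinusoid passes with its analytic gain exactly);
3. the seed's spatial-mean time course is z-transformed and used as the
   predictor of a z-normalized voxelwise GLM; nuisance regressors are
   the 6 motion parameters, their backward-difference derivatives
   (first row zero), the white-matter and ventricle mean signals, an
   intercept, and optionally the global mean. All non-intercept columns
   are z-scored; degenerate columns are kept as zeros and flagged;
4. the subject map is the seed predictor's t statistic (betas are
   retained and selectable). t rather than beta matters: with z-scored
   data the beta is a correlation and saturates at ±1, whereas
   t = (w/σ)·√df is exactly linear in the underlying signal amplitude w
   at fixed noise σ — group variance ratios survive on the t scale and
   are compressed on the beta scale;
5. maps are smoothed with a 6 mm FWHM Gaussian (σ = FWHM/2.355,
   truncated at 4σ, renormalized inside the analysis mask so border
   voxels are unbiased);
6. site standardization. Two readings of "z normalization of the data"
   are implemented. `site_standardize` z-scores each subject's map
   across voxels (mean 0, SD 1 per map). The pipeline default is
   `site_standardize_voxelwise`: each voxel is z-scored across subjects
   within cohort. The voxelwise form is used for all group analyses
   because it preserves the between-group variance ratio at every voxel
   exactly (both groups are divided by the same per-voxel scale),
   whereas the per-subject form divides each map by a normalizer that
   correlates with the subject's own extreme values; at desk scale,
   where a few parcels dominate a map's SD, that shrinks the
   high-variance group specifically and biases the variance ratio
   downward by up to a factor of two. A scalar per-cohort scale is all
   that is needed anyway: the t statistic is invariant to affine site
   effects on the raw signal, so cohorts differ only through global
   factors (scan length, band fraction of the noise).

Group statistics operate on the (subjects × in-mask voxels) matrix:
an unbalanced 2×2 fixed-effects ANOVA (group × cohort) via effect-coded
regression with Type-III tests, a pooled-variance post-hoc t
(blind − sighted, two-sided p), the Brown–Forsythe map (one-way ANOVA F
on |x − group median| with df (1, n−2); a spread-free group contributes
zero deviations and yields the F = 0 path, and perfect separation yields
F = ∞ rather than an error), per-group unbiased variance maps, and the
blind/sighted variance ratio. With `normalize_within_group` the group
variance is the pooled within-(group × cohort)-cell variance — the
cohort-robust variant, and the quantity that is exactly invariant under
cell demeaning. The ratio map is reported only where the Brown–Forsythe
map passes the supplied significance mask, as in the emulated analysis,
with a display threshold of 3 carried along.

## Concordance and its spatial null

Lin's CCC uses population (1/n) moments. The permutation null shuffles
one map's in-mask values, convolves the shuffled volume with a Gaussian
at the FWHM estimated from the original map (mask-renormalized), then
rescales the null map to the original in-mask mean and SD before
recomputing the CCC; p is two-sided with the +1 correction. The
rescaling matters: smoothing shrinks variance, and without it the null
CCC is biased toward zero and the test is invalid. Smoothness for the
null is estimated from the shuffled map's original only.

For the coupled-effect analyses the "variability map" is
log(Brown–Forsythe F) — the log is variance-stabilizing for an
F-distributed field — and the "group-difference map" is the post-hoc t.
Cross-seed specificity computes the CCC for every (variability seed i,
group-difference seed j) pair; after Fisher z = atanh(CCC) (clipped at
1 − 1e−12 with a flag), the designated seed's same-seed value is
compared against the cross-seed distribution and against the other
seeds' same-seed values by one-sample-style t tests — both schemes are
emitted because the emulated analysis's exact pairing could not be
pinned down.

## Cluster-extent correction

The Monte Carlo null smooths white Gaussian volumes to a target FWHM,
z-scores in-mask, thresholds two-sided at the voxel p (clusters formed
separately per sign, 6-neighborhood connectivity), and records the
largest cluster; the minimum extent is the smallest k whose null
exceedance probability, with the +1 finite-sampling correction, is
≤ α. Defaults: α = 0.05, production 10,000 iterations.

Smoothness estimation offers two estimators. The classic
first-difference variance ratio (ρ = 1 − var(Δx)/(2·var), Gaussian ACF,
FWHM = 2.355·voxel·√(−1/(4 ln ρ)), geometric mean over axes) is accurate
for homogeneous fields but overestimates badly when a piecewise-constant
regional pattern (parcel-level subject effects) inflates the total
variance in its denominator. The lag-ratio estimator solves the Gaussian
ACF from var(lag-2 differences)/var(lag-1 differences) and never touches
the total variance, making it robust to that structure; it is used
wherever group maps feed the correction. Both floor at the voxel size
with a warning when neighbor correlation vanishes.

The covariate (education) analysis additionally offers an exact
permutation null: the covariate is permuted across subjects and the
maximum suprathreshold cluster recorded per permutation. This is the
default in the validation experiments because the synthetic r-map null
is a *mixture* of smoothness scales — smoothed parcel blocks on top of
smoothed estimate noise — and is heavy-tailed (a chance parcel-level
correlation produces a ~whole-parcel cluster) in a way no single-FWHM
Gaussian null can represent. For the same reason the covariate
cluster-forming threshold is voxel p = 1e−4 (the emulated analysis
states only "p < 0.05 corrected"; the forming threshold is left
explicit everywhere in this package).

## Fingerprints

Subject profiles are parcel means of the connectivity map (the seed's
own parcel excluded). Dissimilarity is 1 − Pearson r; clustering is
complete linkage (monotone merge heights; deterministic given the
input order). Group dissimilarity levels are compared two ways: the
primary scheme t-tests per-subject mean within-group distances
(df = n_b + n_s − 2), the secondary naive scheme pools lower-triangle
entries and is flagged for pair non-independence. Neither is exactly
calibrated — per-subject means share pairwise entries, so the primary
scheme's null coverage sits a few points below nominal (~0.86–0.89
measured) — and the package uses it for direction and magnitude, not
for calibrated inference.

## The synthetic generator

A session is a low-rank sum of latent signals plus noise:
BOLD(v,t) = Σ_k L_k(v)·s_k(t) + ε(v,t), where every s_k is a
unit-variance Gaussian process band-limited to 0.01–0.1 Hz (so the
analysis band preserves it) and ε is temporally white Gaussian noise,
spatially smoothed to a target FWHM and rescaled. Latents: the primary
seed signal, loaded by each subject's per-parcel connectivity weights
(weight 1 in the seed parcel itself); one signal per control-seed
parcel; white-matter and ventricle signals (unit loading in their
compartments, small random leakage into gray matter so nuisance
regression is consequential); and a motion-coupled component (six
smooth random walks, summed, loaded through a random smooth map).
Cohorts differ by TR (3 s vs 2 s), scan length (180 vs 240 volumes),
and an affine site effect (scale 1.3, offset 0.5 for cohort B).

Default study conditions mirror the emulated design: 13 + 18 (cohort A)
and 12 + 13 (cohort B) blind/sighted subjects; planted blind/sighted
weight SD ratio 2.2 (variance ratio 4.84, the reported order of
magnitude) in two parcels with means 1.0 vs 0.3; an education parcel
with the same mean effect plus a blind-only slope of 0.25 weight units
per education year (education uniform on 8–20 years, giving a planted
education correlation of r ≈ 0.8); and three negative-mean parcels
(−1.0 vs −0.3, equal variances) mirroring the reported
decreased/negative sensorimotor connectivity. Remaining parcel weights
are 0 ± 0.5.

Several scales were set by an explicit desk-scale consideration: any
component shared between the seed time course and target voxels (a
global latent, or the averaged noise inside a small seed parcel) adds
residual variance that grows quadratically with the planted weight,
selectively compressing the extreme (blind) values and deflating the
variance ratio. Real V1 seeds contain hundreds of voxels and the seed
signal is a small fraction of the global signal, so the effect is
negligible there; on a 14×14×12 grid it is not. Hence: noise SD 1.5 at
3 mm spatial FWHM (a realistic raw-BOLD smoothness), no free-standing
global latent (the global *mean* still exists, as the sum of all
components, so global-signal regression remains meaningful), weight
jitter for control seeds and tissue leakage at SD 0.05, a seed parcel
grown two BFS rings larger than the others, and positive/negative
planted parcels balanced so the brain-mean seed loading reduces to the
seed parcel alone (otherwise the global-mean regressor is nearly
collinear with the seed predictor and the GSR variant destroys
detection). Control-seed parcels carry no primary-seed weight at all so
that cross-seed comparisons are true nulls.

The atlas is a brain-like ellipsoid with a central ventricle box and a
white-matter shell; gray matter is partitioned into contiguous parcels
by multi-source BFS from farthest-point-sampled seeds. When clades are
planted, the per-clade profile templates are orthonormalized random
directions scaled to SD 2.5 per parcel — distinct by construction, as a
planted-subgroup study requires — and assigned round-robin to blind
subjects.

## What the generator does and does not emulate

It reproduces the statistical structure the analyses consume: two
groups × two sites with different sampling rates and affine site
effects, region-level between-subject connectivity variation with
planted mean/variance/covariate effects, band-limited hemodynamic-like
signals, motion and tissue confounds, and spatially smooth noise. It
does **not** emulate realistic hemodynamic response shapes,
physiological (cardiac/respiratory) noise spectra, scanner artifacts,
head-motion image displacement (motion enters only as regressors and
couplings), anatomical variability, or registration error. Passing
recovery tests therefore demonstrates that the statistical machinery is
correct and calibrated under the modeled structure, not that the
pipeline is robust to every artifact of real acquisitions.

## Numerical conventions and degenerate inputs

- Voxel coordinates are 0-based grid indices; world coordinates travel
  only through the NIfTI affine.
- Group and cohort labels are case-sensitive controlled vocabularies
  ({blind, sighted} × {A, B}).
- Zero-variance voxel series map to NaN (counted and warned); empty
  seed masks, zero-variance seed time courses, empty ROIs, singleton
  demeaning cells, constant covariates, and zero-variance profiles
  raise descriptive errors.
- Variances are unbiased (n−1) except the population moments inside the
  CCC (Lin's original definition).
- All randomness flows through numpy Generators seeded from explicit
  integers; identical spec + seed reproduces studies bit-identically.
- Validation problem sizes: the default grid is 14×14×12 voxels at
  3 mm (~630 gray voxels, 10 parcels); the Brown–Forsythe null
  calibration uses a 26×26×20 variant so its gray mask holds > 5,000
  voxels, with spatially independent noise and zero between-subject
  weight variability so those voxels are effectively independent tests
  (with parcel-level weights, a whole study carries only ~n_parcels
  independent voxel tests). Replication counts follow the validation
  protocol: 1,000 Brown–Forsythe reference samples, 50 studies for
  ratio recovery, 500 permutation-null replicates × 1,000 iterations,
  100 studies for concordance and clade recovery, 200 null studies for
  family-wise error, 40 for education recovery.

## Known limitations

- The Brown–Forsythe test is itself slightly conservative at these
  group sizes (~0.042 at nominal 0.05 on iid normal data); the
  calibration band in the validation suite reflects the test, not an
  implementation artifact.
- Single-FWHM Gaussian cluster correction under-protects when map
  smoothness is heterogeneous; see the lag-ratio estimator and the
  permutation null above. The study-level family-wise error of the
  Brown–Forsythe cluster pipeline lands at the high end of its band for
  the same reason.
- The group-dissimilarity t is mildly anticonservative (correlated
  per-subject means).
- The per-subject standardization variant is retained for comparison
  but is not recommended for variance-ratio estimation (see above).
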