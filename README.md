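# varconn

Interindividual variability analysis of seed-based resting-state
functional connectivity (RSFC), with a synthetic-study generator that
plants recoverable ground truth.

## The scientific problem

Congenital blindness reorganizes the connectivity of the primary visual
cortex (V1). A natural question is whether that reorganization is the
*same* in every blind person or idiosyncratic: do blind individuals show
larger between-subject variability in their V1 connectivity than sighted
controls, and is the extra variability concentrated exactly where the
group-mean connectivity differs? `varconn` implements the statistical
machinery needed to answer that kind of question on two-site,
two-group resting-state data:

- **Per-subject seed-RSFC maps.** The seed's mean time course is
  z-transformed and used as the predictor in a z-normalized voxelwise
  GLM with 6 motion parameters, their first derivatives, white-matter
  and ventricle means (optionally the global mean) as nuisance
  regressors, after 0.01–0.1 Hz bandpass filtering; maps are smoothed
  with a 6 mm FWHM Gaussian and site-standardized.
- **Variance-homogeneity mapping.** Per voxel, the Brown–Forsythe test
  (one-way ANOVA on absolute deviations from the group medians,
  `F = MS_between(z) / MS_within(z)` with `z_ij = |x_ij − median_j|`)
  asks whether blind and sighted differ in spread, not just mean; the
  directional measure is the variance ratio `S²_blind / S²_sighted`.
- **Concordance of reorganization and variability.** Lin's concordance
  correlation coefficient,
  `CCC = 2·cov(x,y) / (var(x) + var(y) + (mean(x) − mean(y))²)`,
  compares the group-difference map with the variability map; its
  significance comes from a spatial permutation null that shuffles one
  map's voxels and re-smooths to the map's estimated smoothness,
  preserving spatial autocorrelation. Cross-seed comparisons (other
  parcels as control seeds) test spatial specificity via Fisher-z
  transformed CCCs.
- **Cluster-extent correction.** Monte Carlo simulation of smooth null
  volumes yields the minimum cluster size controlling family-wise error
  over the gray-matter mask; smoothness is estimated from the data.
- **Connectivity fingerprints.** Per-subject parcel profiles are
  clustered with complete linkage on correlation distance (1 − Pearson r)
  into clades; group dissimilarity levels are compared, and voxelwise
  correlation with a scalar covariate (e.g. years of education) is
  cluster-corrected.

Real data of this kind are not openly deposited, so the package ships a
first-class synthetic generator (`varconn.synth`): two cohorts with
different TR/scan length (3 s × 180 and 2 s × 240 volumes; 13/18 and
12/13 blind/sighted subjects), subject connectivity weights per atlas
parcel whose group means *and* variances differ in designated parcels
(default SD ratio 2.2, i.e. variance ratio 4.84), affine site effects,
motion-coupled and tissue nuisance signals, spatially smooth noise, a
blind-only education slope, and optional planted subject clades — every
downstream statistic has known truth.

## Worked example

```python
import numpy as np
from varconn import synth, rsfc, variability, concordance

spec = synth.SyntheticSpec(rng_seed=7)          # default two-cohort study
sessions, atlas, participants, truth = synth.simulate_study(spec)
values, groups, cohorts = rsfc.study_connectivity_maps(sessions, atlas)

bf_F, bf_p, _ = variability.brown_forsythe_map(values, groups)
s2b, s2s, ratio, _ = variability.group_variance_and_ratio(
    values, groups, cohorts, normalize_within_group=True,
    sig_mask=bf_p < 0.005)
t_map, df, _ = variability.posthoc_ttest_map(values, groups)

planted = np.isin(atlas.labels[atlas.gray_mask], [3, 4])
print(f"median variance ratio in planted parcels: "
      f"{np.nanmedian(ratio[planted]):.2f} (planted 4.84)")

mask = atlas.gray_mask
v3 = np.zeros(mask.shape); v3[mask] = np.log(bf_F + 1e-6)
d3 = np.zeros(mask.shape); d3[mask] = t_map
res = concordance.spatial_permutation_test(v3, d3, mask, n_iter=10_000,
                                           rng_seed=7)
print(f"variability~reorganization CCC = {res.ccc:.3f}, p = {res.p_value:.4f}")
```

Output:

```
median variance ratio in planted parcels: 3.79 (planted 4.84)
variability~reorganization CCC = 0.325, p = 0.0001
```

The recovered voxelwise blind/sighted variance ratio approaches the
planted 4.84 (any single study scatters widely around it because all
voxels of a parcel share one weight draw per subject; the median over
many studies converges), and the concordance between where the groups differ
in mean and where the blind are more variable is positive and highly
significant — the planted coupling is recovered.

The same pipeline is scriptable from the shell:

```bash
varconn simulate --out study/ --seed 7
varconn rsfc --study study/
varconn groupstats --study study/ --maps study/derived/rsfc --normalize-within-group
varconn profiles --study study/ --maps study/derived/rsfc --exclude 1 --cut 3
varconn covariate --study study/ --maps study/derived/rsfc --group blind
```

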