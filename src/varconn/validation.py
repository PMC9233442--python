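"""Study-level validation experiments on synthetic data.

Each function simulates studies with the generator, runs the analysis
pipeline, and measures a calibration or recovery property: Brown-Forsythe
agreement with an independent reference and its type-I error, recovery of
the planted variance ratio, permutation-null calibration and coupled
mean/variance concordance recovery, cluster-extent family-wise error,
clade recovery, and education-covariate recovery. These drive both the
test suite and ``scripts/acceptance.py``.

Problem sizes: the subject counts, scan lengths and planted effect sizes
are the generator defaults; grids are the desk-scale default
(14 x 14 x 12 at 3 mm) except where a larger mask is the point of the
experiment.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats

from . import clustercorr, concordance, profiles, rsfc, synth, variability

DEFAULT_VOXEL_P = 0.005


def _child_seeds(seed, n):
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in np.random.SeedSequence(seed).spawn(n)]


def null_spec(seed, **overrides):
    """Default study with no planted group, variance, or education effects."""
    kw = dict(region_effects=(), education_slope=0.0, rng_seed=seed)
    kw.update(overrides)
    return synth.SyntheticSpec(**kw)


def run_study_pipeline(spec, stat="t", use_global=False, demean_cells=False,
                       smoothing_fwhm_mm=6.0):
    """Simulate one study and produce the standardized subject-map matrix."""
    sessions, atlas, participants, truth = synth.simulate_study(spec)
    values, groups, cohorts = rsfc.study_connectivity_maps(
        sessions, atlas, stat=stat, use_global=use_global,
        smoothing_fwhm_mm=smoothing_fwhm_mm,
    )
    if demean_cells:
        values = rsfc.demean_by_subgroup(values, groups, cohorts)
    return dict(values=values, groups=groups, cohorts=cohorts, atlas=atlas,
                participants=participants, truth=truth, sessions=sessions)


# ---------------------------------------------------------------------------
# Brown-Forsythe


def bf_reference_agreement(n_samples=1000, n_blind=25, n_sighted=31, seed=0):
    """Max |F difference| between our BF map and scipy's Levene(median)."""
    from scipy.stats import levene

    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_blind, n_samples)) * rng.uniform(0.5, 3.0, n_samples)
    y = rng.standard_normal((n_sighted, n_samples))
    values = np.vstack([x, y])
    groups = np.array(["blind"] * n_blind + ["sighted"] * n_sighted)
    F, p, _ = variability.brown_forsythe_map(values, groups)
    ref = np.array([levene(x[:, j], y[:, j], center="median").statistic
                    for j in range(n_samples)])
    return float(np.max(np.abs(F - ref)))


def bf_null_calibration(seed=0, alpha=0.05, min_voxels=5000):
    """Voxelwise BF type-I error on a null study with >= ``min_voxels``.

    The calibration grid is enlarged so the gray mask holds the requested
    voxel count. Spatially independent noise, no map smoothing, and no
    between-subject parcel-weight variability (baseline_sd = 0) make the
    in-mask voxel tests effectively independent -- otherwise each parcel's
    voxels share one weight draw per subject and a single study carries
    only ~n_parcels independent tests, leaving the empirical rate
    unmeasurable at this precision.
    """
    spec = null_spec(seed, grid_shape=(26, 26, 20), noise_fwhm_mm=0.0,
                     control_seed_parcels=(), baseline_sd=0.0)
    res = run_study_pipeline(spec, smoothing_fwhm_mm=0.0)
    n_vox = res["values"].shape[1]
    if n_vox < min_voxels:
        raise RuntimeError(f"calibration mask has {n_vox} voxels < {min_voxels}")
    _, p, _ = variability.brown_forsythe_map(res["values"], res["groups"])
    return dict(rate=float(np.mean(p < alpha)), n_voxels=n_vox, alpha=alpha)


def variance_ratio_recovery(n_studies=50, seed=0, alpha=0.05,
                            sig_voxel_p=DEFAULT_VOXEL_P):
    """Recovery of the planted SD ratio 2.2 (variance ratio 4.84).

    For each simulated default study, the voxelwise blind/sighted variance
    ratio (within-group normalized) is computed on the voxels of the
    parcels planted with the 2.2 SD ratio that pass the Brown-Forsythe
    cluster-forming threshold (the ratio map is only defined at significant
    voxels, as in the emulated analysis); BF power is the voxelwise
    rejection rate at ``alpha`` over all planted voxels.
    """
    medians, powers = [], []
    for s in _child_seeds(seed, n_studies):
        spec = synth.SyntheticSpec(rng_seed=s)
        res = run_study_pipeline(spec)
        atlas = res["atlas"]
        planted = [e.region_id for e in spec.region_effects
                   if e.sd_sighted > 0 and abs(e.sd_blind / e.sd_sighted - 2.2) < 1e-9]
        sel = np.isin(atlas.labels[atlas.gray_mask], planted)
        _, p, _ = variability.brown_forsythe_map(res["values"], res["groups"])
        _, _, ratio, _ = variability.group_variance_and_ratio(
            res["values"], res["groups"], res["cohorts"], normalize_within_group=True,
            sig_mask=p < sig_voxel_p,
        )
        sig = sel & (p < sig_voxel_p)
        if sig.any():
            medians.append(float(np.median(ratio[sig])))
        powers.append(float(np.mean(p[sel] < alpha)))
    return dict(median_ratio=float(np.median(medians)), medians=medians,
                power=float(np.mean(powers)), true_ratio=4.84)


# ---------------------------------------------------------------------------
# concordance


def _smooth_null_map(shape, mask, fwhm_mm, voxel_size_mm, rng):
    sigma = fwhm_mm * synth.FWHM_TO_SIGMA / voxel_size_mm
    vol = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, truncate=4.0)
    return vol


def permutation_null_calibration(n_replicates=500, n_iter=1000, seed=0,
                                 alpha=0.05, fwhm_mm=6.0):
    """Rejection rate and p-values of the CCC permutation test under a
    true null: pairs of independent 6 mm-smooth maps on the default grid."""
    atlas = synth.make_atlas((14, 14, 12), n_parcels=10, rng_seed=seed)
    mask = atlas.gray_mask
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_replicates)
    for i in range(n_replicates):
        x = _smooth_null_map(mask.shape, mask, fwhm_mm, atlas.voxel_size_mm, rng)
        y = _smooth_null_map(mask.shape, mask, fwhm_mm, atlas.voxel_size_mm, rng)
        res = concordance.spatial_permutation_test(
            x, y, mask, n_iter=n_iter,
            rng_seed=int(rng.integers(2 ** 31)),
            voxel_size_mm=atlas.voxel_size_mm,
        )
        pvals[i] = res.p_value
    ks = stats.kstest(pvals, "uniform")
    return dict(rejection_rate=float(np.mean(pvals < alpha)), p_values=pvals,
                ks_p=float(ks.pvalue))


def coupled_effect_recovery(n_studies=100, n_iter=1000, seed=0, alpha=0.05):
    """Same-seed vs cross-seed concordance in the default coupled study.

    Variability maps are the log-transformed BF F maps (variance
    stabilized), group-difference maps the post-hoc t maps (blind -
    sighted), per seed (primary + control seed parcels). The primary
    same-seed CCC gets a spatial permutation p; cross-seed CCCs are merely
    recorded (they should center on zero).
    """
    same_ccc, same_p, cross_ccc = [], [], []
    for s in _child_seeds(seed, n_studies):
        spec = synth.SyntheticSpec(rng_seed=s)
        sessions, atlas, participants, truth = synth.simulate_study(spec)
        mask = atlas.gray_mask
        var_maps, diff_maps = {}, {}
        seeds = (spec.seed_parcel,) + spec.control_seed_parcels
        by_seed = rsfc.study_multiseed_maps(sessions, atlas, seeds)
        for sp in seeds:
            values, groups, cohorts = by_seed[sp]
            bf_F, _, _ = variability.brown_forsythe_map(values, groups)
            t, _, _ = variability.posthoc_ttest_map(values, groups)
            v3 = np.zeros(mask.shape); v3[mask] = np.log(bf_F + 1e-6)
            d3 = np.zeros(mask.shape); d3[mask] = t
            var_maps[sp], diff_maps[sp] = v3, d3
        spec_res = concordance.cross_seed_specificity(
            var_maps, diff_maps, mask, designated=spec.seed_parcel,
        )
        d = spec_res.seeds.index(spec.seed_parcel)
        off = ~np.eye(len(spec_res.seeds), dtype=bool)
        cross_ccc.extend(spec_res.ccc_matrix[off].tolist())
        perm = concordance.spatial_permutation_test(
            var_maps[spec.seed_parcel], diff_maps[spec.seed_parcel], mask,
            n_iter=n_iter, rng_seed=s, voxel_size_mm=atlas.voxel_size_mm,
        )
        same_ccc.append(perm.ccc)
        same_p.append(perm.p_value)
    same_ccc, same_p = np.array(same_ccc), np.array(same_p)
    return dict(
        mean_same_seed_ccc=float(same_ccc.mean()),
        positive_significant_rate=float(np.mean((same_ccc > 0) & (same_p < alpha))),
        mean_cross_seed_ccc=float(np.mean(cross_ccc)),
        same_seed_ccc=same_ccc, same_seed_p=same_p,
    )


# ---------------------------------------------------------------------------
# cluster correction


def fwe_calibration(n_studies=200, seed=0, voxel_p=DEFAULT_VOXEL_P, alpha=0.05,
                    n_mc_iter=2000):
    """Family-wise error of the full cluster-extent procedure on null studies.

    The BF p map of each null study is thresholded at ``voxel_p`` and
    cluster-corrected with a Monte Carlo minimum extent computed for the
    study's estimated map smoothness (thresholds cached per rounded FWHM).
    """
    cache = {}
    n_positive = 0
    child = _child_seeds(seed, n_studies)
    for i, s in enumerate(child):
        spec = null_spec(s, control_seed_parcels=())
        res = run_study_pipeline(spec)
        atlas = res["atlas"]
        mask = atlas.gray_mask
        values, groups = res["values"], res["groups"]
        _, p, _ = variability.brown_forsythe_map(values, groups)

        resid3 = np.zeros((len(values),) + mask.shape)
        resid3[:, mask] = values - values.mean(0)
        fwhm = clustercorr.estimate_smoothness(resid3, mask, atlas.voxel_size_mm,
                                               method="lag_ratio")
        key = round(fwhm * 2) / 2
        if key not in cache:
            cache[key] = clustercorr.monte_carlo_min_cluster(
                mask, key, voxel_p, alpha, n_mc_iter,
                rng_seed=_child_seeds(seed + 7, 1)[0] + len(cache),
                voxel_size_mm=atlas.voxel_size_mm,
            ).min_cluster_size_voxels
        p3 = np.ones(mask.shape)
        p3[mask] = p
        _, table = clustercorr.p_map_clusters(p3, voxel_p, cache[key], mask=mask)
        n_positive += int(len(table) > 0)
    return dict(fwe_rate=n_positive / n_studies, n_studies=n_studies, alpha=alpha)


def independent_voxel_check(seed=0, voxel_p=0.001, n_iter=20000, n_voxels=100):
    """fwhm = 0 on a scattered 100-voxel mask: the chance of any
    suprathreshold voxel must match the analytic binomial value."""
    shape = (12, 12, 12)
    rng = np.random.default_rng(seed)
    flat = rng.choice(np.prod(shape), size=n_voxels, replace=False)
    mask = np.zeros(np.prod(shape), bool)
    mask[flat] = True
    mask = mask.reshape(shape)
    thr = clustercorr.monte_carlo_min_cluster(mask, 0.0, voxel_p, 0.05, n_iter,
                                              rng_seed=seed)
    p_any = float(np.mean(thr.null_max_sizes >= 1))
    # in-mask z-scoring makes exceedances weakly dependent; the binomial
    # independence value is the reference
    analytic = 1.0 - (1.0 - voxel_p) ** n_voxels
    return dict(p_any_cluster=p_any, analytic=analytic,
                mean_max=float(thr.null_max_sizes.mean()))


# ---------------------------------------------------------------------------
# profiles


def clade_recovery(n_studies=100, seed=0, ari_threshold=0.9):
    """Recovery of three planted blind connectivity-profile subgroups, and
    the blind vs sighted mean-dissimilarity direction."""
    from sklearn.metrics import adjusted_rand_score

    aris, t_stats = [], []
    for s in _child_seeds(seed, n_studies):
        spec = synth.SyntheticSpec(rng_seed=s, n_clades=3)
        res = run_study_pipeline(spec)
        atlas, truth = res["atlas"], res["truth"]
        maps3 = np.full((len(res["values"]),) + atlas.gray_mask.shape, np.nan)
        maps3[:, atlas.gray_mask] = res["values"]
        prof = profiles.parcel_profiles(
            maps3, atlas.labels, excluded_labels=(spec.seed_parcel,),
            mask=atlas.gray_mask,
        )
        blind = res["groups"] == "blind"
        dres_b = profiles.hierarchical_cluster(prof[blind])
        labels = dres_b.cut(3)
        aris.append(adjusted_rand_score(res["truth"].true_clade_by_subject[blind], labels))
        dres_s = profiles.hierarchical_cluster(prof[~blind])
        cmp = profiles.compare_group_distances(dres_b.dissimilarity, dres_s.dissimilarity)
        t_stats.append(cmp["t"])
    aris = np.array(aris)
    t_stats = np.array(t_stats)
    return dict(recovery_rate=float(np.mean(aris > ari_threshold)),
                mean_ari=float(aris.mean()),
                blind_greater_rate=float(np.mean(t_stats > 0)),
                mean_t=float(t_stats.mean()))


def education_recovery(n_studies=40, seed=0, voxel_p=1e-4, alpha=0.05,
                       n_mc_iter=2000):
    """Education-slope recovery: the corrected blind-group correlation
    cluster must overlap the planted parcel; the sighted map must be empty."""
    overlap_hits, sighted_empty = 0, 0
    for s in _child_seeds(seed, n_studies):
        spec = synth.SyntheticSpec(rng_seed=s)
        res = run_study_pipeline(spec)
        atlas = res["atlas"]
        mask = atlas.gray_mask
        planted = np.isin(atlas.labels, spec.education_regions) & mask
        edu = res["participants"]["education_years"].to_numpy(float)
        for group, target in (("blind", "overlap"), ("sighted", "empty")):
            sel = res["groups"] == group
            cov = profiles.covariate_correlation(
                res["values"][sel], edu[sel], mask, atlas.voxel_size_mm,
                voxel_p=voxel_p, alpha=alpha, n_iter=n_mc_iter, rng_seed=s,
                null="permutation",
            )
            hit = (cov["clusters"] > 0) & planted
            if target == "overlap":
                overlap_hits += int(hit.any())
            else:
                sighted_empty += int(len(cov["table"]) == 0)
    return dict(overlap_rate=overlap_hits / n_studies,
                sighted_empty_rate=sighted_empty / n_studies,
                n_studies=n_studies)


# ---------------------------------------------------------------------------
# pipeline parity


def pipeline_parity(seed=0):
    """Global-signal and cell-demeaned variants of the default study.

    Checks that both variants run end to end, that demeaning collapses the
    group t map while leaving the pooled-within-cell S^2 maps unchanged,
    and that variance-difference detection survives both variants.
    """
    spec = synth.SyntheticSpec(rng_seed=seed)
    base = run_study_pipeline(spec)
    gsr = run_study_pipeline(synth.SyntheticSpec(rng_seed=seed), use_global=True)
    atlas = base["atlas"]
    planted = [e.region_id for e in spec.region_effects if e.sd_blind > e.sd_sighted]
    sel = np.isin(atlas.labels[atlas.gray_mask], planted)

    def bf_hit_rate(res):
        _, p, _ = variability.brown_forsythe_map(res["values"], res["groups"])
        return float(np.mean(p[sel] < 0.05))

    demeaned = rsfc.demean_by_subgroup(base["values"], base["groups"], base["cohorts"])

    def s2_pooled(values):
        s2b, s2s, _, _ = variability.group_variance_and_ratio(
            values, base["groups"], base["cohorts"], normalize_within_group=True,
        )
        return s2b, s2s

    s2b0, s2s0 = s2_pooled(base["values"])
    s2b1, s2s1 = s2_pooled(demeaned)
    t_base, _, _ = variability.posthoc_ttest_map(base["values"], base["groups"])
    t_dem, _, _ = variability.posthoc_ttest_map(demeaned, base["groups"])

    return dict(
        bf_power_base=bf_hit_rate(base),
        bf_power_gsr=bf_hit_rate(gsr),
        bf_power_demeaned=bf_hit_rate(dict(values=demeaned, groups=base["groups"])),
        s2_max_abs_change=float(max(np.max(np.abs(s2b1 - s2b0)),
                                    np.max(np.abs(s2s1 - s2s0)))),
        t_base_mean_abs_planted=float(np.mean(np.abs(t_base[sel]))),
        t_demeaned_max_abs=float(np.max(np.abs(t_dem))),
    )
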