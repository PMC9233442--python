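"""Subject connectivity fingerprints: parcel profiles, hierarchical
clustering into clades, clade mean maps, between-group dissimilarity
comparison, and voxelwise covariate correlation with cluster correction.

Dissimilarity between two subjects is 1 - Pearson r of their parcel
profiles; clades come from complete-linkage agglomeration of that
distance (merge heights are monotone for complete linkage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .clustercorr import estimate_smoothness, monte_carlo_min_cluster, threshold_and_label


@dataclass
class DendrogramResult:
    subjects: list
    dissimilarity: np.ndarray      # (n, n), 1 - Pearson r
    linkage_matrix: np.ndarray     # scipy (n-1, 4) merge list
    clades: dict                   # cut K -> labels (n,)

    def cut(self, k):
        labels = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        self.clades[k] = labels
        return labels


def parcel_profiles(maps, parcellation, excluded_labels=(), mask=None,
                    subjects=None):
    """Mean map value per parcel per subject.

    ``maps`` is (n_subjects,) + grid (or a list of 3D maps); columns are
    sorted parcel labels minus ``excluded_labels`` (the seed's own parcel
    and any neighbors to be ignored). Parcels empty after masking are
    dropped with a warning.
    """
    maps = np.asarray(maps, float)
    if maps.ndim == 3:
        maps = maps[None]
    parcellation = np.asarray(parcellation)
    keep = np.ones(parcellation.shape, bool) if mask is None else np.asarray(mask, bool)

    labels = [int(l) for l in np.unique(parcellation) if l > 0 and l not in set(excluded_labels)]
    cols = {}
    for lab in labels:
        sel = (parcellation == lab) & keep
        if not sel.any():
            warnings.warn(f"parcel {lab} empty after masking; column dropped")
            continue
        vals = maps[:, sel]
        cols[lab] = np.nanmean(vals, axis=1)
    index = subjects if subjects is not None else list(range(maps.shape[0]))
    return pd.DataFrame(cols, index=index)


def hierarchical_cluster(profiles) -> DendrogramResult:
    """Complete-linkage clustering on correlation distance (1 - Pearson r)."""
    if isinstance(profiles, pd.DataFrame):
        subjects = list(profiles.index)
        X = profiles.to_numpy(float)
    else:
        X = np.asarray(profiles, float)
        subjects = list(range(X.shape[0]))
    if X.shape[0] < 3:
        raise ValueError("need at least 3 subjects to cluster")
    sd = X.std(1)
    if np.any(sd == 0):
        bad = [subjects[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"zero-variance profile for subject(s) {bad}")

    R = np.corrcoef(X)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
    Z = linkage(squareform(D, checks=False), method="complete")
    return DendrogramResult(subjects=subjects, dissimilarity=D,
                            linkage_matrix=Z, clades={})


def clade_mean_maps(maps, clade_assignment):
    """Voxelwise mean map per clade."""
    maps = np.asarray(maps, float)
    clade_assignment = np.asarray(clade_assignment)
    out = {}
    for c in np.unique(clade_assignment):
        members = clade_assignment == c
        if not members.any():
            raise ValueError(f"clade {c} is empty")
        out[c] = maps[members].mean(0)
    return out


def compare_group_distances(dissimilarity_blind, dissimilarity_sighted):
    """Compare dissimilarity magnitude between groups (blind - sighted sign).

    Primary scheme: each subject's mean distance to own-group members,
    two-sample pooled t across subjects (independent units). Secondary
    scheme: naive t on the pooled lower-triangle entries, flagged for the
    non-independence of pairs.
    """
    def per_subject_means(D):
        D = np.asarray(D, float)
        n = D.shape[0]
        if D.shape != (n, n) or n < 3:
            raise ValueError("each group needs a square matrix of size >= 3")
        if not np.allclose(D, D.T, atol=1e-9) or not np.allclose(np.diag(D), 0, atol=1e-9):
            raise ValueError("dissimilarity matrix must be symmetric with zero diagonal")
        return (D.sum(1)) / (n - 1)

    mb = per_subject_means(dissimilarity_blind)
    ms = per_subject_means(dissimilarity_sighted)
    t, p = stats.ttest_ind(mb, ms, equal_var=True)
    df = len(mb) + len(ms) - 2

    tri_b = np.asarray(dissimilarity_blind)[np.tril_indices(len(mb), -1)]
    tri_s = np.asarray(dissimilarity_sighted)[np.tril_indices(len(ms), -1)]
    t2, p2 = stats.ttest_ind(tri_b, tri_s, equal_var=True)
    return {
        "t": float(t), "df": df, "p": float(p),
        "naive_t": float(t2), "naive_df": len(tri_b) + len(tri_s) - 2,
        "naive_p": float(p2), "naive_nonindependent_pairs": True,
        "mean_blind": float(mb.mean()), "mean_sighted": float(ms.mean()),
    }


def covariate_correlation_map(values, covariate):
    """Pearson r of each voxel's values with a scalar covariate, plus p."""
    values = np.asarray(values, float)
    cov = np.asarray(covariate, float)
    n = len(cov)
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if not np.all(np.isfinite(cov)) or cov.std() == 0:
        raise ValueError("covariate must be finite and nonconstant")
    xc = cov - cov.mean()
    yc = values - values.mean(0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (np.sqrt((xc ** 2).sum()) * np.sqrt((yc ** 2).sum(0)))
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p, df


def covariate_correlation(values, covariate, mask, voxel_size_mm,
                          voxel_p=0.005, alpha=0.05, n_iter=2000, rng_seed=0,
                          fwhm_mm=None, null="gaussian"):
    """Whole-brain covariate correlation with cluster-extent correction.

    ``values`` is (n_subjects, n_in_mask_voxels) for the selected group.
    Two nulls for the minimum cluster extent:

    - ``null='gaussian'``: Monte Carlo smooth Gaussian volumes at the
      map smoothness (estimated from the mean-removed subject maps unless
      ``fwhm_mm`` is given).
    - ``null='permutation'``: the covariate is permuted across subjects
      and the max suprathreshold cluster recorded per permutation. Exact
      for the maps' actual spatial dependence, including
      non-homogeneous-smoothness structure a single-FWHM Gaussian null
      cannot represent.

    Returns a dict with the r map (3D), p map, surviving cluster labels
    and table, and the threshold used.
    """
    mask = np.asarray(mask, bool)
    values = np.asarray(values, float)
    r, p, df = covariate_correlation_map(values, covariate)
    r3 = np.full(mask.shape, np.nan)
    r3[mask] = r
    tcrit = stats.t.isf(voxel_p / 2.0, df)
    rcrit = tcrit / np.sqrt(df + tcrit ** 2)

    if null == "permutation":
        from .clustercorr import ClusterThreshold, _max_cluster_size

        rng = np.random.default_rng(rng_seed)
        cov = np.asarray(covariate, float)
        vol = np.zeros(mask.shape)
        max_sizes = np.zeros(n_iter, int)
        for it in range(n_iter):
            rp, _, _ = covariate_correlation_map(values, rng.permutation(cov))
            vol[:] = 0.0
            vol[mask] = rp
            max_sizes[it] = max(_max_cluster_size((vol > rcrit) & mask),
                                _max_cluster_size((vol < -rcrit) & mask))
        counts = np.bincount(max_sizes)
        surv = (counts[::-1].cumsum()[::-1] + 1.0) / (n_iter + 1.0)
        k = 1
        while k < len(surv) and surv[k] > alpha:
            k += 1
        thr = ClusterThreshold(voxel_p, alpha, float("nan"), int(k), n_iter,
                               rng_seed, null_max_sizes=max_sizes)
    elif null == "gaussian":
        if fwhm_mm is None:
            resid = values - values.mean(0)
            resid3 = np.zeros((len(resid),) + mask.shape)
            resid3[:, mask] = resid
            fwhm_mm = estimate_smoothness(resid3, mask, voxel_size_mm,
                                          method="lag_ratio")
        thr = monte_carlo_min_cluster(mask, fwhm_mm, voxel_p, alpha, n_iter,
                                      rng_seed, voxel_size_mm)
    else:
        raise ValueError("null must be 'gaussian' or 'permutation'")

    labels, table = threshold_and_label(r3, rcrit, thr.min_cluster_size_voxels,
                                        mask=mask, two_sided=True)
    p3 = np.full(mask.shape, np.nan)
    p3[mask] = p
    return {"r_map": r3, "p_map": p3, "df": df, "clusters": labels,
            "table": table, "threshold": thr, "r_critical": float(rcrit)}


def roi_covariate_correlation(values, covariate, roi_index):
    """Mean-ROI covariate correlation: Pearson r and two-sided p."""
    roi_index = np.asarray(roi_index)
    if roi_index.dtype == bool and not roi_index.any():
        raise ValueError("ROI is empty")
    per_subject = np.asarray(values, float)[:, roi_index].mean(1)
    r, p = stats.pearsonr(per_subject, np.asarray(covariate, float))
    return float(r), float(p)
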