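"""Lin's concordance correlation between statistic maps and its
smoothness-matched spatial permutation null.

The CCC penalizes both decorrelation and mean/scale discrepancy:
CCC = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2), with
population (1/n) moments. Its significance against spatial maps is
assessed by shuffling one map's in-mask voxels, re-smoothing the shuffled
volume to the original map's estimated smoothness (restoring spatial
autocorrelation), rescaling to the original in-mask mean/SD, and
recomputing the CCC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .synth import FWHM_TO_SIGMA
from .clustercorr import estimate_smoothness

FISHER_CLIP = 1.0 - 1e-12


@dataclass
class CCCResult:
    ccc: float
    p_value: float
    n_iterations: int
    null_mean: float
    null_sd: float
    matched_fwhm_mm: float
    rng_seed: int
    smoothed_null: bool = True

    def __post_init__(self):
        if not (-1.0 - 1e-9 <= self.ccc <= 1.0 + 1e-9):
            raise ValueError("CCC outside [-1, 1]")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value outside (0, 1]")


@dataclass
class SeedSpecificityResult:
    seeds: list
    ccc_matrix: np.ndarray          # [variability seed i, group-diff seed j]
    fisher_z: np.ndarray
    designated: object
    t_vs_cross: float
    df_vs_cross: int
    p_vs_cross: float
    t_vs_other_same: float
    df_vs_other_same: int
    p_vs_other_same: float
    clipped: bool = False

    @property
    def same_seed_ccc(self):
        return dict(zip(self.seeds, np.diag(self.ccc_matrix)))


def lin_ccc(x, y):
    """Lin's concordance correlation coefficient (population moments)."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape or x.size < 3:
        raise ValueError("inputs must be equal-length with at least 3 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    vx, vy = x.var(), y.var()
    if vx == 0 and vy == 0:
        warnings.warn("both inputs have zero variance; CCC undefined")
        return np.nan
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).mean()
    return float(2.0 * cov / (vx + vy + (mx - my) ** 2))


def fisher_z(r):
    """atanh with clipping of |r| = 1 (flagged by the caller)."""
    return np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))


def _null_ccc_stream(x_map, y_vals, mask, n_iter, rng, sigma_vox):
    """Yield CCC values between permuted-and-resmoothed x and y."""
    xv = x_map[mask]
    target_mean, target_sd = xv.mean(), xv.std()
    vol = np.zeros(x_map.shape)
    if sigma_vox > 0:
        den = ndimage.gaussian_filter(mask.astype(float), sigma_vox, truncate=4.0)
        den = np.where(den > 1e-12, den, np.nan)
    for _ in range(n_iter):
        vol[:] = 0.0
        vol[mask] = rng.permutation(xv)
        if sigma_vox > 0:
            sm = ndimage.gaussian_filter(vol, sigma_vox, truncate=4.0) / den
            nv = sm[mask]
        else:
            nv = vol[mask]
        sd = nv.std()
        if sd > 0:
            nv = (nv - nv.mean()) / sd * target_sd + target_mean
        yield lin_ccc(nv, y_vals)


def spatial_permutation_test(map_x, map_y, mask, n_iter=10000, rng_seed=0,
                             voxel_size_mm=3.0, fwhm_mm=None):
    """Permutation test of the CCC between two maps, preserving smoothness.

    The null shuffles ``map_x``'s in-mask values, convolves with a Gaussian
    whose FWHM matches the estimated smoothness of the original ``map_x``
    (mask-renormalized so border variance is unbiased), and rescales to the
    original in-mask mean/SD. Two-sided p with the +1 correction.
    """
    mask = np.asarray(mask, bool)
    n_mask = int(mask.sum())
    if n_mask < 100:
        warnings.warn(f"mask has only {n_mask} voxels; permutation null is coarse")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    map_x = np.asarray(map_x, float)
    map_y = np.asarray(map_y, float)
    xv, yv = map_x[mask], map_y[mask]
    observed = lin_ccc(xv, yv)

    smoothed = True
    if fwhm_mm is None:
        try:
            fwhm_mm = estimate_smoothness(map_x, mask, voxel_size_mm)
        except ValueError:
            warnings.warn("smoothness estimation failed; unsmoothed permutation null")
            fwhm_mm = 0.0
            smoothed = False
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm if fwhm_mm > 0 else 0.0

    rng = np.random.default_rng(rng_seed)
    null = np.fromiter(
        _null_ccc_stream(map_x, yv, mask, n_iter, rng, sigma_vox),
        dtype=float, count=n_iter,
    )
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (n_iter + 1.0)
    return CCCResult(
        ccc=observed, p_value=float(p), n_iterations=n_iter,
        null_mean=float(null.mean()), null_sd=float(null.std()),
        matched_fwhm_mm=float(fwhm_mm), rng_seed=rng_seed, smoothed_null=smoothed,
    )


def cross_seed_specificity(variability_maps_by_seed, groupdiff_maps_by_seed,
                           mask, designated=None):
    """CCC for every (variability seed i, group-diff seed j) pair.

    The diagonal holds same-seed concordances. After Fisher z transform,
    the designated seed's same-seed value is compared (a) against the
    distribution of cross-seed z values and (b) against the other seeds'
    same-seed z values, each by a one-sample-style t on the comparison
    distribution.
    """
    seeds = list(variability_maps_by_seed)
    if len(seeds) < 3:
        raise ValueError("need at least 3 seeds")
    if set(seeds) != set(groupdiff_maps_by_seed):
        raise ValueError("seed sets of the two map collections differ")
    if designated is None:
        designated = seeds[0]
    mask = np.asarray(mask, bool)

    k = len(seeds)
    ccc = np.empty((k, k))
    for i, si in enumerate(seeds):
        xv = np.asarray(variability_maps_by_seed[si], float)[mask]
        for j, sj in enumerate(seeds):
            ccc[i, j] = lin_ccc(xv, np.asarray(groupdiff_maps_by_seed[sj], float)[mask])

    clipped = bool(np.any(np.abs(ccc) >= 1.0))
    if clipped:
        warnings.warn("|CCC| = 1 encountered; Fisher z clipped")
    z = fisher_z(ccc)
    d = seeds.index(designated)
    z_same = z[d, d]
    off = ~np.eye(k, dtype=bool)
    z_cross = z[off]
    z_other = np.diag(z)[np.arange(k) != d]

    def one_sample(value, sample):
        sample = np.asarray(sample, float)
        m, s, n = sample.mean(), sample.std(ddof=1), len(sample)
        t = (value - m) / (s / np.sqrt(n)) if s > 0 else np.inf * np.sign(value - m)
        df = n - 1
        return float(t), df, float(2.0 * stats.t.sf(abs(t), df))

    t1, df1, p1 = one_sample(z_same, z_cross)
    t2, df2, p2 = one_sample(z_same, z_other)
    return SeedSpecificityResult(
        seeds=seeds, ccc_matrix=ccc, fisher_z=z, designated=designated,
        t_vs_cross=t1, df_vs_cross=df1, p_vs_cross=p1,
        t_vs_other_same=t2, df_vs_other_same=df2, p_vs_other_same=p2,
        clipped=clipped,
    )
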