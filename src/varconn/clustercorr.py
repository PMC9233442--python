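"""Monte Carlo cluster-extent multiple-comparison correction.

The family-wise error over a mask is controlled by simulating smooth null
volumes, thresholding them voxelwise, and recording the largest connected
suprathreshold cluster per iteration; the minimum surviving cluster extent
is the smallest size whose null exceedance probability is <= alpha.
Smoothness of real maps is estimated with the classic first-difference
variance-ratio estimator (Gaussian autocorrelation model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .synth import FWHM_TO_SIGMA

_FACES = ndimage.generate_binary_structure(3, 1)  # 6-neighborhood


@dataclass
class ClusterThreshold:
    voxel_p: float
    alpha: float
    estimated_fwhm_mm: float
    min_cluster_size_voxels: int
    n_iterations: int
    rng_seed: int
    null_max_sizes: np.ndarray = None

    def __post_init__(self):
        if self.min_cluster_size_voxels < 1:
            raise ValueError("minimum cluster size must be >= 1")


def _lag_var(maps, mask, ax, lag):
    """Pooled variance of in-mask value differences at ``lag`` along ``ax``."""
    shifted = np.roll(mask, -lag, axis=ax)
    edge = [slice(None)] * 3
    edge[ax] = slice(-lag, None)
    pair = mask & shifted
    pair[tuple(edge)] = False
    if not pair.any():
        return None, None
    diffs, vals = [], []
    for m in maps:
        a = m[pair]
        b = np.roll(m, -lag, axis=ax)[pair]
        diffs.append(b - a)
        vals.append(a)
        vals.append(b)
    return np.nanvar(np.concatenate(diffs)), np.nanvar(np.concatenate(vals))


def estimate_smoothness(maps, mask, voxel_size_mm, method="variance_ratio"):
    """Estimate spatial smoothness (FWHM, mm) from one or more maps.

    ``method='variance_ratio'`` is the classic first-difference estimator
    under a Gaussian autocorrelation model: rho = 1 - var(dx) / (2 var),
    FWHM_axis = 2.3548 * voxel * sqrt(-1 / (4 ln rho)).

    ``method='lag_ratio'`` solves the Gaussian ACF from the ratio of
    lag-2 to lag-1 difference variances, (1 - rho^4') / (1 - rho'):
    because the total map variance never enters, it is robust to
    piecewise-constant regional structure superimposed on a smooth noise
    field (which inflates the denominator of the classic estimator).

    Axes are combined by geometric mean; near-zero neighbor correlation
    returns the voxel-size floor with a warning.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    maps = np.asarray(maps, float)
    if maps.ndim == 3:
        maps = maps[None]
    vals = maps[:, mask]
    if np.nanstd(vals) == 0:
        raise ValueError("constant map: smoothness undefined (zero variance)")

    fwhms = []
    for ax in range(3):
        v1, den = _lag_var(maps, mask, ax, 1)
        if v1 is None or den is None or den <= 0 or v1 <= 0:
            continue
        if method == "variance_ratio":
            rho = 1.0 - v1 / (2.0 * den)
            if rho <= 0.05:
                fwhms.append(voxel_size_mm)
                continue
            sigma_vox = np.sqrt(-1.0 / (4.0 * np.log(rho)))
        elif method == "lag_ratio":
            v2, _ = _lag_var(maps, mask, ax, 2)
            if v2 is None or v2 <= 0:
                continue
            # v_lag = 2 sigma_n^2 (1 - exp(-lag^2 a)), a = 1/(4 sigma_k^2)
            ratio = v2 / v1
            if ratio >= 3.9:        # effectively unsmoothed
                fwhms.append(voxel_size_mm)
                continue
            ratio = max(ratio, 1.0 + 1e-6)
            from scipy.optimize import brentq

            a = brentq(lambda t: (1 - np.exp(-4 * t)) / (1 - np.exp(-t)) - ratio,
                       1e-8, 50.0)
            sigma_vox = np.sqrt(1.0 / (4.0 * a))
        else:
            raise ValueError("method must be 'variance_ratio' or 'lag_ratio'")
        fwhms.append(sigma_vox / FWHM_TO_SIGMA * voxel_size_mm)
    if not fwhms:
        warnings.warn("smoothness not estimable; returning voxel-size floor")
        return float(voxel_size_mm)
    fwhm = float(np.exp(np.mean(np.log(fwhms))))
    if fwhm <= voxel_size_mm * 1.0001:
        warnings.warn("near-zero neighbor correlation; voxel-size floor returned")
    return max(fwhm, float(voxel_size_mm))


def _max_cluster_size(binary):
    if not binary.any():
        return 0
    lab, n = ndimage.label(binary, structure=_FACES)
    if n == 0:
        return 0
    return int(np.bincount(lab.ravel())[1:].max())


def monte_carlo_min_cluster(mask, fwhm_mm, voxel_p, alpha, n_iter, rng_seed,
                            voxel_size_mm=3.0):
    """Monte Carlo null distribution of the largest suprathreshold cluster.

    Each iteration: white Gaussian volume -> smooth to ``fwhm_mm`` ->
    z-score in-mask -> two-sided threshold at ``voxel_p`` (clusters formed
    separately per sign) -> record the largest cluster. The minimum extent
    is the smallest k with P(max cluster >= k) <= alpha.
    """
    if not (0 < voxel_p < 1 and 0 < alpha < 1):
        raise ValueError("voxel_p and alpha must be in (0, 1)")
    if alpha < 1.0 / n_iter:
        raise ValueError(f"alpha={alpha} below the 1/{n_iter} Monte Carlo resolution")
    mask = np.asarray(mask, bool)
    rng = np.random.default_rng(rng_seed)
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm if fwhm_mm > 0 else 0.0
    zthr = stats.norm.isf(voxel_p / 2.0)

    max_sizes = np.zeros(n_iter, int)
    vol = np.zeros(mask.shape)
    for it in range(n_iter):
        noise = rng.standard_normal(mask.shape)
        if sigma > 0:
            noise = ndimage.gaussian_filter(noise, sigma, truncate=4.0)
        v = noise[mask]
        z = (v - v.mean()) / v.std()
        vol[:] = 0.0
        vol[mask] = z
        m = max(_max_cluster_size((vol > zthr) & mask),
                _max_cluster_size((vol < -zthr) & mask))
        max_sizes[it] = m

    # survival function of the max-cluster distribution, with the +1
    # finite-sampling correction so the selected extent is conservative
    counts = np.bincount(max_sizes)
    surv = (counts[::-1].cumsum()[::-1] + 1.0) / (n_iter + 1.0)
    k = 1
    while k < len(surv) and surv[k] > alpha:
        k += 1
    return ClusterThreshold(voxel_p, alpha, float(fwhm_mm), int(k), n_iter,
                            rng_seed, null_max_sizes=max_sizes)


def threshold_and_label(stat_map, threshold, min_cluster_size, mask=None,
                        two_sided=True):
    """Connected components (6-adjacency) of suprathreshold voxels >= k.

    ``threshold`` is on the statistic's own scale (convert from a p-value
    with the statistic's df before calling). Returns (labels, table):
    labels > 0 for surviving clusters; the table lists size, sign, peak
    value and peak voxel index per cluster.
    """
    stat_map = np.asarray(stat_map, float)
    if mask is None:
        mask = np.isfinite(stat_map)
    mask = np.asarray(mask, bool) & np.isfinite(stat_map)

    out = np.zeros(stat_map.shape, np.int32)
    rows = []
    next_label = 0
    signs = [1, -1] if two_sided else [1]
    for sign in signs:
        supra = (sign * stat_map > threshold) & mask
        lab, n = ndimage.label(supra, structure=_FACES)
        for i in range(1, n + 1):
            comp = lab == i
            size = int(comp.sum())
            if size < min_cluster_size:
                continue
            next_label += 1
            out[comp] = next_label
            vals = np.where(comp, stat_map, np.nan)
            peak_flat = np.nanargmax(sign * vals)
            peak = np.unravel_index(peak_flat, stat_map.shape)
            rows.append(dict(cluster=next_label, sign=sign, size=size,
                             peak_value=float(stat_map[peak]),
                             peak_x=int(peak[0]), peak_y=int(peak[1]),
                             peak_z=int(peak[2])))
    table = pd.DataFrame(rows, columns=["cluster", "sign", "size", "peak_value",
                                        "peak_x", "peak_y", "peak_z"])
    return out, table


def p_map_clusters(p_map, voxel_p, min_cluster_size, mask=None):
    """Cluster-extent correction of a one-sided p map (e.g. Brown-Forsythe)."""
    p_map = np.asarray(p_map, float)
    score = -np.log10(np.maximum(p_map, np.finfo(float).tiny))
    return threshold_and_label(score, -np.log10(voxel_p), min_cluster_size,
                               mask=mask, two_sided=False)
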