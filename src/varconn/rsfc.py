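"""Per-subject seed-RSFC mapping: bandpass, nuisance regression, seed GLM,
smoothing, and the two map-level normalizations used by the group analyses.

The per-subject output is a 3D map of the seed predictor's GLM statistic
(t by default, beta retained alongside). All voxelwise math is vectorized
over the in-mask voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy.ndimage import gaussian_filter

from .synth import FWHM_TO_SIGMA, ScanSession, Atlas

N_DROP_INITIAL = 2  # non-steady-state volumes excluded before filtering


@dataclass
class ConnectivityMap:
    """One subject's 3D seed-connectivity statistic map."""

    subject_id: str
    seed: str
    kind: str                  # "t" or "beta"
    data: np.ndarray           # 3D, NaN outside mask
    mask: np.ndarray           # bool
    smoothing_fwhm_mm: float = 0.0
    standardized: bool = False

    def __post_init__(self):
        if self.kind not in ("t", "beta"):
            raise ValueError("statistic kind must be 't' or 'beta'")
        vals = self.data[self.mask]
        if not np.all(np.isfinite(vals)):
            n_bad = int((~np.isfinite(vals)).sum())
            warnings.warn(f"{n_bad} non-finite in-mask voxels in map {self.subject_id}")


def zscore(x, axis=-1):
    x = np.asarray(x, float)
    m = x.mean(axis=axis, keepdims=True)
    s = x.std(axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (x - m) / s


def extract_seed_timecourse(bold, seed_mask):
    """Spatial mean over the seed per timepoint, z-transformed."""
    seed_mask = np.asarray(seed_mask, bool)
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    ts = bold[seed_mask].mean(axis=0).astype(float)
    sd = ts.std()
    if sd == 0:
        raise ValueError("seed time course has zero variance")
    return (ts - ts.mean()) / sd


def bandpass_response(n_t, tr, low_hz=0.01, high_hz=0.1, transition_hz=0.005):
    """Frequency response of the zero-phase filter (raised-cosine transitions)."""
    f = np.fft.rfftfreq(n_t, tr)
    tw = transition_hz

    def ramp_up(edge):
        r = np.clip((f - (edge - tw / 2)) / tw, 0.0, 1.0)
        return 0.5 - 0.5 * np.cos(np.pi * r)

    resp = ramp_up(low_hz) * (1.0 - ramp_up(high_hz))
    resp[f == 0] = 0.0
    return f, resp


def bandpass(data, tr, low_hz=0.01, high_hz=0.1, axis=-1, transition_hz=0.005):
    """Zero-phase frequency-domain bandpass (default 0.01-0.1 Hz)."""
    data = np.asarray(data)
    n_t = data.shape[axis]
    nyquist = 0.5 / tr
    if not (0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"invalid band [{low_hz}, {high_hz}] Hz for TR {tr} s (Nyquist {nyquist:.3g} Hz)"
        )
    _, resp = bandpass_response(n_t, tr, low_hz, high_hz, transition_hz)
    shape = [1] * data.ndim
    shape[axis] = len(resp)
    spec = sp_fft.rfft(data, axis=axis)
    spec *= resp.reshape(shape)
    return sp_fft.irfft(spec, n=n_t, axis=axis)


def build_nuisance_design(session: ScanSession, wm_mask, ventricle_mask,
                          use_global=False, brain_mask=None, bold=None,
                          motion=None):
    """Nuisance design: 6 motion + 6 backward-difference derivatives +
    WM mean + ventricle mean + intercept (+ global mean when flagged).

    Non-intercept columns are z-scored; all-zero (degenerate) columns are
    kept as zeros and reported. ``bold``/``motion`` override the session's
    arrays (e.g. after dropping initial volumes and filtering).
    """
    bold = session.bold if bold is None else bold
    motion = session.motion if motion is None else np.asarray(motion, float)
    n_t = bold.shape[-1]
    if motion.shape[0] != n_t:
        raise ValueError(
            f"motion table has {motion.shape[0]} rows but data has {n_t} timepoints"
        )
    if not np.asarray(wm_mask, bool).any() or not np.asarray(ventricle_mask, bool).any():
        raise ValueError("tissue masks must be nonempty")

    deriv = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    cols = [motion, deriv, bold[np.asarray(wm_mask, bool)].mean(0)[:, None],
            bold[np.asarray(ventricle_mask, bool)].mean(0)[:, None]]
    if use_global:
        gmask = np.asarray(brain_mask, bool) if brain_mask is not None else np.ones(bold.shape[:3], bool)
        cols.append(bold[gmask].mean(0)[:, None])
    X = np.hstack(cols).astype(float)

    sd = X.std(0)
    degenerate = sd == 0
    X = X - X.mean(0)
    X[:, ~degenerate] /= sd[~degenerate]
    X = np.hstack([X, np.ones((n_t, 1))])
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} degenerate (constant) nuisance columns")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient nuisance design; pseudoinverse solution used")
    return X


def seed_glm_map(bold, seed_series, nuisance_design, mask, subject_id="sub",
                 seed="seed"):
    """Voxelwise OLS of the z-scored voxel series on [seed | nuisance].

    Returns (t_map, beta_map, df) as ConnectivityMap pair for the seed
    predictor. Degenerate (zero-variance) voxel series map to NaN.
    """
    mask = np.asarray(mask, bool)
    n_t = bold.shape[-1]
    seed_series = np.asarray(seed_series, float)
    if seed_series.shape[0] != n_t or nuisance_design.shape[0] != n_t:
        raise ValueError("timepoint counts of data, seed and design differ")

    Y = np.asarray(bold[mask], float)               # (m, T)
    sd = Y.std(1)
    good = sd > 0
    Yz = np.full_like(Y, np.nan)
    Yz[good] = (Y[good] - Y[good].mean(1, keepdims=True)) / sd[good, None]

    X = np.column_stack([zscore(seed_series), nuisance_design])
    p = X.shape[1]
    pinv = np.linalg.pinv(X)
    beta = pinv @ Yz[good].T                        # (p, m_good)
    resid = Yz[good].T - X @ beta
    dof = n_t - np.linalg.matrix_rank(X)
    sigma2 = (resid ** 2).sum(0) / dof
    xtx_inv00 = (pinv @ pinv.T)[0, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[0] / np.sqrt(sigma2 * xtx_inv00)

    def to_map(values, kind):
        out = np.full(mask.shape, np.nan)
        flat = np.full(int(mask.sum()), np.nan)
        flat[good] = values
        out[mask] = flat
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return ConnectivityMap(subject_id, seed, kind, out, mask)

    n_bad = int((~good).sum())
    if n_bad:
        warnings.warn(f"{n_bad} degenerate voxel series set to NaN")
    return to_map(t, "t"), to_map(beta[0], "beta"), dof


def smooth_map(data, fwhm_mm, voxel_size_mm, mask=None):
    """Gaussian smoothing in mm with in-mask renormalization at borders."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm_mm == 0:
        return np.array(data, float, copy=True)
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    data = np.asarray(data, float)
    if mask is None:
        mask = np.isfinite(data)
    mask = np.asarray(mask, bool) & np.isfinite(data)
    filled = np.where(mask, data, 0.0)
    num = gaussian_filter(filled, sigma, truncate=4.0)
    den = gaussian_filter(mask.astype(float), sigma, truncate=4.0)
    out = np.full(data.shape, np.nan)
    nz = den > 1e-12
    out[nz & mask] = num[nz & mask] / den[nz & mask]
    return out


def site_standardize(values, cohort_labels=None):
    """Per-subject z-normalization of each map across in-mask voxels.

    ``values`` is (n_subjects, n_voxels). Removes per-cohort affine
    scale/offset site effects by construction (each map ends mean 0, SD 1).
    """
    values = np.asarray(values, float)
    if cohort_labels is not None:
        cohort_labels = np.asarray(cohort_labels)
        for c in np.unique(cohort_labels):
            if (cohort_labels == c).sum() < 2:
                raise ValueError(f"cohort {c!r} has fewer than 2 subjects")
    sd = values.std(1)
    if np.any(sd == 0):
        bad = np.where(sd == 0)[0]
        raise ValueError(f"zero-SD map(s) at subject index {bad.tolist()}")
    return (values - values.mean(1, keepdims=True)) / sd[:, None]


def site_standardize_voxelwise(values, cohort_labels):
    """Per-voxel z-normalization across subjects within each cohort.

    The alternative reading of post hoc site standardization, and the one
    used by the group pipeline: every voxel is centered and scaled by the
    pooled (both groups) mean/SD of its cohort, so cohort-level affine site
    effects vanish while between-subject variance ratios at each voxel are
    exactly preserved -- the property the variance-homogeneity analyses
    depend on.
    """
    values = np.asarray(values, float)
    cohort_labels = np.asarray(cohort_labels)
    out = np.empty_like(values)
    for c in np.unique(cohort_labels):
        sel = cohort_labels == c
        if sel.sum() < 2:
            raise ValueError(f"cohort {c!r} has fewer than 2 subjects")
        x = values[sel]
        sd = x.std(0, ddof=0)
        if np.any(sd == 0):
            raise ValueError(f"zero-variance voxel(s) within cohort {c!r}")
        out[sel] = (x - x.mean(0)) / sd
    return out


def demean_by_subgroup(values, group_labels, cohort_labels):
    """Remove the voxelwise mean of each group x cohort cell."""
    values = np.array(values, float, copy=True)
    group_labels = np.asarray(group_labels)
    cohort_labels = np.asarray(cohort_labels)
    for g in np.unique(group_labels):
        for c in np.unique(cohort_labels):
            cell = (group_labels == g) & (cohort_labels == c)
            if cell.sum() == 1:
                raise ValueError(f"singleton cell {g}/{c}; cannot demean")
            if cell.any():
                values[cell] -= values[cell].mean(0)
    return values


# ---------------------------------------------------------------------------
# pipeline drivers


def subject_connectivity_map(session: ScanSession, atlas: Atlas, *,
                             seed_mask=None, low_hz=0.01, high_hz=0.1,
                             use_global=False, smoothing_fwhm_mm=6.0,
                             stats=("t", "beta")):
    """Full per-subject pipeline: drop initial volumes, bandpass, extract the
    seed, nuisance-regress, fit the seed GLM, smooth. Returns a dict of 3D
    maps (NaN outside gray matter) for the requested statistics."""
    seed_mask = atlas.seed_mask if seed_mask is None else np.asarray(seed_mask, bool)
    bold = session.bold[..., N_DROP_INITIAL:]
    motion = session.motion[N_DROP_INITIAL:]

    brain = atlas.brain_mask
    filt = np.zeros(bold.shape, np.float32)
    filt[brain] = bandpass(bold[brain], session.tr, low_hz, high_hz)

    seed_series = extract_seed_timecourse(filt, seed_mask)
    design = build_nuisance_design(
        session, atlas.wm_mask, atlas.ventricle_mask, use_global=use_global,
        brain_mask=brain, bold=filt, motion=motion,
    )
    tmap, bmap, _ = seed_glm_map(
        filt, seed_series, design, atlas.gray_mask, subject_id=session.subject_id
    )
    out = {}
    for kind, m in (("t", tmap), ("beta", bmap)):
        if kind in stats:
            out[kind] = smooth_map(m.data, smoothing_fwhm_mm, atlas.voxel_size_mm,
                                   atlas.gray_mask)
    return out


def study_multiseed_maps(sessions, atlas, seed_parcels, *, stat="t",
                         use_global=False, smoothing_fwhm_mm=6.0,
                         low_hz=0.01, high_hz=0.1, standardize="voxelwise"):
    """Seed-RSFC map matrices for several seed parcels in one pass.

    Filtering and the nuisance design are computed once per subject; only
    the seed extraction and GLM differ between seeds. Returns a dict
    {parcel label: (values, groups, cohorts)} like study_connectivity_maps.
    """
    gray = atlas.gray_mask
    brain = atlas.brain_mask
    out = {p: np.empty((len(sessions), int(gray.sum()))) for p in seed_parcels}
    for i, ses in enumerate(sessions):
        bold = ses.bold[..., N_DROP_INITIAL:]
        motion = ses.motion[N_DROP_INITIAL:]
        filt = np.zeros(bold.shape, np.float32)
        filt[brain] = bandpass(bold[brain], ses.tr, low_hz, high_hz)
        design = build_nuisance_design(
            ses, atlas.wm_mask, atlas.ventricle_mask, use_global=use_global,
            brain_mask=brain, bold=filt, motion=motion,
        )
        for p in seed_parcels:
            seed_series = extract_seed_timecourse(filt, atlas.labels == p)
            tmap, bmap, _ = seed_glm_map(filt, seed_series, design, gray,
                                         subject_id=ses.subject_id, seed=str(p))
            m = (tmap if stat == "t" else bmap).data
            out[p][i] = smooth_map(m, smoothing_fwhm_mm, atlas.voxel_size_mm, gray)[gray]
    groups = np.array([s.group for s in sessions])
    cohorts = np.array([s.cohort for s in sessions])
    result = {}
    for p in seed_parcels:
        values = out[p]
        if standardize == "voxelwise":
            values = site_standardize_voxelwise(values, cohorts)
        elif standardize == "subject":
            values = site_standardize(values, cohorts)
        result[p] = (values, groups, cohorts)
    return result


def study_connectivity_maps(sessions, atlas, *, seed_mask=None, stat="t",
                            use_global=False, smoothing_fwhm_mm=6.0,
                            low_hz=0.01, high_hz=0.1, standardize="voxelwise"):
    """Run the per-subject pipeline for every session.

    Returns (values, group_labels, cohort_labels) where ``values`` is the
    (n_subjects, n_gray_voxels) matrix of maps. ``standardize`` selects the
    site-effect normalization: "voxelwise" (per voxel across subjects
    within cohort; the default), "subject" (per-subject z across voxels),
    or None.
    """
    if stat not in ("t", "beta"):
        raise ValueError("stat must be 't' or 'beta'")
    gray = atlas.gray_mask
    values = np.empty((len(sessions), int(gray.sum())))
    for i, ses in enumerate(sessions):
        maps = subject_connectivity_map(
            ses, atlas, seed_mask=seed_mask, low_hz=low_hz, high_hz=high_hz,
            use_global=use_global, smoothing_fwhm_mm=smoothing_fwhm_mm,
            stats=(stat,),
        )
        values[i] = maps[stat][gray]
    groups = np.array([s.group for s in sessions])
    cohorts = np.array([s.cohort for s in sessions])
    if standardize == "voxelwise":
        values = site_standardize_voxelwise(values, cohorts)
    elif standardize == "subject":
        values = site_standardize(values, cohorts)
    elif standardize not in (None, False):
        raise ValueError("standardize must be 'voxelwise', 'subject' or None")
    return values, groups, cohorts
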