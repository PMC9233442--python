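"""Voxelwise and ROI-level group statistics.

All functions operate on a ``values`` matrix of shape (n_subjects,
n_voxels) -- the stacked in-mask subject maps -- plus label vectors, and
are fully vectorized over voxels. The central piece is the Brown-Forsythe
variance-homogeneity map: a one-way ANOVA on absolute deviations from the
group medians, robust to skewed data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class GroupStatMaps:
    """Voxelwise group statistics sharing one grid/mask."""

    F_group: np.ndarray
    F_cohort: np.ndarray
    F_interaction: np.ndarray
    df_anova: tuple          # (df_effect, df_residual)
    t_group: np.ndarray
    df_t: int
    BF_F: np.ndarray
    BF_p: np.ndarray
    S2_blind: np.ndarray
    S2_sighted: np.ndarray
    ratio: np.ndarray


def _check_groups(group_labels):
    group_labels = np.asarray(group_labels)
    blind = group_labels == "blind"
    sighted = group_labels == "sighted"
    if blind.sum() < 2 or sighted.sum() < 2:
        raise ValueError("both groups need at least 2 subjects")
    return blind, sighted


def anova_2x2_map(values, group_labels, cohort_labels):
    """Unbalanced two-way fixed-effects ANOVA per voxel via effect coding.

    Type-III style tests: each effect's F compares the full effect-coded
    model [1, g, c, g*c] against the model without that column. Returns a
    dict with F and p maps for group, cohort and interaction plus dfs.
    """
    values = np.asarray(values, float)
    group_labels = np.asarray(group_labels)
    cohort_labels = np.asarray(cohort_labels)
    n = values.shape[0]
    for g in ("blind", "sighted"):
        for c in ("A", "B"):
            if not ((group_labels == g) & (cohort_labels == c)).any():
                raise ValueError(f"empty cell {g}/{c}")

    g = np.where(group_labels == "blind", 1.0, -1.0)
    c = np.where(cohort_labels == "A", 1.0, -1.0)
    X = np.column_stack([np.ones(n), g, c, g * c])

    def rss(design):
        coef, *_ = np.linalg.lstsq(design, values, rcond=None)
        r = values - design @ coef
        return (r ** 2).sum(0)

    rss_full = rss(X)
    df_resid = n - 4
    mse = rss_full / df_resid
    out = {}
    for name, col in (("group", 1), ("cohort", 2), ("interaction", 3)):
        reduced = np.delete(X, col, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            F = (rss(reduced) - rss_full) / mse
        F = np.where(mse > np.finfo(float).eps * np.abs(values).max() ** 2, F, np.nan)
        out[f"F_{name}"] = F
        out[f"p_{name}"] = stats.f.sf(F, 1, df_resid)
    out["df"] = (1, df_resid)
    return out


def posthoc_ttest_map(values, group_labels):
    """Two-sample pooled-variance t per voxel, sign convention blind - sighted."""
    blind, sighted = _check_groups(group_labels)
    values = np.asarray(values, float)
    nb, ns = int(blind.sum()), int(sighted.sum())
    mb = values[blind].mean(0)
    ms = values[sighted].mean(0)
    sp2 = ((nb - 1) * values[blind].var(0, ddof=1)
           + (ns - 1) * values[sighted].var(0, ddof=1)) / (nb + ns - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mb - ms) / np.sqrt(sp2 * (1.0 / nb + 1.0 / ns))
    t = np.where(sp2 > 0, t, np.nan)
    df = nb + ns - 2
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, df, p


def brown_forsythe_map(values, group_labels):
    """Brown-Forsythe equal-variance test per voxel.

    z_ij = |x_ij - median(group j)|; F is the one-way ANOVA F on z across
    the two groups with df (1, n_b + n_s - 2). A constant group contributes
    zero deviations (F = 0 path, not an error).
    """
    blind, sighted = _check_groups(group_labels)
    values = np.asarray(values, float)
    nb, ns = int(blind.sum()), int(sighted.sum())
    n = nb + ns

    zb = np.abs(values[blind] - np.median(values[blind], axis=0))
    zs = np.abs(values[sighted] - np.median(values[sighted], axis=0))
    mb, ms = zb.mean(0), zs.mean(0)
    grand = (zb.sum(0) + zs.sum(0)) / n
    ssb = nb * (mb - grand) ** 2 + ns * (ms - grand) ** 2
    ssw = ((zb - mb) ** 2).sum(0) + ((zs - ms) ** 2).sum(0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        F = ssb / (ssw / df)
    F = np.where(ssw > 0, F, np.where(ssb > 0, np.inf, 0.0))
    p = stats.f.sf(F, 1, df)
    return F, p, (1, df)


def group_variance_and_ratio(values, group_labels, cohort_labels=None,
                             normalize_within_group=False, sig_mask=None,
                             display_threshold=3.0):
    """Per-group unbiased variance maps and their blind/sighted ratio.

    With ``normalize_within_group`` (requires ``cohort_labels``), each
    group's variance is the pooled within-cohort-cell variance, removing
    cohort effects on the group mean before measuring spread. The ratio is
    reported only where ``sig_mask`` (e.g. a corrected Brown-Forsythe
    significance mask) is True; ``display_threshold`` is carried along for
    presentation (ratio > 3 in the emulated study's figures).
    """
    blind, sighted = _check_groups(group_labels)
    values = np.asarray(values, float)

    def group_s2(sel):
        x = values[sel]
        if normalize_within_group:
            if cohort_labels is None:
                raise ValueError("normalize_within_group requires cohort_labels")
            co = np.asarray(cohort_labels)[sel]
            ss = np.zeros(values.shape[1])
            dof = 0
            for c in np.unique(co):
                cell = x[co == c]
                ss += ((cell - cell.mean(0)) ** 2).sum(0)
                dof += len(cell) - 1
            return ss / dof
        return x.var(0, ddof=1)

    s2b = group_s2(blind)
    s2s = group_s2(sighted)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(s2s > 0, s2b / s2s, np.nan)
    if sig_mask is not None:
        ratio = np.where(np.asarray(sig_mask, bool), ratio, np.nan)
    return s2b, s2s, ratio, display_threshold


def roi_variability_summary(values, roi_index, group_labels):
    """Mean map value over an ROI per subject, then S^2 per group and ratio.

    ``roi_index`` selects ROI voxels among the columns of ``values``
    (boolean or integer index).
    """
    roi_index = np.asarray(roi_index)
    if roi_index.dtype == bool and not roi_index.any():
        raise ValueError("ROI is empty")
    if roi_index.size == 0:
        raise ValueError("ROI is empty")
    blind, sighted = _check_groups(group_labels)
    per_subject = np.asarray(values, float)[:, roi_index].mean(1)
    s2b = per_subject[blind].var(ddof=1)
    s2s = per_subject[sighted].var(ddof=1)
    ratio = s2b / s2s if s2s > 0 else np.nan
    return {"S2_blind": float(s2b), "S2_sighted": float(s2s), "ratio": float(ratio),
            "per_subject": per_subject}


def group_stat_maps(values, group_labels, cohort_labels,
                    normalize_within_group=True, sig_mask=None) -> GroupStatMaps:
    """Convenience bundle of all voxelwise group statistics."""
    an = anova_2x2_map(values, group_labels, cohort_labels)
    t, df_t, _ = posthoc_ttest_map(values, group_labels)
    F, p, (_, df_bf) = brown_forsythe_map(values, group_labels)
    s2b, s2s, ratio, _ = group_variance_and_ratio(
        values, group_labels, cohort_labels,
        normalize_within_group=normalize_within_group, sig_mask=sig_mask,
    )
    return GroupStatMaps(
        F_group=an["F_group"], F_cohort=an["F_cohort"],
        F_interaction=an["F_interaction"], df_anova=an["df"],
        t_group=t, df_t=df_t, BF_F=F, BF_p=p,
        S2_blind=s2b, S2_sighted=s2s, ratio=ratio,
    )
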