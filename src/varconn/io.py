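"""Readers/writers for the study's on-disk layout.

Images are NIfTI-1 (via nibabel), tables are TSV, configuration is a flat
YAML file. All voxel coordinates are 0-based grid indices; world
coordinates travel only through the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .synth import Atlas, ScanSession, GROUPS, COHORTS


class StudyValidationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    bandpass_low_hz: float = 0.01
    bandpass_high_hz: float = 0.1
    smoothing_fwhm_mm: float = 6.0
    use_global_signal: bool = False
    n_permutations: int = 100_000
    cluster_alpha: float = 0.05
    voxel_p: float = 0.005
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 < self.bandpass_low_hz < self.bandpass_high_hz):
            raise ValueError("need 0 < bandpass_low_hz < bandpass_high_hz")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not (0 < self.cluster_alpha < 1 and 0 < self.voxel_p < 1):
            raise ValueError("cluster_alpha and voxel_p must be in (0, 1)")

    def validate_band(self, tr):
        if self.bandpass_high_hz >= 0.5 / tr:
            raise ValueError(
                f"bandpass_high_hz {self.bandpass_high_hz} at or above the "
                f"Nyquist frequency for TR {tr} s"
            )

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class StudyLayout:
    root: Path
    participants: pd.DataFrame
    bold_paths: dict
    motion_paths: dict
    atlas_path: Path
    masks: dict = field(default_factory=dict)
    derived_dir: Path = None


def save_stat_map(data, affine, path, mask=None):
    """Write a 3D statistic map; voxels outside the mask become NaN."""
    data = np.asarray(data, float)
    if mask is not None:
        data = np.where(np.asarray(mask, bool), data, np.nan)
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))


def load_stat_map(path, reference_affine=None):
    img = nib.load(str(path))
    if reference_affine is not None and not np.allclose(img.affine, reference_affine, atol=1e-4):
        raise StudyValidationError(f"affine of {path} does not match the reference grid")
    return np.asarray(img.get_fdata(), float), img.affine


def write_study(sessions, atlas, participants, truth, outdir):
    """Write a simulated study to disk in the standard layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = atlas.affine
    participants.to_csv(outdir / "participants.tsv", sep="\t", index=False)

    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), aff), str(outdir / "atlas.nii.gz"))
    for name, mask in (("seed", atlas.seed_mask), ("gray", atlas.gray_mask),
                       ("wm", atlas.wm_mask), ("ventricles", atlas.ventricle_mask)):
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), aff),
                 str(outdir / f"mask_{name}.nii.gz"))

    for ses in sessions:
        img = nib.Nifti1Image(ses.bold.astype(np.float32), aff)
        img.header.set_zooms((atlas.voxel_size_mm,) * 3 + (ses.tr,))
        nib.save(img, str(outdir / f"{ses.subject_id}_bold.nii.gz"))
        np.savetxt(outdir / f"{ses.subject_id}_motion.txt", ses.motion, fmt="%.6f")

    if truth is not None:
        gt = pd.DataFrame(
            truth.weight_by_subject_region,
            index=truth.subject_ids,
            columns=[f"region_{i+1}" for i in range(truth.weight_by_subject_region.shape[1])],
        )
        gt.insert(0, "clade", truth.true_clade_by_subject)
        gt.index.name = "subject_id"
        gt.to_csv(outdir / "ground_truth.tsv", sep="\t")
    return outdir


def load_study(root):
    """Validate and index a study directory."""
    root = Path(root)
    ppath = root / "participants.tsv"
    if not ppath.exists():
        raise StudyValidationError(f"missing participants table {ppath}")
    participants = pd.read_csv(ppath, sep="\t")

    bad_groups = set(participants["group"]) - set(GROUPS)
    if bad_groups:
        raise StudyValidationError(
            f"unknown group label(s) {sorted(bad_groups)}; allowed: {list(GROUPS)}"
        )
    bad_cohorts = set(participants["cohort"]) - set(COHORTS)
    if bad_cohorts:
        raise StudyValidationError(
            f"unknown cohort label(s) {sorted(bad_cohorts)}; allowed: {list(COHORTS)}"
        )

    atlas_path = root / "atlas.nii.gz"
    if not atlas_path.exists():
        raise StudyValidationError(f"missing atlas {atlas_path}")
    ref_affine = nib.load(str(atlas_path)).affine

    bold_paths, motion_paths = {}, {}
    for _, row in participants.iterrows():
        sid = row["subject_id"]
        bp = root / f"{sid}_bold.nii.gz"
        mp = root / f"{sid}_motion.txt"
        if not bp.exists():
            raise StudyValidationError(f"missing BOLD file for {sid}: {bp}")
        if not mp.exists():
            raise StudyValidationError(f"missing motion file for {sid}: {mp}")
        img = nib.load(str(bp))
        if not np.allclose(img.affine, ref_affine, atol=1e-4):
            raise StudyValidationError(f"grid/affine mismatch for {sid}")
        n_t = img.shape[-1]
        n_rows = np.loadtxt(mp).shape[0]
        if n_rows != n_t:
            raise StudyValidationError(
                f"motion/BOLD length mismatch for {sid}: {n_rows} rows vs {n_t} volumes"
            )
        bold_paths[sid] = bp
        motion_paths[sid] = mp

    masks = {name: root / f"mask_{name}.nii.gz"
             for name in ("seed", "gray", "wm", "ventricles")
             if (root / f"mask_{name}.nii.gz").exists()}
    return StudyLayout(root=root, participants=participants,
                       bold_paths=bold_paths, motion_paths=motion_paths,
                       atlas_path=atlas_path, masks=masks,
                       derived_dir=root / "derived")


def load_atlas(layout: StudyLayout) -> Atlas:
    labels_img = nib.load(str(layout.atlas_path))
    labels = np.asarray(labels_img.get_fdata()).astype(np.int32)
    vox = float(labels_img.header.get_zooms()[0])

    def mask(name):
        return np.asarray(nib.load(str(layout.masks[name])).get_fdata()) > 0

    seed_mask = mask("seed")
    seed_labels = np.unique(labels[seed_mask])
    seed_parcel = int(seed_labels[seed_labels > 0][0]) if seed_labels.size else 1
    return Atlas(labels, mask("gray"), mask("wm"), mask("ventricles"),
                 seed_parcel, vox)


def load_sessions(layout: StudyLayout):
    sessions = []
    for _, row in layout.participants.iterrows():
        sid = row["subject_id"]
        img = nib.load(str(layout.bold_paths[sid]))
        tr = float(img.header.get_zooms()[-1]) or 1.0
        sessions.append(ScanSession(
            subject_id=sid, group=row["group"], cohort=row["cohort"],
            age=int(row.get("age", 0)), education_years=int(row["education_years"]),
            tr=tr, bold=np.asarray(img.get_fdata(), np.float32),
            motion=np.loadtxt(layout.motion_paths[sid]).reshape(-1, 6),
        ))
    return sessions
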