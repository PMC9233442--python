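"""Synthetic two-cohort, two-group resting-state studies with planted ground truth.

The generator emulates the statistical structure of a two-site resting-state
comparison between congenitally blind and sighted adults: per subject, a 4D
BOLD-like volume is built as a sum of region-weighted latent signals plus
nuisance sources (motion-coupled signal, white-matter and ventricle signals,
an optional global component) and spatially smooth temporally white noise.

Each subject draws one connectivity weight per atlas parcel for the primary
seed; group means AND group variances of those weights differ in designated
parcels, so every downstream statistic (group t/F maps, Brown-Forsythe
variance maps, variance ratios, concordance of the two, subject clades,
education correlations) has a recoverable planted truth.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

GROUPS = ("blind", "sighted")
COHORTS = ("A", "B")

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


class AtlasSizeError(ValueError):
    """Grid too small for the requested parcel count."""


@dataclass(frozen=True)
class RegionEffect:
    """Planted connectivity-weight parameters for one parcel (primary seed)."""

    region_id: int
    mean_blind: float
    mean_sighted: float
    sd_blind: float
    sd_sighted: float

    def __post_init__(self):
        if self.sd_blind < 0 or self.sd_sighted < 0:
            raise ValueError("planted SDs must be nonnegative")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-level parameters of the synthetic two-cohort design.

    Defaults follow the emulated study: 13/18 blind/sighted in cohort A
    (TR 3 s, 180 volumes) and 12/13 in cohort B (TR 2 s, 240 volumes);
    maps are analyzed in a 0.01-0.1 Hz band and planted SD ratios of 2.2
    (variance ratio 4.84) match the reported order of magnitude of the
    blind/sighted variability ratio.
    """

    grid_shape: tuple[int, int, int] = (14, 14, 12)
    voxel_size_mm: float = 3.0
    n_blind_A: int = 13
    n_sighted_A: int = 18
    n_blind_B: int = 12
    n_sighted_B: int = 13
    tr_by_cohort: dict = field(default_factory=lambda: {"A": 3.0, "B": 2.0})
    n_vols_by_cohort: dict = field(default_factory=lambda: {"A": 180, "B": 240})
    n_parcels: int = 10
    seed_parcel: int = 1
    control_seed_parcels: tuple[int, ...] = (8, 9, 10)
    # (region_id, mean_blind, mean_sighted, sd_blind, sd_sighted)
    region_effects: tuple[RegionEffect, ...] = (
        RegionEffect(3, 1.0, 0.3, 1.1, 0.5),
        RegionEffect(4, 1.0, 0.3, 1.1, 0.5),
        RegionEffect(5, 1.0, 0.3, 0.5, 0.5),
        RegionEffect(2, -1.0, -0.3, 0.5, 0.5),
        RegionEffect(6, -1.0, -0.3, 0.5, 0.5),
        RegionEffect(7, -1.0, -0.3, 0.5, 0.5),
    )
    baseline_mean: float = 0.0
    baseline_sd: float = 0.5
    control_weight_sd: float = 0.05
    noise_fwhm_mm: float = 3.0
    noise_sd: float = 1.5
    cohort_scale: dict = field(default_factory=lambda: {"A": 1.0, "B": 1.3})
    cohort_offset: dict = field(default_factory=lambda: {"A": 0.0, "B": 0.5})
    signal_band_hz: tuple[float, float] = (0.01, 0.1)
    motion_coupling: float = 0.2
    nuisance_leak_sd: float = 0.05
    global_amp: float = 0.0
    education_slope: float = 0.25
    education_regions: tuple[int, ...] = (5,)
    education_group: str | None = "blind"
    education_range: tuple[int, int] = (8, 20)
    n_clades: int = 0
    clade_sd: float = 2.5
    clade_group: str | None = "blind"
    rng_seed: int = 0

    def __post_init__(self):
        for n in (self.n_blind_A, self.n_sighted_A, self.n_blind_B, self.n_sighted_B):
            if n < 2:
                raise ValueError("all subject counts must be >= 2")
        if self.noise_fwhm_mm < 0 or self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("noise parameters must be nonnegative")
        ids = set(range(1, self.n_parcels + 1))
        planted = {e.region_id for e in self.region_effects}
        if not planted <= ids:
            raise ValueError(f"region_effects reference parcels outside 1..{self.n_parcels}")
        if not set(self.education_regions) <= ids:
            raise ValueError("education_regions outside the parcellation")
        if self.seed_parcel not in ids:
            raise ValueError("seed_parcel outside the parcellation")

    @property
    def n_subjects(self) -> int:
        return self.n_blind_A + self.n_sighted_A + self.n_blind_B + self.n_sighted_B

    def with_(self, **kw) -> "SyntheticSpec":
        return replace(self, **kw)


@dataclass
class Atlas:
    """Integer parcellation plus seed/tissue masks on one grid."""

    labels: np.ndarray          # int, 0 = background/non-gray
    gray_mask: np.ndarray       # bool
    wm_mask: np.ndarray
    ventricle_mask: np.ndarray
    seed_parcel: int
    voxel_size_mm: float

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0] = a[1, 1] = a[2, 2] = self.voxel_size_mm
        return a

    @property
    def brain_mask(self) -> np.ndarray:
        return self.gray_mask | self.wm_mask | self.ventricle_mask

    @property
    def seed_mask(self) -> np.ndarray:
        return self.labels == self.seed_parcel

    @property
    def n_parcels(self) -> int:
        return int(self.labels.max())

    def parcel_mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class ScanSession:
    """One subject's 4D data, motion table, and metadata."""

    subject_id: str
    group: str
    cohort: str
    age: int
    education_years: int
    tr: float
    bold: np.ndarray           # (x, y, z, t) float32
    motion: np.ndarray         # (t, 6)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {COHORTS}, got {self.cohort!r}")
        if self.motion.shape != (self.bold.shape[-1], 6):
            raise ValueError("motion table must be (n_timepoints, 6)")


@dataclass
class GroundTruth:
    """Planted quantities of a simulated study."""

    weight_by_subject_region: np.ndarray   # (n_subjects, n_parcels), primary seed
    true_variance_ratio_by_region: np.ndarray  # (n_parcels,)
    true_clade_by_subject: np.ndarray      # int, -1 when no clade planted
    subject_ids: list

    def __post_init__(self):
        if np.any(self.true_variance_ratio_by_region < 0):
            raise ValueError("variance ratios must be nonnegative")
        if self.weight_by_subject_region.shape[0] != len(self.subject_ids):
            raise ValueError("ground-truth dimensions do not match the study")


# ---------------------------------------------------------------------------
# atlas construction


def make_atlas(grid_shape, n_parcels=10, rng_seed=0, voxel_size_mm=3.0, seed_parcel=1):
    """Build a brain-like ellipsoid with gray parcels, WM core and ventricles.

    Parcels are contiguous (multi-source BFS with 6-adjacency from
    farthest-point sampled seeds), mutually exclusive, labeled 1..n_parcels
    and restricted to the gray-matter mask; a central box is split into
    ventricle and surrounding white-matter compartments.
    """
    if n_parcels < 2:
        raise ValueError("n_parcels must be >= 2")
    grid_shape = tuple(int(g) for g in grid_shape)
    center = (np.array(grid_shape) - 1) / 2.0
    semi = np.maximum(np.array(grid_shape) / 2.0 - 1.0, 1.0)
    ix = np.indices(grid_shape)
    d2 = sum(((ix[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    brain = d2 <= 1.0

    cx, cy, cz = (np.array(grid_shape) // 2).tolist()
    vent = np.zeros(grid_shape, bool)
    vent[cx - 1:cx + 1, cy - 1:cy + 1, cz - 1:cz + 1] = True
    vent &= brain
    wm = np.zeros(grid_shape, bool)
    wm[cx - 3:cx + 3, cy - 3:cy + 3, cz - 2:cz + 2] = True
    wm &= brain
    wm &= ~vent
    gray = brain & ~wm & ~vent

    n_gray = int(gray.sum())
    if n_gray < 8 * n_parcels:
        raise AtlasSizeError(
            f"grid {grid_shape} has {n_gray} gray voxels; "
            f"{n_parcels} parcels need at least {8 * n_parcels}"
        )

    rng = np.random.default_rng(rng_seed)
    coords = np.argwhere(gray)
    # farthest-point sampling of parcel seeds for even, well-separated parcels
    first = int(rng.integers(len(coords)))
    seeds = [first]
    dmin = np.linalg.norm(coords - coords[first], axis=1)
    for _ in range(n_parcels - 1):
        nxt = int(np.argmax(dmin))
        seeds.append(nxt)
        dmin = np.minimum(dmin, np.linalg.norm(coords - coords[nxt], axis=1))

    labels = np.zeros(grid_shape, np.int32)
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]

    def grow(queue, n_rounds=None):
        rounds = 0
        while queue and (n_rounds is None or rounds < n_rounds):
            rounds += 1
            nxt = deque()
            while queue:
                x, y, z = queue.popleft()
                lab = labels[x, y, z]
                for dx, dy, dz in offsets:
                    nx_, ny_, nz_ = x + dx, y + dy, z + dz
                    if (0 <= nx_ < grid_shape[0] and 0 <= ny_ < grid_shape[1]
                            and 0 <= nz_ < grid_shape[2]
                            and gray[nx_, ny_, nz_] and labels[nx_, ny_, nz_] == 0):
                        labels[nx_, ny_, nz_] = lab
                        nxt.append((nx_, ny_, nz_))
            queue = nxt
        return queue

    # the seed parcel grows two rings first: a larger seed stabilizes the
    # extracted seed time course (less averaged-noise contamination)
    seed_q = deque()
    v = tuple(coords[seeds[seed_parcel - 1]])
    labels[v] = seed_parcel
    seed_q.append(v)
    seed_q = grow(seed_q, n_rounds=2)

    queue = deque(seed_q)
    for lab, si in enumerate(seeds, start=1):
        if lab == seed_parcel:
            continue
        v = tuple(coords[si])
        if labels[v] == 0:
            labels[v] = lab
            queue.append(v)
    grow(queue)

    # any gray voxel unreachable by face adjacency joins the nearest parcel seed
    leftover = np.argwhere(gray & (labels == 0))
    for v in leftover:
        d = np.linalg.norm(coords[seeds] - v, axis=1)
        labels[tuple(v)] = int(np.argmin(d)) + 1

    sizes = np.bincount(labels.ravel(), minlength=n_parcels + 1)[1:]
    if sizes.min() < 8:
        raise AtlasSizeError(
            f"smallest parcel has {int(sizes.min())} voxels (< 8); use a larger grid"
        )
    return Atlas(labels, gray, wm, vent, seed_parcel, voxel_size_mm)


# ---------------------------------------------------------------------------
# signals and weights


def bandlimited_signal(n_t, tr, band, rng):
    """Unit-variance Gaussian process band-limited to ``band`` (Hz)."""
    f = np.fft.rfftfreq(n_t, tr)
    keep = (f >= band[0]) & (f <= band[1])
    if not keep.any():
        raise ValueError("band contains no resolvable frequency")
    spec = np.zeros(len(f), complex)
    spec[keep] = rng.standard_normal(keep.sum()) + 1j * rng.standard_normal(keep.sum())
    x = np.fft.irfft(spec, n=n_t)
    x -= x.mean()
    return x / x.std()


def _region_params(spec):
    """Per-parcel (mean_blind, mean_sighted, sd_blind, sd_sighted) arrays."""
    mb = np.full(spec.n_parcels, spec.baseline_mean)
    ms = np.full(spec.n_parcels, spec.baseline_mean)
    sb = np.full(spec.n_parcels, spec.baseline_sd)
    ss = np.full(spec.n_parcels, spec.baseline_sd)
    for e in spec.region_effects:
        i = e.region_id - 1
        mb[i], ms[i], sb[i], ss[i] = e.mean_blind, e.mean_sighted, e.sd_blind, e.sd_sighted
    # control-seed parcels carry no primary-seed signal: their own latent
    # must not be contaminated by the primary latent, so cross-seed
    # comparisons are true nulls
    for p in spec.control_seed_parcels:
        i = p - 1
        mb[i] = ms[i] = 0.0
        sb[i] = ss[i] = 0.0
    i = spec.seed_parcel - 1
    mb[i] = ms[i] = 1.0
    sb[i] = ss[i] = 0.0
    return mb, ms, sb, ss


def _education_sd(spec) -> float:
    lo, hi = spec.education_range
    vals = np.arange(lo, hi + 1)
    return float(vals.std())


def true_variance_ratios(spec) -> np.ndarray:
    """Planted blind/sighted weight-variance ratio per parcel (primary seed)."""
    mb, ms, sb, ss = _region_params(spec)
    var_b, var_s = sb ** 2, ss ** 2
    edu_var = (spec.education_slope * _education_sd(spec)) ** 2
    for r in spec.education_regions:
        if spec.education_group in (None, "blind"):
            var_b[r - 1] += edu_var
        if spec.education_group in (None, "sighted"):
            var_s[r - 1] += edu_var
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(var_s > 0, var_b / var_s, np.nan)


def draw_subject_weights(spec, group, education_years, rng, clade_template=None):
    """Draw the primary-seed connectivity weight for every parcel."""
    mb, ms, sb, ss = _region_params(spec)
    mean, sd = (mb, sb) if group == "blind" else (ms, ss)
    w = mean + sd * rng.standard_normal(spec.n_parcels)
    if spec.education_slope and (spec.education_group in (None, group)):
        mid = 0.5 * (spec.education_range[0] + spec.education_range[1])
        for r in spec.education_regions:
            w[r - 1] += spec.education_slope * (education_years - mid)
    if clade_template is not None:
        w = w + clade_template
    w[spec.seed_parcel - 1] = 1.0
    return w


# ---------------------------------------------------------------------------
# session / study simulation


def simulate_session(spec, subject_row, atlas, rng):
    """Simulate one subject's 4D session.

    ``subject_row`` is a mapping with at least ``subject_id``, ``group``,
    ``cohort``, ``age`` and ``education_years``; optional ``weights``
    (primary-seed parcel weights) and ``control_weights`` (dict parcel ->
    weight vector) override the internally drawn ones so a study-level
    ground truth can be planted first.
    """
    for key in ("group", "cohort", "education_years"):
        if key not in subject_row or subject_row[key] is None:
            raise ValueError(f"subject_row missing required field {key!r}")
    group, cohort = subject_row["group"], subject_row["cohort"]
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; allowed: {GROUPS}")
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}; allowed: {COHORTS}")
    tr = spec.tr_by_cohort[cohort]
    n_t = int(spec.n_vols_by_cohort[cohort])
    edu = int(subject_row["education_years"])

    w = subject_row.get("weights")
    if w is None:
        w = draw_subject_weights(spec, group, edu, rng)
    w = np.asarray(w, float)

    labels = atlas.labels
    gray = atlas.gray_mask
    brain = atlas.brain_mask
    shape = labels.shape
    n_brain = int(brain.sum())
    gray_in_brain = gray[brain]
    region_of_brain = labels[brain] - 1          # valid only where gray

    # low-rank construction: BOLD(brain voxels) = loadings @ signals + noise
    loadings, signals = [], []

    def add_latent(load, sig):
        loadings.append(load)
        signals.append(sig)

    # primary-seed latent: the subject's parcel weights
    load = np.zeros(n_brain)
    load[gray_in_brain] = w[region_of_brain[gray_in_brain]]
    add_latent(load, bandlimited_signal(n_t, tr, spec.signal_band_hz, rng))

    # control-seed latents: weight 1 in their own parcel, weak unstructured
    # weights elsewhere (no group structure)
    control_weights = subject_row.get("control_weights") or {}
    for p in spec.control_seed_parcels:
        wk = control_weights.get(p)
        if wk is None:
            wk = spec.control_weight_sd * rng.standard_normal(spec.n_parcels)
            wk[p - 1] = 1.0
        load = np.zeros(n_brain)
        load[gray_in_brain] = np.asarray(wk, float)[region_of_brain[gray_in_brain]]
        add_latent(load, bandlimited_signal(n_t, tr, spec.signal_band_hz, rng))

    # tissue nuisance latents: unit loading in their compartment, small
    # random leakage into gray matter so nuisance regression is consequential
    for mask in (atlas.wm_mask, atlas.ventricle_mask):
        load = np.zeros(n_brain)
        load[mask[brain]] = 1.0
        load[gray_in_brain] = spec.nuisance_leak_sd * rng.standard_normal(int(gray.sum()))
        add_latent(load, bandlimited_signal(n_t, tr, spec.signal_band_hz, rng))

    if spec.global_amp:
        add_latent(np.full(n_brain, spec.global_amp),
                   bandlimited_signal(n_t, tr, spec.signal_band_hz, rng))

    # motion: smooth random walks; coupled into the data via a random smooth map
    motion = np.cumsum(rng.normal(0.0, 0.02, size=(n_t, 6)), axis=0)
    msig = motion - motion.mean(0)
    sd = msig.std(0)
    msig = msig[:, sd > 0] / sd[sd > 0]
    if msig.size and spec.motion_coupling:
        combined = msig.sum(1)
        combined = (combined - combined.mean()) / (combined.std() or 1.0)
        load3 = gaussian_filter(rng.standard_normal(shape), 1.0)
        load3 *= spec.motion_coupling / load3.std()
        add_latent(load3[brain], combined)

    bold = np.zeros(shape + (n_t,), np.float32)
    bold[brain] = (np.column_stack(loadings) @ np.vstack(signals)).astype(np.float32)

    if spec.noise_sd > 0:
        noise = rng.standard_normal(shape + (n_t,), dtype=np.float32)
        if spec.noise_fwhm_mm > 0:
            sigma = spec.noise_fwhm_mm * FWHM_TO_SIGMA / spec.voxel_size_mm
            gaussian_filter(noise, sigma=(sigma, sigma, sigma, 0), truncate=4.0, output=noise)
            noise *= 1.0 / noise.std()
        bold += np.float32(spec.noise_sd) * noise

    # affine site effect, removed later by per-subject standardization
    bold *= np.float32(spec.cohort_scale[cohort])
    bold += np.float32(spec.cohort_offset[cohort])

    return ScanSession(
        subject_id=subject_row.get("subject_id", "sub-000"),
        group=group,
        cohort=cohort,
        age=int(subject_row.get("age", 0)),
        education_years=edu,
        tr=tr,
        bold=bold,
        motion=motion,
    )


def make_participants(spec, rng):
    """Participants table: subject_id, group, cohort, age, education_years."""
    import pandas as pd

    rows = []
    counts = [
        ("blind", "A", spec.n_blind_A),
        ("sighted", "A", spec.n_sighted_A),
        ("blind", "B", spec.n_blind_B),
        ("sighted", "B", spec.n_sighted_B),
    ]
    i = 0
    lo, hi = spec.education_range
    for group, cohort, n in counts:
        for _ in range(n):
            i += 1
            rows.append(
                dict(
                    subject_id=f"sub-{i:03d}",
                    group=group,
                    cohort=cohort,
                    age=int(rng.integers(22, 64)),
                    education_years=int(rng.integers(lo, hi + 1)),
                )
            )
    return pd.DataFrame(rows)


def simulate_study(spec):
    """Simulate the full study; returns (sessions, atlas, participants, truth)."""
    root = np.random.default_rng(spec.rng_seed)
    atlas = make_atlas(
        spec.grid_shape, spec.n_parcels, rng_seed=spec.rng_seed,
        voxel_size_mm=spec.voxel_size_mm, seed_parcel=spec.seed_parcel,
    )
    participants = make_participants(spec, root)

    clades = np.full(len(participants), -1)
    templates = None
    if spec.n_clades > 0:
        # orthonormalized template directions so planted profiles are
        # distinct by construction, scaled to clade_sd per parcel
        raw = root.standard_normal((spec.n_parcels, spec.n_clades))
        q, _ = np.linalg.qr(raw)
        templates = (spec.clade_sd * np.sqrt(spec.n_parcels)) * q.T
        templates[:, spec.seed_parcel - 1] = 0.0
        members = (
            participants.index
            if spec.clade_group is None
            else participants.index[participants["group"] == spec.clade_group]
        )
        for j, idx in enumerate(members):
            clades[idx] = j % spec.n_clades

    seqs = np.random.SeedSequence(spec.rng_seed).spawn(len(participants) + 1)
    weight_rng = np.random.default_rng(seqs[0])
    weights = np.empty((len(participants), spec.n_parcels))
    for i, row in participants.iterrows():
        tmpl = templates[clades[i]] if templates is not None and clades[i] >= 0 else None
        weights[i] = draw_subject_weights(
            spec, row["group"], row["education_years"], weight_rng, clade_template=tmpl
        )

    sessions = []
    for i, row in participants.iterrows():
        srow = dict(row)
        srow["weights"] = weights[i]
        rng = np.random.default_rng(seqs[i + 1])
        sessions.append(simulate_session(spec, srow, atlas, rng))

    truth = GroundTruth(
        weight_by_subject_region=weights,
        true_variance_ratio_by_region=true_variance_ratios(spec),
        true_clade_by_subject=clades,
        subject_ids=list(participants["subject_id"]),
    )
    return sessions, atlas, participants, truth
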