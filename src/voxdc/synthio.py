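"""Synthetic resting-state cohort generation.

Generates BOLD-like 4D volumes with a controlled correlation structure so
that voxel-wise degree centrality (DC) has known ground truth:

* a low-rank latent-factor signal model — each gray-matter voxel follows one
  of ``n_latents`` independent band-limited (0.01-0.08 Hz) network time
  courses, so within-community correlations are strong and between-community
  correlations are near zero;
* a small set of *hub* voxels that load on every latent, giving them
  supra-threshold correlations with most of the mask and hence elevated DC;
* a group contrast — patient-like (group B) subjects have their latent
  loadings scaled inside configured regions, shifting regional DC;
* a clinical severity score on a 0-48 scale coupled (with configurable slope
  and noise) to a per-subject loading gain in a score region, so that
  covariate-adjusted DC/score correlations have a known sign;
* rigid-body motion parameters (bounded mean-reverting random walk), a
  motion-coupled artifact, per-voxel linear drift, and white noise.

Everything is a pure function of (config, seed). Volumes are written as
NIfTI-1, motion and cohort manifests as TSV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

MOTION_COLUMNS = ["tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg"]
MANIFEST_COLUMNS = ["subject_id", "group", "age", "sex", "score"]

#: ALSFRS-r–like clinical score range (0 = maximal impairment, 48 = intact).
SCORE_RANGE = (0.0, 48.0)


def default_affine(grid_shape: Sequence[int], voxel_size_mm: Sequence[float]) -> np.ndarray:
    """RAS affine with the grid centered on the world origin."""
    vox = np.asarray(voxel_size_mm, dtype=float)
    aff = np.diag(np.concatenate([vox, [1.0]]))
    center = (np.asarray(grid_shape, dtype=float) - 1) / 2.0
    aff[:3, 3] = -center * vox
    return aff


@dataclass(frozen=True)
class AcquisitionConfig:
    """EPI acquisition geometry and timing.

    Defaults mirror a standard 3 T resting-state protocol: TR 2.0 s, 240
    volumes (480 s of scanning), 3 mm isotropic voxels.
    """

    tr_seconds: float = 2.0
    n_volumes: int = 240
    grid_shape: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_volumes < 20:
            raise ValueError("n_volumes must be >= 20")
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.affine is None:
            object.__setattr__(
                self, "affine", default_affine(self.grid_shape, self.voxel_size_mm)
            )

    @property
    def scan_seconds(self) -> float:
        return self.tr_seconds * self.n_volumes


# A region spec is ("sphere", (fx, fy, fz), radius_mm): center as fractions
# of the grid extent, radius in millimetres.
RegionSpec = tuple[str, tuple[float, float, float], float]


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of a synthetic two-group cohort."""

    n_per_group: tuple[int, int] = (15, 15)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    n_latents: int = 6
    hub_fraction: float = 0.02
    hub_loading_gain: float = 1.8
    base_loading: float = 0.9
    group_effect_regions: tuple[tuple[RegionSpec, float], ...] = (
        (("sphere", (0.35, 0.5, 0.55), 7.5), 0.5),
    )
    noise_sd: float = 0.5
    motion_amplitude_mm: float = 0.05
    motion_coupling: float = 0.2
    drift_amplitude: float = 0.3
    score_coupling: tuple[RegionSpec, float, float] = (
        ("sphere", (0.65, 0.45, 0.5), 7.5),
        -20.0,
        2.0,
    )
    score_gain_sd: float = 0.25
    score_intercept: float = 36.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.hub_fraction < 1):
            raise ValueError("hub_fraction must be in (0, 1)")
        if self.n_latents < 2:
            raise ValueError("n_latents must be >= 2")
        if any(mult <= 0 for _, mult in self.group_effect_regions):
            raise ValueError("group-effect multipliers must be positive")
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("n_per_group entries must be >= 1")


@dataclass
class CohortTruth:
    """Planted ground truth of a cohort.

    ``group_effect_mask`` is signed: +1 where group B has elevated loading
    (hence elevated DC), -1 where it is suppressed.
    """

    gm_probability: np.ndarray
    gm_mask: np.ndarray
    hub_mask: np.ndarray
    group_effect_mask: np.ndarray
    score_region_mask: np.ndarray
    score_slope: float
    community: np.ndarray  # per-voxel latent index, -1 outside the mask
    hub_latent_sets: np.ndarray  # (n_hubs, n_latents) bool, hubs in raster order

    def __post_init__(self) -> None:
        for name in ("hub_mask", "group_effect_mask", "score_region_mask"):
            m = getattr(self, name)
            if np.any(m.astype(bool) & ~self.gm_mask):
                raise ValueError(f"{name} must lie inside the gray-matter mask")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    sex: str
    clinical_score: float
    volume_path: Path | None = None
    motion_path: Path | None = None


def simulate_motion(
    acquisition: AcquisitionConfig, amplitude_mm: float, seed: int
) -> np.ndarray:
    """Bounded rigid-body motion series: n_volumes x 6 (tx,ty,tz mm; rx,ry,rz deg).

    Mean-reverting (AR(1), rho=0.95) random walk starting at zero, so the
    stationary spread is ~3.2x the per-step amplitude and excursions stay
    far below clinical exclusion thresholds at realistic amplitudes.
    Rotational innovations are scaled to 0.6 deg per mm of translational
    amplitude.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude_mm must be >= 0")
    n = acquisition.n_volumes
    params = np.zeros((n, 6))
    if amplitude_mm == 0:
        return params
    rng = np.random.default_rng(seed)
    rho = 0.95
    scale = np.array([amplitude_mm] * 3 + [0.6 * amplitude_mm] * 3)
    innov = rng.normal(size=(n - 1, 6)) * scale
    for t in range(1, n):
        params[t] = rho * params[t - 1] + innov[t - 1]
    return params


def make_gm_probability(acquisition: AcquisitionConfig, seed: int) -> np.ndarray:
    """Smooth interior gray-matter probability blob in [0, 1].

    A sigmoid-of-radius ellipsoid centered in the grid, with mildly smoothed
    noise on top; tapers to ~0 at the grid edges and yields a single
    connected component when thresholded at > 0.20.
    """
    shape = acquisition.grid_shape
    if int(np.prod(shape)) < 1000:
        raise ValueError("grid too small for a gray-matter blob (< 10^3 voxels)")
    rng = np.random.default_rng(seed)
    center = (np.asarray(shape, dtype=float) - 1) / 2.0
    radii = 0.38 * np.asarray(shape, dtype=float)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    d = np.sqrt(sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii)))
    prob = 0.98 / (1.0 + np.exp((d - 1.0) / 0.08))
    noise = ndimage.gaussian_filter(rng.normal(size=shape), 1.5)
    noise *= 0.03 / noise.std()
    return np.clip(prob + noise, 0.0, 1.0)


def resolve_region(
    spec: RegionSpec,
    grid_shape: Sequence[int],
    voxel_size_mm: Sequence[float],
    within: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask for a region spec, optionally intersected with a mask."""
    kind, center_frac, radius_mm = spec
    if kind != "sphere":
        raise ValueError(f"unknown region kind: {kind!r}")
    shape = np.asarray(grid_shape, dtype=float)
    vox = np.asarray(voxel_size_mm, dtype=float)
    center = np.asarray(center_frac, dtype=float) * (shape - 1)
    grids = np.meshgrid(*[np.arange(s) for s in grid_shape], indexing="ij")
    d2 = sum(((g - c) * v) ** 2 for g, c, v in zip(grids, center, vox))
    region = d2 <= radius_mm**2
    if within is not None:
        region &= within
    return region


def build_truth(cohort: CohortConfig) -> CohortTruth:
    """Deterministically derive the planted structure from the cohort config."""
    acq = cohort.acquisition
    ss = np.random.SeedSequence([cohort.seed, 0])
    gm_seed, hub_seed = (int(s) for s in ss.generate_state(2) % (2**31))
    gm_probability = make_gm_probability(acq, gm_seed)
    gm_mask = gm_probability > 0.2

    flat_idx = np.flatnonzero(gm_mask.ravel())  # raster (lexicographic) order
    n_mask = flat_idx.size
    community = np.full(acq.grid_shape, -1, dtype=np.int32).ravel()
    for k, chunk in enumerate(np.array_split(flat_idx, cohort.n_latents)):
        community[chunk] = k
    community = community.reshape(acq.grid_shape)

    rng = np.random.default_rng(hub_seed)
    n_hubs = max(1, int(round(cohort.hub_fraction * n_mask)))
    n_hubs = min(n_hubs, n_mask)
    hub_flat = rng.choice(flat_idx, size=n_hubs, replace=False)
    hub_mask = np.zeros(acq.grid_shape, dtype=bool).ravel()
    hub_mask[hub_flat] = True
    hub_mask = hub_mask.reshape(acq.grid_shape)

    # Each hub loads on its own random half of the latent networks. Loading
    # on *all* latents would make a hub's time course proportional to the
    # global mean signal, so global-signal regression in preprocessing would
    # erase exactly the hubs the cohort is supposed to contain.
    K = cohort.n_latents
    n_hub_latents = max(2, K // 2)
    hub_latent_sets = np.zeros((n_hubs, K), dtype=bool)
    for i in range(n_hubs):
        hub_latent_sets[i, rng.choice(K, size=n_hub_latents, replace=False)] = True

    group_effect = np.zeros(acq.grid_shape, dtype=np.int8)
    for spec, mult in cohort.group_effect_regions:
        region = resolve_region(spec, acq.grid_shape, acq.voxel_size_mm, gm_mask)
        group_effect[region] = 1 if mult > 1 else -1

    score_spec, score_slope, _ = cohort.score_coupling
    score_region = resolve_region(score_spec, acq.grid_shape, acq.voxel_size_mm, gm_mask)

    return CohortTruth(
        gm_probability=gm_probability,
        gm_mask=gm_mask,
        hub_mask=hub_mask,
        group_effect_mask=group_effect,
        score_region_mask=score_region,
        score_slope=float(score_slope),
        community=community,
        hub_latent_sets=hub_latent_sets,
    )


def band_limited_series(
    n_timepoints: int,
    tr_seconds: float,
    n_series: int,
    rng: np.random.Generator,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
) -> np.ndarray:
    """Unit-variance time courses with all spectral energy in [low, high] Hz."""
    freqs = np.fft.rfftfreq(n_timepoints, tr_seconds)
    band = (freqs >= low_hz) & (freqs <= high_hz) & (freqs > 0)
    if not band.any():
        raise ValueError("no Fourier bins inside the requested band")
    coeffs = np.zeros((n_series, freqs.size), dtype=complex)
    n_band = int(band.sum())
    coeffs[:, band] = rng.normal(size=(n_series, n_band)) + 1j * rng.normal(
        size=(n_series, n_band)
    )
    series = np.fft.irfft(coeffs, n=n_timepoints, axis=1)
    series /= series.std(axis=1, keepdims=True)
    return series


def _subject_loadings(
    cohort: CohortConfig,
    truth: CohortTruth,
    group: str,
    score_gain: float,
) -> np.ndarray:
    """(n_mask, n_latents) loading matrix for one subject."""
    mask_flat = truth.gm_mask.ravel()
    comm = truth.community.ravel()[mask_flat]
    hubs = truth.hub_mask.ravel()[mask_flat]
    n_mask = comm.size
    K = cohort.n_latents
    load = np.zeros((n_mask, K))
    load[np.arange(n_mask), comm] = cohort.base_loading
    hub_rows = np.flatnonzero(hubs)
    sets = truth.hub_latent_sets
    per_latent = cohort.hub_loading_gain / np.sqrt(max(sets.sum(axis=1).max(), 1))
    for row, latent_set in zip(hub_rows, sets):
        load[row] = 0.0
        load[row, latent_set] = per_latent

    acq = cohort.acquisition
    if group == "B":
        for spec, mult in cohort.group_effect_regions:
            region = resolve_region(spec, acq.grid_shape, acq.voxel_size_mm, truth.gm_mask)
            sel = region.ravel()[mask_flat] & ~hubs
            load[sel] *= mult
    score_sel = truth.score_region_mask.ravel()[mask_flat] & ~hubs
    load[score_sel] *= score_gain
    return load


def simulate_subject(
    cohort: CohortConfig,
    truth: CohortTruth,
    group: str,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, SubjectRecord]:
    """One subject's 4D volume, motion parameters and record.

    Signal model per in-mask voxel: sum of loaded band-limited latents +
    linear drift + motion-coupled artifact + white noise. The clinical score
    is ``intercept + slope * (score_gain - 1) + noise`` clamped to [0, 48],
    where ``score_gain`` is the subject's multiplicative loading gain in the
    score region — so regional DC and score are coupled with a known sign.
    """
    if group not in ("A", "B"):
        raise ValueError(f"group must be 'A' or 'B', got {group!r}")
    acq = cohort.acquisition
    if truth.gm_mask.shape != acq.grid_shape:
        raise ValueError("truth grid does not match the cohort acquisition grid")
    ss = np.random.SeedSequence([seed, 1])
    sig_seed, motion_seed = (int(s) for s in ss.generate_state(2) % (2**31))
    rng = np.random.default_rng(sig_seed)

    T = acq.n_volumes
    latents = band_limited_series(T, acq.tr_seconds, cohort.n_latents, rng)
    score_gain = float(np.exp(rng.normal(0.0, cohort.score_gain_sd)))
    load = _subject_loadings(cohort, truth, group, score_gain)
    Y = load @ latents  # (n_mask, T)

    trend = np.linspace(-1.0, 1.0, T)
    Y += np.outer(rng.normal(0.0, cohort.drift_amplitude, size=Y.shape[0]), trend)

    motion = simulate_motion(acq, cohort.motion_amplitude_mm, motion_seed)
    if cohort.motion_coupling > 0 and cohort.motion_amplitude_mm > 0:
        deltas = np.abs(np.diff(motion, axis=0)).sum(axis=1)
        art = np.concatenate([[0.0], deltas])
        sd = art.std()
        if sd > 0:
            art = (art - art.mean()) / sd
            Y += cohort.motion_coupling * np.outer(rng.normal(size=Y.shape[0]), art)

    if cohort.noise_sd > 0:
        Y += cohort.noise_sd * rng.standard_normal(Y.shape)

    data = np.zeros(acq.grid_shape + (T,), dtype=np.float64)
    data[truth.gm_mask] = Y

    _, slope, score_noise_sd = cohort.score_coupling
    score = cohort.score_intercept + slope * (score_gain - 1.0)
    if score_noise_sd > 0:
        score += rng.normal(0.0, score_noise_sd)
    score = float(np.clip(score, *SCORE_RANGE))

    age = float(rng.normal(50.0, 9.0))
    while not (24.0 <= age <= 71.0):
        age = float(rng.normal(50.0, 9.0))
    sex = str(rng.choice(["M", "F"]))

    record = SubjectRecord(
        subject_id=f"sub-{group}{seed:08d}",
        group=group,
        age=round(age, 1),
        sex=sex,
        clinical_score=round(score, 2),
    )
    return data, motion, record


def write_motion_tsv(motion: np.ndarray, path: Path) -> None:
    pd.DataFrame(motion, columns=MOTION_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_motion_tsv(path: Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"motion TSV {path} missing columns {missing}")
    return df[MOTION_COLUMNS].to_numpy(dtype=float)


def simulate_cohort(
    cohort: CohortConfig, outdir: Path | str
) -> tuple[list[SubjectRecord], CohortTruth]:
    """Generate and write a full cohort: per-subject NIfTI + motion TSV + manifest.

    Also writes the gray-matter probability volume and the planted truth
    masks so downstream validation can recover the ground truth. Ages are
    drawn from N(50, 9) truncated to [24, 71].
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {outdir}: {exc}") from exc
    acq = cohort.acquisition
    truth = build_truth(cohort)

    nib.save(
        nib.Nifti1Image(truth.gm_probability.astype(np.float32), acq.affine),
        outdir / "gm_probability.nii.gz",
    )
    for name, arr in (
        ("truth_hub_mask", truth.hub_mask.astype(np.int8)),
        ("truth_group_effect", truth.group_effect_mask),
        ("truth_score_region", truth.score_region_mask.astype(np.int8)),
    ):
        nib.save(nib.Nifti1Image(arr, acq.affine), outdir / f"{name}.nii.gz")

    n_total = sum(cohort.n_per_group)
    seeds = np.random.SeedSequence([cohort.seed, 2]).generate_state(n_total) % (2**31)
    records: list[SubjectRecord] = []
    i = 0
    for group, n in zip(("A", "B"), cohort.n_per_group):
        for j in range(n):
            data, motion, rec = simulate_subject(cohort, truth, group, int(seeds[i]))
            rec.subject_id = f"sub-{group}{j:03d}"
            vol_path = outdir / f"{rec.subject_id}_bold.nii.gz"
            mot_path = outdir / f"{rec.subject_id}_motion.tsv"
            try:
                nib.save(nib.Nifti1Image(data.astype(np.float32), acq.affine), vol_path)
                write_motion_tsv(motion, mot_path)
            except OSError as exc:
                raise OSError(f"failed writing subject files under {outdir}: {exc}") from exc
            rec.volume_path = vol_path
            rec.motion_path = mot_path
            records.append(rec)
            i += 1

    manifest = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "score": [r.clinical_score for r in records],
        }
    )
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return records, truth


def read_manifest(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns {missing}")
    return df
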