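"""Temporal preprocessing of aligned BOLD time series.

Covers the computations that act on already-registered 4D data: discarding
initial volumes, motion QC against translation/rotation limits, Jenkinson
framewise displacement, the Friston 24-parameter motion expansion, nuisance
regression (motion + tissue signals + global mean + polynomial trends) and
ideal frequency-domain band-pass filtering.

The canonical stage order is: discard -> motion QC / FD -> nuisance
regression -> band-pass. Mean FD is a per-subject scalar; within a subject's
own regression it is absorbed by the intercept, so it is carried in the QC
record for use as a group-level covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthio import MOTION_COLUMNS

FRISTON24_COLUMNS = (
    [c for c in MOTION_COLUMNS]
    + [f"{c}_lag1" for c in MOTION_COLUMNS]
    + [f"{c}_sq" for c in MOTION_COLUMNS]
    + [f"{c}_lag1_sq" for c in MOTION_COLUMNS]
)


@dataclass
class FDSeries:
    """Per-volume Jenkinson framewise displacement (mm); first volume is 0."""

    values: np.ndarray
    mean_fd: float

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("framewise displacement cannot be negative")


@dataclass
class MotionQC:
    excluded: bool
    offenders: list[tuple[int, str, float]] = field(default_factory=list)
    max_trans_mm: float = 0.0
    max_rot_deg: float = 0.0


def discard_initial(
    data: np.ndarray, n_discard: int, motion: np.ndarray | None = None
):
    """Drop the first ``n_discard`` volumes (and paired motion rows)."""
    n_volumes = data.shape[-1]
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if n_discard >= n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {n_volumes} volumes: nothing would remain"
        )
    out = data[..., n_discard:]
    if motion is None:
        return out
    if motion.shape[0] != n_volumes:
        raise ValueError("motion rows do not match volume count")
    return out, motion[n_discard:]


def motion_exclusion(
    motion: np.ndarray, trans_max_mm: float = 1.5, rot_max_deg: float = 1.5
) -> MotionQC:
    """Exclusion decision: any |translation| > trans_max_mm or |rotation| > rot_max_deg.

    Strict inequality — a parameter exactly at the limit is retained.
    """
    motion = np.asarray(motion, dtype=float)
    if np.isnan(motion).any():
        raise ValueError("motion parameters contain NaN")
    offenders: list[tuple[int, str, float]] = []
    limits = [trans_max_mm] * 3 + [rot_max_deg] * 3
    for t, row in enumerate(motion):
        for j, (val, lim) in enumerate(zip(row, limits)):
            if abs(val) > lim:
                offenders.append((t, MOTION_COLUMNS[j], float(val)))
    return MotionQC(
        excluded=bool(offenders),
        offenders=offenders,
        max_trans_mm=float(np.abs(motion[:, :3]).max()),
        max_rot_deg=float(np.abs(motion[:, 3:]).max()),
    )


def _rigid_transform(row: np.ndarray) -> np.ndarray:
    """4x4 rigid transform from (tx,ty,tz mm, rx,ry,rz deg), R = Rx@Ry@Rz."""
    tx, ty, tz = row[:3]
    rx, ry, rz = np.deg2rad(row[3:6])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    T = np.eye(4)
    T[:3, :3] = Rx @ Ry @ Rz
    T[:3, 3] = (tx, ty, tz)
    return T


def jenkinson_fd(motion: np.ndarray, sphere_radius_mm: float = 80.0) -> FDSeries:
    """Jenkinson RMS framewise displacement.

    For consecutive rigid transforms T_{t-1}, T_t the relative motion is
    M = T_t @ T_{t-1}^{-1} - I and
    FD(t) = sqrt( (R^2/5) * trace(A^T A) + b^T b ) with A = M[:3,:3],
    b = M[:3,3], integrating rotation over a sphere of radius R (default
    80 mm). FD(0) = 0 by convention; mean_fd averages volumes 2..n.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes for framewise displacement")
    transforms = [_rigid_transform(row) for row in motion]
    fd = np.zeros(motion.shape[0])
    for t in range(1, len(transforms)):
        M = transforms[t] @ np.linalg.inv(transforms[t - 1]) - np.eye(4)
        A, b = M[:3, :3], M[:3, 3]
        fd[t] = np.sqrt(sphere_radius_mm**2 / 5.0 * np.trace(A.T @ A) + b @ b)
    return FDSeries(values=fd, mean_fd=float(fd[1:].mean()))


def friston24(motion: np.ndarray) -> np.ndarray:
    """Friston 24-parameter expansion: [p, p_lag1, p^2, p_lag1^2].

    The lagged block is the parameters shifted by one volume with the first
    row zero-padded (no wraparound). Column order follows
    ``FRISTON24_COLUMNS``.
    """
    motion = np.asarray(motion, dtype=float)
    lagged = np.vstack([np.zeros((1, motion.shape[1])), motion[:-1]])
    return np.hstack([motion, lagged, motion**2, lagged**2])


def build_nuisance_matrix(
    friston: np.ndarray,
    mean_fd: float,
    wm_ts: np.ndarray,
    csf_ts: np.ndarray,
    global_ts: np.ndarray,
    n_volumes: int,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the 30-column nuisance design.

    Columns: intercept, 24 motion regressors, WM, CSF, global-mean time
    series, linear and quadratic trends. ``mean_fd`` is a per-subject scalar
    and therefore collinear with the intercept at subject level; it is
    accepted here for provenance but contributes no extra column.
    """
    del mean_fd  # constant within subject: absorbed by the intercept
    for name, ts in (("wm_ts", wm_ts), ("csf_ts", csf_ts), ("global_ts", global_ts)):
        if np.asarray(ts).shape[0] != n_volumes:
            raise ValueError(f"{name} has {np.asarray(ts).shape[0]} rows, expected {n_volumes}")
    if friston.shape[0] != n_volumes:
        raise ValueError(
            f"friston matrix has {friston.shape[0]} rows, expected {n_volumes}"
        )
    t = np.linspace(-1.0, 1.0, n_volumes)
    X = np.column_stack(
        [np.ones(n_volumes), friston, wm_ts, csf_ts, global_ts, t, t**2]
    )
    labels = (
        ["intercept"]
        + list(FRISTON24_COLUMNS)
        + ["wm", "csf", "global", "trend_linear", "trend_quadratic"]
    )
    return X, labels


def regress_out(
    data: np.ndarray, regressors: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """OLS residualization of every in-mask voxel time series.

    Uses the Moore-Penrose pseudo-inverse so rank-deficient (collinear)
    designs reduce to the minimum-norm fit instead of failing. Out-of-mask
    voxels are zeroed.
    """
    if regressors.shape[0] != data.shape[-1]:
        raise ValueError("regressor rows must equal the number of volumes")
    Y = data[mask].T  # (T, n_vox)
    beta = np.linalg.pinv(regressors) @ Y
    resid = Y - regressors @ beta
    out = np.zeros_like(data)
    out[mask] = resid.T
    return out


def bandpass_series(
    ts: np.ndarray, low_hz: float, high_hz: float, tr_seconds: float
) -> np.ndarray:
    """Ideal (boxcar) band-pass along axis 0 of a (T, ...) array.

    Fourier bins with frequency < low_hz or > high_hz are zeroed; the DC bin
    is always removed. Idempotent, and exactly energy-preserving on the
    retained bins.
    """
    T = ts.shape[0]
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyquist + 1e-12:
        raise ValueError(f"high_hz {high_hz} exceeds Nyquist {nyquist:.4f} Hz")
    freqs = np.fft.rfftfreq(T, tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    keep[0] = False
    spec = np.fft.rfft(ts, axis=0)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=T, axis=0)


def bandpass(
    data: np.ndarray,
    tr_seconds: float,
    mask: np.ndarray,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
) -> np.ndarray:
    """Band-pass each in-mask voxel of a 4D volume; out-of-mask zeroed."""
    out = np.zeros_like(data)
    out[mask] = bandpass_series(data[mask].T, low_hz, high_hz, tr_seconds).T
    return out


def tissue_proxy_series(
    data: np.ndarray, gm_probability: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean WM-proxy, CSF-proxy and global time series from tissue probability.

    With no separate tissue segmentations available, the probability taper
    around the gray-matter core stands in for the tissue compartments: the
    0.10-0.20 shell as white matter, the 0.02-0.10 shell as CSF; the global
    signal is the mean over the analysis mask (probability > 0.20).
    """
    gm = gm_probability > 0.2
    wm = (gm_probability <= 0.2) & (gm_probability > 0.1)
    csf = (gm_probability <= 0.1) & (gm_probability > 0.02)
    T = data.shape[-1]

    def _mean(m: np.ndarray) -> np.ndarray:
        if not m.any():
            return np.zeros(T)
        return data[m].mean(axis=0)

    return _mean(wm), _mean(csf), _mean(gm)


@dataclass
class PreprocessResult:
    data: np.ndarray
    motion: np.ndarray
    fd: FDSeries
    qc: MotionQC
    nuisance_labels: list[str]


def preprocess_subject(
    data: np.ndarray,
    motion: np.ndarray,
    gm_probability: np.ndarray,
    tr_seconds: float,
    n_discard: int = 10,
    trans_max_mm: float = 1.5,
    rot_max_deg: float = 1.5,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
) -> PreprocessResult:
    """Full temporal pipeline for one subject (in the canonical stage order)."""
    data, motion = discard_initial(data, n_discard, motion)
    qc = motion_exclusion(motion, trans_max_mm, rot_max_deg)
    fd = jenkinson_fd(motion)
    mask = gm_probability > 0.2
    wm_ts, csf_ts, global_ts = tissue_proxy_series(data, gm_probability)
    X, labels = build_nuisance_matrix(
        friston24(motion), fd.mean_fd, wm_ts, csf_ts, global_ts, data.shape[-1]
    )
    cleaned = regress_out(data, X, mask)
    cleaned = bandpass(cleaned, tr_seconds, mask, low_hz, high_hz)
    if qc.excluded:
        warnings.warn(
            f"subject exceeds motion limits ({len(qc.offenders)} offending samples)",
            stacklevel=2,
        )
    return PreprocessResult(
        data=cleaned, motion=motion, fd=fd, qc=qc, nuisance_labels=labels
    )
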