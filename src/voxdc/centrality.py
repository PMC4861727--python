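"""Voxel-wise degree centrality (DC) mapping.

For every voxel inside a gray-matter mask, the Pearson correlation of its
time course with every other in-mask voxel is computed; correlations with
r > r_threshold (strictly, positive side only) count as connections. Degree
centrality is either the connection count (binarized) or the sum of the
supra-threshold r values (weighted). Maps are z-standardized within the mask
and optionally smoothed with a Gaussian kernel.

The pairwise correlation is computed blockwise so the full n x n matrix is
never materialized; the result is exactly the full-matrix computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class DCMap:
    data: np.ndarray  # 3D, zero outside the mask
    mode: str  # "weighted" | "binarized"
    r_threshold: float


def gm_mask(probability: np.ndarray, threshold: float = 0.20) -> np.ndarray:
    """Analysis mask: voxels with tissue probability strictly above threshold."""
    probability = np.asarray(probability)
    if probability.min() < 0 or probability.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    mask = probability > threshold
    if not mask.any():
        raise ValueError(f"empty mask: no probability exceeds {threshold}")
    return mask


def _standardized_timeseries(
    data: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardized (zero-mean, unit-norm) in-mask time series.

    Zero-variance voxels are dropped from the mask with a warning. Returns
    (Z, effective_mask) where Z @ Z.T is the Pearson correlation matrix.
    """
    ts = data[mask].astype(np.float64)
    sd = ts.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance voxels from the mask",
            stacklevel=3,
        )
        idx = np.argwhere(mask)[~keep]
        mask = mask.copy()
        mask[tuple(idx.T)] = False
        ts, sd = ts[keep], sd[keep]
    if ts.shape[0] < 2:
        raise ValueError("mask must retain at least 2 voxels with signal variance")
    ts = ts - ts.mean(axis=1, keepdims=True)
    ts /= np.linalg.norm(ts, axis=1, keepdims=True)
    return ts, mask


def degree_centrality(
    data: np.ndarray,
    mask: np.ndarray,
    r_threshold: float = 0.25,
    mode: str = "weighted",
    block_size: int = 2048,
) -> DCMap:
    """Thresholded-correlation degree centrality of every in-mask voxel.

    Connections are pairs with Pearson r strictly greater than
    ``r_threshold`` (negative correlations never count). Self-pairs are
    excluded. Weighted DC sums the raw r of the connections; binarized DC
    counts them. ``block_size`` bounds memory: at most
    ``block_size * n_mask`` correlations are held at once, and the result is
    independent of the block size.
    """
    if mode not in ("weighted", "binarized"):
        raise ValueError(f"mode must be 'weighted' or 'binarized', got {mode!r}")
    if data.shape[:3] != mask.shape:
        raise ValueError("data and mask grids do not match")
    if data.shape[-1] < 3:
        raise ValueError("need at least 3 time points")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")

    Z, mask = _standardized_timeseries(data, mask)
    n = Z.shape[0]
    dc = np.zeros(n)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        corr = Z[start:stop] @ Z.T  # (block, n)
        corr[np.arange(stop - start), np.arange(start, stop)] = 0.0  # no self-pairs
        supra = corr > r_threshold
        if mode == "binarized":
            dc[start:stop] = supra.sum(axis=1)
        else:
            dc[start:stop] = np.where(supra, corr, 0.0).sum(axis=1)
    out = np.zeros(mask.shape)
    out[mask] = dc
    return DCMap(data=out, mode=mode, r_threshold=r_threshold)


def standardize_z(dc: DCMap | np.ndarray, mask: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Within-mask z-standardization: (DC - mean) / sd, out-of-mask zero.

    Population (divide-by-n) standard deviation by default; pass ``ddof=1``
    for the sample convention (difference is negligible at realistic mask
    sizes).
    """
    arr = dc.data if isinstance(dc, DCMap) else dc
    vals = arr[mask]
    sd = vals.std(ddof=ddof)
    if sd == 0:
        raise ValueError("degree centrality is constant within the mask: cannot z-score")
    out = np.zeros_like(arr, dtype=float)
    out[mask] = (vals - vals.mean()) / sd
    return out


def smooth_map(
    data: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian smoothing over the whole grid, sigma = FWHM / (2 sqrt(2 ln 2)).

    Values outside ``mask`` (if given) are zeroed before convolving; the
    convolution itself runs over the full grid with zero boundary, matching
    standard volumetric-toolkit behavior. ``fwhm_mm=0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    arr = np.asarray(data, dtype=float)
    if mask is not None:
        arr = np.where(mask, arr, 0.0)
    if fwhm_mm == 0:
        return arr.copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / np.asarray(voxel_size_mm, dtype=float)
    return ndimage.gaussian_filter(arr, sigma_vox, mode="constant", cval=0.0)


def dc_zmap(
    data: np.ndarray,
    gm_probability: np.ndarray,
    r_threshold: float = 0.25,
    mode: str = "weighted",
    fwhm_mm: float = 4.0,
    voxel_size_mm=(3.0, 3.0, 3.0),
    gm_threshold: float = 0.20,
    block_size: int = 2048,
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: mask -> DC -> z-score -> smooth. Returns (zmap, mask)."""
    mask = gm_mask(gm_probability, gm_threshold)
    dc = degree_centrality(data, mask, r_threshold, mode, block_size)
    z = standardize_z(dc, mask)
    z = smooth_map(z, fwhm_mm, voxel_size_mm, mask)
    return z, mask
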