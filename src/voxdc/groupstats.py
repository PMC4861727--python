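"""Group-level inference on degree-centrality z-maps.

Voxel-wise two-sample t-maps, Monte Carlo cluster-extent correction (the
AlphaSim procedure: simulate smoothed Gaussian null fields, threshold, and
take the null distribution of the maximum cluster size), cluster reporting
with peak world coordinates, and covariate-adjusted (partial) correlation of
regional DC with a clinical score.

The null simulation thresholds the smoothed, restandardized Gaussian field
one-sidedly at the voxel p by default — the construction used by the AFNI
AlphaSim program — and the derived extent threshold is then applied
separately to the positive and negative suprathreshold sets of the real
t-map. A ``two_sided`` flag switches the null to |z| >= Phi^-1(1 - p/2) with
the per-iteration maximum taken over both sign sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats


@dataclass
class TMap:
    data: np.ndarray
    df: int
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("degrees of freedom must be positive")


def two_sample_t(
    maps_a: list[np.ndarray],
    maps_b: list[np.ndarray],
    mask: np.ndarray,
    equal_var: bool = True,
) -> TMap:
    """Voxel-wise two-sample t (group A minus group B), pooled variance.

    ``equal_var=False`` switches to Welch's t (df still reported as
    n_a + n_b - 2 for the map container; per-voxel Welch df is not retained).
    Zero-variance voxels get t = 0 with a warning.
    """
    n_a, n_b = len(maps_a), len(maps_b)
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects per group")
    A = np.stack([m[mask] for m in maps_a])
    B = np.stack([m[mask] for m in maps_b])
    mean_diff = A.mean(axis=0) - B.mean(axis=0)
    va = A.var(axis=0, ddof=1)
    vb = B.var(axis=0, ddof=1)
    if equal_var:
        pooled = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
        se = np.sqrt(pooled * (1.0 / n_a + 1.0 / n_b))
    else:
        se = np.sqrt(va / n_a + vb / n_b)
    t = np.zeros_like(mean_diff)
    ok = se > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} voxels have zero pooled variance; t set to 0",
            stacklevel=2,
        )
    t[ok] = mean_diff[ok] / se[ok]
    out = np.zeros(mask.shape)
    out[mask] = t
    return TMap(data=out, df=n_a + n_b - 2, n_a=n_a, n_b=n_b)


def neighbor_offsets(rmm_mm: float, voxel_size_mm) -> np.ndarray:
    """Integer voxel offsets whose world-space center distance is <= rmm_mm."""
    if rmm_mm <= 0:
        raise ValueError("rmm_mm must be positive")
    vox = np.asarray(voxel_size_mm, dtype=float)
    reach = np.floor(rmm_mm / vox).astype(int)
    axes = [np.arange(-r, r + 1) for r in reach]
    offs = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    dist = np.linalg.norm(offs * vox, axis=1)
    keep = (dist <= rmm_mm) & (dist > 0)
    return offs[keep]


def _label_structure(offsets: np.ndarray) -> np.ndarray | None:
    """3x3x3 connectivity structure if all offsets fit; else None."""
    if offsets.size and np.abs(offsets).max() <= 1:
        st = np.zeros((3, 3, 3), dtype=bool)
        st[1, 1, 1] = True
        for o in offsets:
            st[tuple(o + 1)] = True
        return st
    return None


def _bfs_label(binary: np.ndarray, offsets: np.ndarray) -> tuple[np.ndarray, int]:
    """Flood-fill labeling for adjacency reaching beyond adjacent voxels."""
    labels = np.zeros(binary.shape, dtype=np.int32)
    current = 0
    coords = {tuple(c) for c in np.argwhere(binary)}
    shape = binary.shape
    for start in sorted(coords):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            v = stack.pop()
            for o in offsets:
                w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if (
                    0 <= w[0] < shape[0]
                    and 0 <= w[1] < shape[1]
                    and 0 <= w[2] < shape[2]
                    and binary[w]
                    and not labels[w]
                ):
                    labels[w] = current
                    stack.append(w)
    return labels, current


def label_clusters(
    binary: np.ndarray, rmm_mm: float, voxel_size_mm
) -> tuple[np.ndarray, np.ndarray]:
    """Connected components under the rmm adjacency.

    Returns (labels, sizes): labels are 1..k ordered by descending size with
    ties broken by the smallest linear (raster) index; sizes[i] is the voxel
    count of label i+1. An empty input yields zero clusters.
    """
    offsets = neighbor_offsets(rmm_mm, voxel_size_mm)
    if offsets.size == 0:
        raise ValueError(
            f"rmm={rmm_mm} mm is below the voxel spacing: no neighbors possible"
        )
    binary = np.asarray(binary, dtype=bool)
    structure = _label_structure(offsets)
    if structure is not None:
        raw, n = ndimage.label(binary, structure=structure)
    else:
        raw, n = _bfs_label(binary, offsets)
    if n == 0:
        return np.zeros(binary.shape, dtype=np.int32), np.zeros(0, dtype=int)
    flat = raw.ravel()
    sizes = np.bincount(flat, minlength=n + 1)[1:]
    # first occurrence in raster order = smallest linear index per label
    first_idx = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    np.minimum.at(first_idx, flat[nz], nz)
    order = sorted(range(1, n + 1), key=lambda lab: (-sizes[lab - 1], first_idx[lab]))
    remap = np.zeros(n + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    labels = remap[raw]
    return labels, sizes[np.array(order) - 1]


def _max_cluster_size(binary: np.ndarray, structure: np.ndarray) -> int:
    lab, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(lab.ravel())[1:].max())


@dataclass
class NullClusterDistribution:
    """Monte Carlo null distribution of the maximum suprathreshold cluster size."""

    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    fwhm_mm: float
    voxel_p: float
    rmm_mm: float
    alpha: float
    n_iterations: int
    seed: int
    two_sided: bool
    max_cluster_sizes: np.ndarray = field(repr=False)
    extent_threshold_voxels: int = 0

    def threshold_for_alpha(self, alpha: float) -> int:
        """Smallest extent k with empirical P(max cluster >= k) <= alpha."""
        if not (0 < alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        maxs = self.max_cluster_sizes
        for k in range(1, int(maxs.max()) + 2):
            if (maxs >= k).mean() <= alpha:
                return k
        return int(maxs.max()) + 1

    def to_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "voxel_size_mm": list(self.voxel_size_mm),
            "fwhm_mm": self.fwhm_mm,
            "voxel_p": self.voxel_p,
            "rmm_mm": self.rmm_mm,
            "alpha": self.alpha,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "two_sided": self.two_sided,
            "extent_threshold_voxels": self.extent_threshold_voxels,
            "max_cluster_sizes": self.max_cluster_sizes.tolist(),
        }


def _simulate_null_field(
    rng: np.random.Generator,
    grid_shape,
    sigma_vox: np.ndarray,
    smooth: bool,
) -> np.ndarray:
    x = rng.standard_normal(grid_shape, dtype=np.float32)
    if smooth:
        # periodic convolution keeps the smoothed field stationary
        x = ndimage.gaussian_filter(x, sigma_vox, mode="wrap")
    x -= x.mean()
    x /= x.std()
    return x


def alphasim_threshold(
    grid_shape,
    voxel_size_mm,
    fwhm_mm: float,
    voxel_p: float,
    rmm_mm: float,
    alpha: float,
    n_iterations: int,
    seed: int,
    two_sided: bool = False,
    mask: np.ndarray | None = None,
) -> NullClusterDistribution:
    """Monte Carlo estimate of the cluster-extent threshold.

    Each iteration draws an independent standard Gaussian field on the grid,
    smooths it to the stated FWHM, restandardizes to zero mean / unit
    variance (smoothing deflates the variance, which would otherwise
    miscalibrate the voxel p), thresholds at the Gaussian quantile for
    ``voxel_p`` (one-sided by default; two-sided takes the maximum over the
    positive and negative suprathreshold sets), and records the maximum
    cluster size under the rmm adjacency. The extent threshold is the
    smallest size whose null exceedance probability is <= alpha.
    """
    if not (0 < voxel_p < 1):
        raise ValueError("voxel_p must be in (0, 1)")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    grid_shape = tuple(int(s) for s in grid_shape)
    voxel_size_mm = tuple(float(v) for v in voxel_size_mm)
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / np.asarray(voxel_size_mm)
    if fwhm_mm > 0 and np.any(sigma_vox * 2 > np.asarray(grid_shape)):
        raise ValueError("smoothing kernel is too large for the grid")
    offsets = neighbor_offsets(rmm_mm, voxel_size_mm)
    structure = _label_structure(offsets)
    if structure is None:
        raise ValueError("rmm adjacency beyond adjacent voxels is not supported here")
    if mask is not None and mask.shape != grid_shape:
        raise ValueError("mask shape does not match grid_shape")

    zthr = (
        stats.norm.ppf(1 - voxel_p / 2) if two_sided else stats.norm.ppf(1 - voxel_p)
    )
    rng = np.random.default_rng(seed)
    maxs = np.zeros(n_iterations, dtype=np.int64)
    for i in range(n_iterations):
        x = _simulate_null_field(rng, grid_shape, sigma_vox, fwhm_mm > 0)
        if mask is not None:
            x = np.where(mask, x, -np.inf)
        m = _max_cluster_size(x >= zthr, structure)
        if two_sided:
            neg = np.where(mask, x, np.inf) if mask is not None else x
            m = max(m, _max_cluster_size(neg <= -zthr, structure))
        maxs[i] = m

    dist = NullClusterDistribution(
        grid_shape=grid_shape,
        voxel_size_mm=voxel_size_mm,
        fwhm_mm=fwhm_mm,
        voxel_p=voxel_p,
        rmm_mm=rmm_mm,
        alpha=alpha,
        n_iterations=n_iterations,
        seed=seed,
        two_sided=two_sided,
        max_cluster_sizes=maxs,
    )
    dist.extent_threshold_voxels = dist.threshold_for_alpha(alpha)
    return dist


def null_fwe_rate(
    null: NullClusterDistribution,
    extent_threshold: int,
    n_replicates: int,
    seed: int,
) -> float:
    """Family-wise false-positive rate of the extent rule on fresh null fields.

    Replays the same null construction as ``alphasim_threshold`` with an
    independent seed and measures the fraction of fields with any cluster of
    size >= extent_threshold.
    """
    sigma_vox = (
        null.fwhm_mm
        / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        / np.asarray(null.voxel_size_mm)
    )
    structure = _label_structure(neighbor_offsets(null.rmm_mm, null.voxel_size_mm))
    zthr = (
        stats.norm.ppf(1 - null.voxel_p / 2)
        if null.two_sided
        else stats.norm.ppf(1 - null.voxel_p)
    )
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        x = _simulate_null_field(rng, null.grid_shape, sigma_vox, null.fwhm_mm > 0)
        m = _max_cluster_size(x >= zthr, structure)
        if null.two_sided:
            m = max(m, _max_cluster_size(x <= -zthr, structure))
        if m >= extent_threshold:
            hits += 1
    return hits / n_replicates


CLUSTER_TABLE_COLUMNS = [
    "cluster_id",
    "sign",
    "extent_voxels",
    "volume_mm3",
    "peak_x",
    "peak_y",
    "peak_z",
    "peak_t",
]


def cluster_report(
    tmap: TMap,
    voxel_p: float,
    extent_threshold: int,
    rmm_mm: float,
    voxel_size_mm,
    affine: np.ndarray,
) -> pd.DataFrame:
    """Suprathreshold clusters surviving the extent threshold.

    The voxel threshold is the two-sided t quantile |t| >= t_{1 - p/2, df};
    positive and negative suprathreshold sets are clustered separately.
    Each surviving cluster is reported with extent (voxels), volume
    (extent x voxel volume, mm^3), the world coordinate of the peak |t|
    voxel (ties broken by smallest raster index) and the signed peak t.
    Rows are ordered by descending extent, ties by peak raster index, so the
    table is equivariant under t-map negation up to the sign columns.
    """
    if extent_threshold < 1:
        raise ValueError("extent_threshold must be >= 1")
    tthr = stats.t.ppf(1 - voxel_p / 2, tmap.df)
    vox_vol = float(np.prod(voxel_size_mm))
    rows = []
    for sign, binary in (("+", tmap.data >= tthr), ("-", tmap.data <= -tthr)):
        if not binary.any():
            continue
        labels, sizes = label_clusters(binary, rmm_mm, voxel_size_mm)
        for lab, size in enumerate(sizes, start=1):
            if size < extent_threshold:
                continue
            in_cluster = labels == lab
            absval = np.where(in_cluster, np.abs(tmap.data), -np.inf)
            peak_flat = int(np.argmax(absval))  # first max = smallest raster index
            peak_vox = np.unravel_index(peak_flat, tmap.data.shape)
            world = affine @ np.array([*peak_vox, 1.0])
            rows.append(
                {
                    "sign": sign,
                    "extent_voxels": int(size),
                    "volume_mm3": float(size * vox_vol),
                    "peak_x": float(world[0]),
                    "peak_y": float(world[1]),
                    "peak_z": float(world[2]),
                    "peak_t": float(tmap.data[peak_vox]),
                    "_peak_flat": peak_flat,
                }
            )
    rows.sort(key=lambda r: (-r["extent_voxels"], r["_peak_flat"]))
    for i, r in enumerate(rows, start=1):
        r["cluster_id"] = i
        del r["_peak_flat"]
    return pd.DataFrame(rows, columns=CLUSTER_TABLE_COLUMNS)


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray
) -> tuple[float, float, int]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on [intercept, covariates] by least
    squares; the correlation of the residuals is tested against the t
    distribution with df = n - n_covariates - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != x.shape[0]:
        covariates = covariates.T
    n = x.shape[0]
    n_cov = covariates.shape[1]
    if n <= n_cov + 3:
        raise ValueError(f"need n > n_covariates + 3 (n={n}, covariates={n_cov})")
    X = np.column_stack([np.ones(n), covariates])
    pinv = np.linalg.pinv(X)
    rx = x - X @ (pinv @ x)
    ry = y - X @ (pinv @ y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("constant residuals: partial correlation undefined")
    r = float(np.dot(rx, ry) / (np.linalg.norm(rx) * np.linalg.norm(ry)))
    df = n - n_cov - 2
    r_clamped = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    tstat = r_clamped * np.sqrt(df / (1.0 - r_clamped**2))
    p = float(2.0 * stats.t.sf(abs(tstat), df))
    return r, p, n


def extract_region_z(zmaps: list[np.ndarray], region: np.ndarray) -> np.ndarray:
    """Per-subject mean z over a region of interest."""
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("region is empty")
    return np.array([z[region].mean() for z in zmaps])
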