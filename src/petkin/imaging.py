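"""Voxelwise maps, group statistics, cluster thresholding and mask algebra.

Grids are plain 3-D numpy arrays with voxel dimensions in mm; 4-D dynamic
data are (x, y, z, frame).  All volumes entering one operation must share a
grid — no resampling is done here.  Missing voxels are NaN and are excluded
from means, smoothing normalisation and t-statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .frames import FrameSchedule, TimeActivityCurve
from .kinetics import _srtm_fit_many, _resolve_weights, default_theta3_grid, patlak_integral

__all__ = [
    "LabelVolume", "ParametricMap", "ClusterConfig", "fit_parametric_map",
    "smooth_map", "group_tmap", "threshold_clusters", "cluster_extent_mc",
    "intersect_masks", "posterior_cerebellum_mask", "extract_roi",
    "dice_coefficient", "fwhm_to_sigma",
]


def fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class LabelVolume:
    """Integer-labelled 3-D grid (0 = background).

    ``ap_axis`` names the anterior→posterior axis and ``anterior_low``
    says whether index 0 along it is the anterior end (used by the
    posterior-cerebellum rule).
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ap_axis: int = 1
    anterior_low: bool = True

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("labels must be a 3-D integer array")
        if np.any(np.asarray(self.voxel_size_mm) <= 0):
            raise ValueError("voxel dimensions must be positive")
        if np.any(self.data < 0):
            raise ValueError("labels must be >= 0")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def to_nifti(self, path) -> None:
        affine = np.diag(list(self.voxel_size_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.int16), affine), str(path))

    @classmethod
    def from_nifti(cls, path, **kw) -> "LabelVolume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj).astype(np.int32),
                   tuple(float(z) for z in img.header.get_zooms()[:3]), **kw)


@dataclass
class ParametricMap:
    """3-D float grid of a fitted quantity (Ki, BP_ND, t, mask)."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    quantity: str = "map"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("map must be 3-D")
        if np.any(np.asarray(self.voxel_size_mm) <= 0):
            raise ValueError("voxel dimensions must be positive")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def to_nifti(self, path) -> None:
        affine = np.diag(list(self.voxel_size_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path, quantity="map") -> "ParametricMap":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=float),
                   tuple(float(z) for z in img.header.get_zooms()[:3]), quantity)


@dataclass(frozen=True)
class ClusterConfig:
    """Cluster-forming p threshold + minimum extent, with connectivity."""

    p_threshold: float = 0.001
    df: int = 39
    k_min: int = 55
    connectivity: int = 6     # face (6), edge (18) or corner (26) adjacency
    two_tailed: bool = True

    def __post_init__(self):
        if not (0 < self.p_threshold < 1):
            raise ValueError("p threshold must be in (0, 1)")
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.df < 1:
            raise ValueError("df must be >= 1")


_STRUCTS = {6: 1, 18: 2, 26: 3}


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, _STRUCTS[connectivity])


def fit_parametric_map(dynamic: np.ndarray, schedule: FrameSchedule,
                       ref: TimeActivityCurve, model: str,
                       voxel_size_mm=(1.0, 1.0, 1.0), t_star: float = 25.0,
                       theta3_grid: np.ndarray | None = None,
                       weights=None) -> ParametricMap:
    """Apply the Patlak or SRTM fit voxel by voxel to a 4-D volume.

    Voxels that violate the scalar fit's preconditions (all-zero or
    non-finite series) become NaN rather than raising.
    """
    dynamic = np.asarray(dynamic, dtype=float)
    if dynamic.ndim != 4 or dynamic.shape[-1] != schedule.n_frames:
        raise ValueError("dynamic volume must be (x, y, z, n_frames)")
    if ref.schedule != schedule:
        raise ValueError("reference TAC schedule does not match the dynamic data")
    shape = dynamic.shape[:3]
    Y = dynamic.reshape(-1, schedule.n_frames)
    ok = np.all(np.isfinite(Y), axis=1) & np.any(Y != 0, axis=1)
    out = np.full(Y.shape[0], np.nan)
    if model == "patlak":
        sel = schedule.midpoints >= t_star
        if sel.sum() < 3 or np.any(ref.activity[sel] <= 0):
            raise ValueError("invalid Patlak window for this schedule/reference")
        x = (patlak_integral(ref) / ref.activity)[sel]
        X = np.column_stack([x, np.ones_like(x)])
        pinv = np.linalg.pinv(X)
        yy = Y[ok][:, sel] / ref.activity[sel]
        out[ok] = (yy @ pinv.T)[:, 0]
    elif model == "srtm":
        grid = default_theta3_grid() if theta3_grid is None else np.asarray(theta3_grid, float)
        w = _resolve_weights(weights, schedule)
        if ok.any():
            _, _, _, bp, _ = _srtm_fit_many(Y[ok], ref, grid, w)
            out[ok] = bp
    else:
        raise ValueError(f"unknown model {model!r}")
    tag = "Ki" if model == "patlak" else "BP_ND"
    return ParametricMap(out.reshape(shape), tuple(voxel_size_mm), tag)


def smooth_map(pmap: ParametricMap, fwhm_mm: float) -> ParametricMap:
    """Gaussian smoothing in mm with NaN-aware renormalisation.

    Missing voxels contribute nothing; the kernel is renormalised over the
    defined voxels so a constant map stays constant.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be >= 0")
    if fwhm_mm == 0:
        return ParametricMap(pmap.data.copy(), pmap.voxel_size_mm, pmap.quantity,
                             dict(pmap.meta))
    sigma = [fwhm_to_sigma(fwhm_mm) / v for v in pmap.voxel_size_mm]
    valid = np.isfinite(pmap.data)
    filled = np.where(valid, pmap.data, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=sigma, mode="constant", truncate=6.0)
    den = ndimage.gaussian_filter(valid.astype(float), sigma=sigma, mode="constant",
                                  truncate=6.0)
    out = np.full(pmap.data.shape, np.nan)
    nz = den > 1e-12
    out[nz & valid] = num[nz & valid] / den[nz & valid]
    return ParametricMap(out, pmap.voxel_size_mm, pmap.quantity, dict(pmap.meta))


def group_tmap(maps_a, maps_b=None, mode: str = "one_sample") -> ParametricMap:
    """Voxelwise t map: one-sample against 0, or paired on a - b.

    Zero-variance voxels (and voxels missing in any subject) are NaN.
    Degrees of freedom (n - 1) are stored in ``meta['df']``.
    """
    A = np.stack([m.data for m in maps_a])
    if mode == "paired":
        if maps_b is None:
            raise ValueError("paired mode needs maps_b")
        B = np.stack([m.data for m in maps_b])
        if B.shape != A.shape:
            raise ValueError("paired map stacks must have equal shape")
        A = A - B
    elif mode != "one_sample":
        raise ValueError(f"unknown mode {mode!r}")
    n = A.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mean = np.nanmean(A, axis=0)
    sd = np.nanstd(A, axis=0, ddof=1)
    complete = np.all(np.isfinite(A), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~complete | (sd == 0)] = np.nan
    return ParametricMap(t, maps_a[0].voxel_size_mm, "t", {"df": n - 1, "n": n})


def threshold_clusters(tmap: ParametricMap, cc: ClusterConfig):
    """Suprathreshold connected components with a minimum-extent filter.

    Positive and negative excursions are clustered separately (a cluster is
    a same-sign component).  Returns a boolean mask of surviving voxels and
    a table (sign, size, peak coordinate at the largest |t|, ties resolved
    to the lowest linear index, peak t).
    """
    t = tmap.data
    if not np.any(np.isfinite(t)):
        raise ValueError("t map has no defined voxels")
    if cc.two_tailed:
        t_crit = sps.t.ppf(1.0 - cc.p_threshold / 2.0, cc.df)
    else:
        t_crit = sps.t.ppf(1.0 - cc.p_threshold, cc.df)
    struct = _structure(cc.connectivity)
    mask = np.zeros(t.shape, dtype=bool)
    rows = []
    signs = [(1, np.nan_to_num(t) > t_crit)]
    if cc.two_tailed:
        signs.append((-1, np.nan_to_num(t) < -t_crit))
    for sign, supra in signs:
        lab, n_lab = ndimage.label(supra, structure=struct)
        for i in range(1, n_lab + 1):
            comp = lab == i
            size = int(comp.sum())
            if size < cc.k_min:
                continue
            mask |= comp
            flat = np.flatnonzero(comp.ravel())
            peak_flat = flat[np.argmax(np.abs(t.ravel()[flat]))]
            peak = np.unravel_index(peak_flat, t.shape)
            rows.append({"sign": sign, "size_voxels": size,
                         "volume_mm3": size * tmap.voxel_volume,
                         "peak_x": peak[0], "peak_y": peak[1], "peak_z": peak[2],
                         "peak_t": float(t[peak])})
    table = pd.DataFrame(rows, columns=["sign", "size_voxels", "volume_mm3",
                                        "peak_x", "peak_y", "peak_z", "peak_t"])
    table = table.sort_values("size_voxels", ascending=False, ignore_index=True)
    return mask, table


def cluster_extent_mc(search_mask: np.ndarray, voxel_size_mm, fwhm_mm: float,
                      p_thresh: float = 0.001, alpha: float = 0.05,
                      n_iter: int = 1000, seed: int = 0,
                      connectivity: int = 6) -> int:
    """Monte-Carlo minimum cluster extent controlling family-wise error.

    Simulates Gaussian white noise on the grid, smooths it to the stated
    FWHM, standardises within the search mask, thresholds |z| at the
    two-tailed ``p_thresh``, and records the largest suprathreshold cluster
    per iteration.  Returns the smallest k with P(max cluster >= k) <= alpha
    under this null — the same calibration idea as AFNI's 3dClustSim.
    """
    search_mask = np.asarray(search_mask, dtype=bool)
    if not search_mask.any():
        raise ValueError("search mask is empty")
    if n_iter < 100:
        raise ValueError("need at least 100 iterations")
    rng = np.random.default_rng(seed)
    sigma = [fwhm_to_sigma(fwhm_mm) / v for v in voxel_size_mm]
    z_crit = sps.norm.ppf(1.0 - p_thresh / 2.0)
    struct = _structure(connectivity)
    max_sizes = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        noise = rng.standard_normal(search_mask.shape)
        if fwhm_mm > 0:
            noise = ndimage.gaussian_filter(noise, sigma=sigma, mode="constant")
        vals = noise[search_mask]
        noise = (noise - vals.mean()) / vals.std(ddof=1)
        supra = (np.abs(noise) > z_crit) & search_mask
        if supra.any():
            lab, n_lab = ndimage.label(supra, structure=struct)
            max_sizes[it] = np.bincount(lab.ravel())[1:].max()
    # smallest k with empirical P(max >= k) <= alpha
    max_sizes.sort()
    for k in range(1, int(max_sizes[-1]) + 2):
        exceed = n_iter - np.searchsorted(max_sizes, k, side="left")
        if exceed / n_iter <= alpha:
            return int(k)
    return int(max_sizes[-1]) + 1  # pragma: no cover


def intersect_masks(masks, voxel_size_mm=(1.0, 1.0, 1.0)):
    """Logical AND of boolean masks; returns (mask, volume in mm^3)."""
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if not masks:
        raise ValueError("no masks given")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("masks are on different grids")
    out = masks[0].copy()
    for m in masks[1:]:
        out &= m
    return out, float(out.sum() * np.prod(voxel_size_mm))


def posterior_cerebellum_mask(cerebellum: LabelVolume,
                              remove_fraction: float = 0.25) -> np.ndarray:
    """Drop the most anterior coronal slices of a cerebellar label.

    Among the slices along the anterior-posterior axis that contain the
    label, the most anterior round(fraction * n_slices) slices are cleared
    (round half up), limiting spill-in from midbrain dopamine nuclei when
    the remainder is used as the reference region.
    """
    if not (0 <= remove_fraction < 1):
        raise ValueError("remove_fraction must be in [0, 1)")
    mask = cerebellum.data > 0
    if not mask.any():
        raise ValueError("cerebellum label is empty")
    axis = cerebellum.ap_axis
    has = np.any(mask, axis=tuple(i for i in range(3) if i != axis))
    idx = np.flatnonzero(has)
    n_remove = int(np.floor(remove_fraction * idx.size + 0.5))
    if n_remove:
        drop = idx[:n_remove] if cerebellum.anterior_low else idx[-n_remove:]
        sl = [slice(None)] * 3
        out = mask.copy()
        for d in drop:
            sl[axis] = d
            out[tuple(sl)] = False
        return out
    return mask


def extract_roi(data, labels: LabelVolume, label_id: int,
                schedule: FrameSchedule | None = None):
    """Mean over an ROI's voxels, ignoring NaNs.

    3-D input returns (value, volume_mm3); 4-D input with a schedule
    returns (TimeActivityCurve, volume_mm3).
    """
    arr = data.data if isinstance(data, ParametricMap) else np.asarray(data, dtype=float)
    roi = labels.data == label_id
    if not roi.any():
        raise ValueError(f"label {label_id} not present")
    volume = float(roi.sum() * labels.voxel_volume)
    if arr.ndim == 3:
        vals = arr[roi]
        if np.all(np.isnan(vals)):
            raise ValueError("ROI contains no defined voxels")
        return float(np.nanmean(vals)), volume
    if arr.ndim == 4:
        if schedule is None:
            raise ValueError("dynamic input needs a frame schedule")
        tac = np.nanmean(arr[roi, :], axis=0)
        return TimeActivityCurve(schedule, tac), volume
    raise ValueError("data must be 3-D or 4-D")


def dice_coefficient(mask_a, mask_b) -> float:
    """Sorensen-Dice overlap 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks are on different grids")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
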