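"""ROI-based geometric transfer matrix (GTM) partial-volume correction.

Scanner resolution mixes signal across regions: each observed regional mean
is a weighted combination of the true means, with weights given by how much
of each region's PSF-smoothed indicator falls inside the target region.
Collecting those weights in a matrix omega and solving
``omega @ true = observed`` undoes the mixing at the ROI level (Rousset-style
correction).  The non-ROI remainder of the grid is always included as an
explicit background region so each row of omega is a partition of unity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._psf import psf_blur
from .imaging import LabelVolume, fwhm_to_sigma

__all__ = ["GTMatrix", "gtm_matrix", "gtm_correct"]


@dataclass(frozen=True)
class GTMatrix:
    """Observed-signal fractions omega[i, j]: share of region j's signal seen
    in region i, rows ordered by ``region_ids`` (background id -1 denotes
    everything unlabelled)."""

    omega: np.ndarray
    region_ids: tuple[int, ...]

    def __post_init__(self):
        om = np.asarray(self.omega, dtype=float)
        if om.ndim != 2 or om.shape[0] != om.shape[1] or om.shape[0] != len(self.region_ids):
            raise ValueError("omega must be square and match region_ids")
        if np.any(om < -1e-9) or np.any(om > 1 + 1e-9):
            raise ValueError("omega entries must lie in [0, 1]")
        object.__setattr__(self, "omega", om)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.omega, index=self.region_ids, columns=self.region_ids)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.omega))


BACKGROUND_ID = -1


def gtm_matrix(labels: LabelVolume, fwhm_mm: float,
               include_background: bool = True) -> GTMatrix:
    """omega[i, j] = mean over region i's voxels of region j's smoothed indicator."""
    if fwhm_mm < 0:
        raise ValueError("FWHM must be >= 0")
    ids = [int(i) for i in np.unique(labels.data) if i != 0]
    if not ids:
        raise ValueError("no labelled regions")
    if include_background:
        ids = ids + [BACKGROUND_ID]
    masks = []
    for rid in ids:
        m = (labels.data == 0) if rid == BACKGROUND_ID else (labels.data == rid)
        if not m.any():
            raise ValueError(f"region {rid} is empty")
        masks.append(m)
    sigma = [fwhm_to_sigma(fwhm_mm) / v for v in labels.voxel_size_mm]
    omega = np.empty((len(ids), len(ids)))
    for j, mj in enumerate(masks):
        # box-integrated kernel + "nearest" edges keep the smoothed
        # indicators a partition of unity, so rows of omega sum to 1
        sm = psf_blur(mj.astype(float), sigma)
        for i, mi in enumerate(masks):
            omega[i, j] = sm[mi].mean()
    return GTMatrix(np.clip(omega, 0.0, 1.0), tuple(ids))


def gtm_correct(observed_means, gtm: GTMatrix, cond_max: float = 1e8) -> np.ndarray:
    """Solve omega @ corrected = observed for the true regional means."""
    obs = np.asarray(observed_means, dtype=float)
    if obs.shape != (len(gtm.region_ids),):
        raise ValueError("observed means must match the GTM's region order")
    cond = gtm.condition_number
    if not np.isfinite(cond) or cond > cond_max:
        raise np.linalg.LinAlgError(
            f"GTM is ill-conditioned (condition number {cond:.3g})")
    return np.linalg.solve(gtm.omega, obs)
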