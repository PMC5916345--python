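"""Reference-region kinetic models for dynamic PET.

Two models cover the two tracer classes used in striatal dopamine imaging:

* :class:`PatlakModel` — graphical analysis for irreversibly trapped
  tracers.  With a reference-tissue input, the plot of tissue/reference
  against (cumulative reference integral)/reference becomes linear once the
  free compartment equilibrates (t >= t*); the slope is the net influx rate
  Ki scaled to the distribution volume of the reference region.  For an
  AADC substrate, Ki = k2*k3/(k2+k3) indexes dopamine synthesis capacity.

* :class:`SRTMModel` — the simplified reference tissue model fitted with
  basis functions.  The operational equation

      C_T(t) = R1*C_R(t) + (k2 - R1*k2a) * (C_R ⊗ exp(-k2a*t))

  is linear in (theta1, theta2) = (R1, k2 - R1*k2a) once theta3 = k2a is
  fixed, so the fit is a 1-D grid search over theta3 with a weighted linear
  least-squares solve per basis.  BP_ND = k2/theta3 - 1 is the
  non-displaceable binding potential, f_ND * B_avail / K_D.

Both follow the statsmodels convention: construct the model from data, call
``fit()``, get a results object with estimates, diagnostics and
``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._grid import expconv, fine_curve_from_frames
from .frames import FrameSchedule, TimeActivityCurve

__all__ = [
    "PatlakModel", "PatlakResults", "SRTMModel", "SRTMResults",
    "patlak_fit", "srtm_fit", "ReceptorParams", "bpnd_from_receptors",
    "percent_change", "ReleaseResult", "default_theta3_grid",
    "patlak_integral",
]

BASIS_DT = 0.1  # minutes; internal grid for basis-function convolution


def patlak_integral(ref: TimeActivityCurve) -> np.ndarray:
    """Cumulative integral of the reference TAC at frame midpoints.

    Trapezoid rule on the midpoint samples with an implicit (0, 0) origin,
    the standard discretisation for graphical analyses of frame data.
    """
    t = np.concatenate([[0.0], ref.midpoints])
    y = np.concatenate([[0.0], ref.activity])
    return np.cumsum(np.diff(t) * (y[1:] + y[:-1]) / 2.0)


def default_theta3_grid(n: int = 128, lo: float = 0.006, hi: float = 0.6) -> np.ndarray:
    """Log-spaced theta3 (=k2a) grid, 1/min, bracketing plausible clearances."""
    return np.geomspace(lo, hi, n)


# ---------------------------------------------------------------------------
# Patlak


@dataclass(frozen=True)
class PatlakResults:
    """Graphical-analysis fit: slope Ki (1/min), unitless intercept.

    ``x`` and ``y`` are the Patlak-transformed points used in the fit
    (normalised integral vs normalised tissue), kept for diagnostics.
    """

    ki: float
    intercept: float
    r_squared: float
    n_frames_used: int
    t_star: float
    x: np.ndarray | None = None
    y: np.ndarray | None = None

    def summary(self) -> str:
        return (
            "Patlak graphical analysis (reference-tissue input)\n"
            f"  Ki (slope)     {self.ki: .6f} 1/min\n"
            f"  intercept      {self.intercept: .6f}\n"
            f"  r-squared      {self.r_squared: .6f}\n"
            f"  frames used    {self.n_frames_used} (midpoint >= {self.t_star:g} min)\n"
        )

    def plot(self, ax=None):  # pragma: no cover - thin QC helper
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        if self.x is not None:
            ax.plot(self.x, self.y, "o", label="frames")
            ax.plot(self.x, self.ki * self.x + self.intercept, "-",
                    label=f"Ki={self.ki:.4g}/min")
            ax.legend()
        ax.set_xlabel("∫ref / ref (min)")
        ax.set_ylabel("tissue / ref")
        ax.set_title("Patlak plot")
        return ax


class PatlakModel:
    """Patlak plot of an irreversible-tracer TAC against a reference TAC."""

    def __init__(self, tissue: TimeActivityCurve, ref: TimeActivityCurve):
        if tissue.schedule != ref.schedule:
            raise ValueError("tissue and reference schedules differ")
        self.tissue = tissue
        self.ref = ref

    def fit(self, t_star: float = 25.0) -> PatlakResults:
        sel = self.tissue.midpoints >= t_star
        if sel.sum() < 3:
            raise ValueError(f"need >= 3 frames with midpoint >= t_star={t_star}")
        ref_act = self.ref.activity
        if np.any(ref_act[sel] <= 0):
            raise ValueError("reference activity must be positive in the fit window")
        x = (patlak_integral(self.ref) / ref_act)[sel]
        y = (self.tissue.activity / ref_act)[sel]
        slope, intercept, ssr, sst = _ols_line(x, y)
        r2 = 1.0 if sst == 0 else max(0.0, 1.0 - ssr / sst)
        return PatlakResults(ki=slope, intercept=intercept, r_squared=r2,
                             n_frames_used=int(sel.sum()), t_star=float(t_star),
                             x=x, y=y)


def _ols_line(x, y):
    X = np.column_stack([x, np.ones_like(x)])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    ssr = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return float(beta[0]), float(beta[1]), ssr, sst


def patlak_fit(tissue: TimeActivityCurve, ref: TimeActivityCurve,
               t_star: float = 25.0) -> PatlakResults:
    """Convenience wrapper: ``PatlakModel(tissue, ref).fit(t_star)``."""
    return PatlakModel(tissue, ref).fit(t_star=t_star)


# ---------------------------------------------------------------------------
# SRTM


@dataclass(frozen=True)
class SRTMResults:
    """Basis-function SRTM fit.

    ``bp_nd = k2/theta3 - 1``; ``theta3`` is the clearance of the apparent
    single tissue compartment (k2a = k2/(1+BP_ND)).
    """

    r1: float
    k2: float
    theta3: float
    bp_nd: float
    rss: float
    fitted: np.ndarray | None = None  # model curve at the frame midpoints

    def summary(self) -> str:
        return (
            "Simplified reference tissue model (basis functions)\n"
            f"  R1             {self.r1: .6f}\n"
            f"  k2             {self.k2: .6f} 1/min\n"
            f"  theta3 (k2a)   {self.theta3: .6f} 1/min\n"
            f"  BP_ND          {self.bp_nd: .6f}\n"
            f"  RSS            {self.rss: .6g}\n"
        )


class SRTMModel:
    """Simplified reference tissue model fitted over a theta3 basis grid.

    Parameters
    ----------
    tissue, ref : TimeActivityCurve
        Target and reference-region TACs on the same schedule.
    theta3_grid : array, optional
        Sorted positive k2a candidates (1/min); default 128 log-spaced
        values in [0.006, 0.6].
    weights : None or "frame_duration"
        Per-frame weights for the least-squares solve.  Uniform by default.
    """

    def __init__(self, tissue: TimeActivityCurve, ref: TimeActivityCurve,
                 theta3_grid: np.ndarray | None = None,
                 weights: str | np.ndarray | None = None):
        if tissue.schedule != ref.schedule:
            raise ValueError("tissue and reference schedules differ")
        if not np.any(ref.activity != 0):
            raise ValueError("reference TAC is identically zero")
        if theta3_grid is None:
            theta3_grid = default_theta3_grid()
        grid = np.asarray(theta3_grid, dtype=float)
        if grid.size == 0 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("theta3_grid must be nonempty, positive, strictly increasing")
        self.tissue = tissue
        self.ref = ref
        self.theta3_grid = grid
        self.weights = _resolve_weights(weights, tissue.schedule)
        self._basis = srtm_basis(ref, grid)

    def fit(self) -> SRTMResults:
        y = self.tissue.activity
        if np.all(np.isnan(y)):
            raise ValueError("tissue TAC is all-NaN")
        r1, k2, th3, bp, rss = _srtm_fit_many(
            y[None, :], self.ref, self.theta3_grid, self.weights, basis=self._basis)
        j = int(np.argmin(np.abs(self.theta3_grid - th3[0])))
        theta2 = k2[0] - r1[0] * th3[0]
        fitted = r1[0] * self.ref.activity + theta2 * self._basis[j]
        return SRTMResults(r1=float(r1[0]), k2=float(k2[0]), theta3=float(th3[0]),
                           bp_nd=float(bp[0]), rss=float(rss[0]), fitted=fitted)


def _resolve_weights(weights, schedule: FrameSchedule) -> np.ndarray:
    if weights is None:
        return np.ones(schedule.n_frames)
    if isinstance(weights, str):
        if weights == "frame_duration":
            return schedule.frame_durations.copy()
        raise ValueError(f"unknown weighting {weights!r}")
    w = np.asarray(weights, dtype=float)
    if w.shape != (schedule.n_frames,) or np.any(w < 0):
        raise ValueError("weights must be nonnegative, one per frame")
    return w


def srtm_basis(ref: TimeActivityCurve, theta3_grid: np.ndarray,
               dt: float = BASIS_DT) -> np.ndarray:
    """Frame-averaged basis functions B_j = C_R ⊗ exp(-theta3_j * t).

    The reference curve is reconstructed on a fine uniform grid (linear
    through the frame midpoints with a (0,0) origin), convolved exactly for
    that interpolant, then averaged over frames.  Returns (n_theta, n_frames).
    """
    from ._grid import frame_average
    t, fine = fine_curve_from_frames(ref, dt)
    out = np.empty((theta3_grid.size, ref.schedule.n_frames))
    for j, th in enumerate(theta3_grid):
        out[j] = frame_average(t, expconv(fine, th, dt), ref.schedule)
    return out


def _srtm_fit_many(Y: np.ndarray, ref: TimeActivityCurve, grid: np.ndarray,
                   weights: np.ndarray, basis: np.ndarray | None = None):
    """Vectorised basis-function SRTM over rows of Y (n_series, n_frames).

    For each theta3 the design is [ref, B(theta3)]; the weighted normal
    equations are solved in closed form for all series at once.  Ties in
    RSS resolve to the smallest theta3 (first minimum on the sorted grid).
    """
    if basis is None:
        basis = srtm_basis(ref, grid)
    r = ref.activity
    w = weights
    Yw = Y * w  # (n, F)
    rr = float(np.sum(w * r * r))
    n_series = Y.shape[0]
    best_rss = np.full(n_series, np.inf)
    best_t1 = np.zeros(n_series)
    best_t2 = np.zeros(n_series)
    best_j = np.zeros(n_series, dtype=int)
    yy = np.sum(w * Y * Y, axis=1)
    ry = Yw @ r
    for j in range(grid.size):
        b = basis[j]
        rb = float(np.sum(w * r * b))
        bb = float(np.sum(w * b * b))
        det = rr * bb - rb * rb
        if det <= 0 or not np.isfinite(det):
            raise np.linalg.LinAlgError(
                "singular SRTM design (reference and basis collinear or zero)")
        by = Yw @ b
        t1 = (bb * ry - rb * by) / det
        t2 = (rr * by - rb * ry) / det
        rss = yy - t1 * ry - t2 * by  # y'Wy - beta' X'Wy
        # strict improvement only: on exact RSS ties the earlier (smaller)
        # theta3 is kept, the conservative smooth solution
        better = rss < best_rss
        if np.any(better):
            best_rss[better] = rss[better]
            best_t1[better] = t1[better]
            best_t2[better] = t2[better]
            best_j[better] = j
    theta3 = grid[best_j]
    r1 = best_t1
    k2 = best_t2 + best_t1 * theta3
    bp = k2 / theta3 - 1.0
    return r1, k2, theta3, bp, np.maximum(best_rss, 0.0)


def srtm_fit(tissue: TimeActivityCurve, ref: TimeActivityCurve,
             theta3_grid: np.ndarray | None = None,
             weights: str | np.ndarray | None = None) -> SRTMResults:
    """Convenience wrapper: ``SRTMModel(tissue, ref, ...).fit()``."""
    return SRTMModel(tissue, ref, theta3_grid=theta3_grid, weights=weights).fit()


# ---------------------------------------------------------------------------
# Receptor-parameter identities


@dataclass(frozen=True)
class ReceptorParams:
    """Receptor-level determinants of BP_ND for a reversible antagonist."""

    bavail: float  # nM, available receptor concentration
    kd: float      # nM, dissociation constant (raclopride: 1.2 nM)
    fnd: float = 1.0  # free fraction in the non-displaceable compartment

    def __post_init__(self):
        if self.bavail < 0:
            raise ValueError("bavail must be >= 0")
        if self.kd <= 0:
            raise ValueError("kd must be > 0")
        if not (0 < self.fnd <= 1):
            raise ValueError("fnd must be in (0, 1]")


def bpnd_from_receptors(p: ReceptorParams) -> float:
    """BP_ND = f_ND * B_avail / K_D."""
    return p.fnd * p.bavail / p.kd


@dataclass(frozen=True)
class ReleaseResult:
    """Challenge-induced change in binding potential.

    ``percent_change`` is positive when the drug lowers BP_ND, i.e. when
    increased synaptic dopamine displaces the radioligand.
    """

    bp_placebo: float
    bp_drug: float

    @property
    def percent_change(self) -> float:
        return percent_change(self.bp_placebo, self.bp_drug)


def percent_change(bp_placebo, bp_drug):
    """100*(placebo - drug)/placebo; the challenge-paradigm release index."""
    bp_placebo = np.asarray(bp_placebo, dtype=float)
    if np.any(bp_placebo <= 0):
        raise ValueError("baseline BP_ND must be positive")
    out = 100.0 * (bp_placebo - np.asarray(bp_drug, dtype=float)) / bp_placebo
    return float(out) if out.ndim == 0 else out
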