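"""Synthetic dynamic-PET data with known ground truth.

Every estimator in this package is validated by parameter recovery, so the
generators here produce exactly the structures the analysis assumes:

* a tri-exponential bolus plasma input (never observed by the fitters —
  reference-region models need no arterial sampling — it only has to drive
  realistic reference curves);
* a one-tissue reference region (cerebellar-gray-like kinetics);
* irreversible-trapping target tissue with a known net influx rate Ki;
* reversible D2/3-tracer tissue following the SRTM operational equation
  with known (R1, k2, BP_ND), and a drug scan whose true BP_ND is reduced
  by a per-subject release fraction;
* multi-subject cohorts whose per-region means, SDs and cross-measure
  correlations are set by a :class:`CohortSpec`;
* small labelled voxel phantoms blurred by a Gaussian PSF for the
  partial-volume-correction and cluster machinery.

All randomness flows through explicit seeds; a fixed seed reproduces every
draw bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._grid import expconv, fine_grid, frame_average, fine_curve_from_frames
from ._psf import psf_blur
from .frames import FrameSchedule, TimeActivityCurve, make_frame_schedule
from .kinetics import patlak_integral, srtm_basis

__all__ = [
    "FengInput", "simulate_reference_tac", "IrreversibleParams",
    "simulate_irreversible_tac", "SRTMTruth", "simulate_srtm_tac",
    "add_frame_noise", "ROISpec", "CohortSpec", "Cohort", "simulate_cohort",
    "PhantomSpec", "Phantom", "simulate_phantom", "DEFAULT_ROIS",
    "simulate_reference_stability_data",
]


# ---------------------------------------------------------------------------
# Plasma input and single-TAC simulators


@dataclass(frozen=True)
class FengInput:
    """Tri-exponential bolus input C_p(t) = (A1*t - A2 - A3)e^{-l1 t} + A2 e^{-l2 t} + A3 e^{-l3 t}.

    Zero at t=0, decays to zero; defaults give a sharp ~0.5 min peak with a
    slow washout tail, a generic bolus shape adequate for driving reference
    kinetics.  Units are arbitrary activity concentration.
    """

    a1: float = 851.1   # (conc)/min
    a2: float = 21.9
    a3: float = 20.8
    l1: float = 4.134   # 1/min
    l2: float = 0.1191
    l3: float = 0.0104

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = ((self.a1 * t - self.a2 - self.a3) * np.exp(-self.l1 * t)
               + self.a2 * np.exp(-self.l2 * t)
               + self.a3 * np.exp(-self.l3 * t))
        return np.where(t < 0, 0.0, out)


def simulate_reference_tac(plasma, k1p: float, k2p: float,
                           schedule: FrameSchedule, dt: float = 0.01) -> TimeActivityCurve:
    """One-tissue reference region: C_R = K1' * (C_p ⊗ e^{-k2' t}), frame-averaged."""
    if k1p <= 0 or k2p <= 0:
        raise ValueError("rate constants must be positive")
    t = fine_grid(schedule.total_duration, dt)
    fine = k1p * expconv(plasma(t), k2p, dt)
    return TimeActivityCurve(schedule, frame_average(t, fine, schedule))


@dataclass(frozen=True)
class IrreversibleParams:
    """Two-tissue irreversible kinetics relative to a reference input.

    k2 returns free tracer to plasma, k3 traps it; the net influx rate is
    Ki = K1 * k3/(k2+k3), which for the reference-normalised form (K1
    absorbed into the reference scaling) is k2*k3/(k2+k3) expressed per
    unit delivery.
    """

    k1: float = 1.0   # delivery relative to reference
    k2: float = 0.05  # 1/min
    k3: float = 0.01  # 1/min

    def __post_init__(self):
        if self.k1 < 0 or self.k2 < 0 or self.k3 < 0:
            raise ValueError("rate constants must be >= 0")

    @property
    def ki(self) -> float:
        return self.k1 * self.k3 / (self.k2 + self.k3)


def simulate_irreversible_tac(ref: TimeActivityCurve, ki: float | None = None,
                              v: float = 0.5, mode: str = "graphical_exact",
                              params: IrreversibleParams | None = None,
                              dt: float = 0.01) -> TimeActivityCurve:
    """Target tissue for an irreversibly trapped tracer.

    ``graphical_exact`` builds the tissue at the frame level as
    ``Ki * ∫ref + v * ref`` using the same midpoint-trapezoid integral the
    Patlak fitter uses, so the Patlak plot of the output is linear to
    machine precision with slope ``ki`` and intercept ``v``.

    ``compartmental`` integrates the two-tissue irreversible system driven
    by the (reconstructed) reference curve, producing the transient that
    Patlak analysis only linearises beyond t*.
    """
    if mode == "graphical_exact":
        if ki is None or ki < 0 or v < 0:
            raise ValueError("graphical_exact needs ki >= 0 and v >= 0")
        act = ki * patlak_integral(ref) + v * ref.activity
        return TimeActivityCurve(ref.schedule, act)
    if mode == "compartmental":
        p = params or IrreversibleParams()
        t, fine = fine_curve_from_frames(ref, dt)
        c1 = p.k1 * expconv(fine, p.k2 + p.k3, dt)
        from scipy.integrate import cumulative_trapezoid
        c2 = p.k3 * cumulative_trapezoid(c1, dx=dt, initial=0.0)
        return TimeActivityCurve(ref.schedule, frame_average(t, c1 + c2, ref.schedule))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class SRTMTruth:
    """Ground-truth SRTM parameters; k2a = k2/(1+BP_ND)."""

    r1: float = 1.0
    k2: float = 0.3     # 1/min
    bp_nd: float = 2.19

    def __post_init__(self):
        if self.r1 <= 0 or self.k2 <= 0 or self.bp_nd < 0:
            raise ValueError("need r1 > 0, k2 > 0, bp_nd >= 0")

    @property
    def k2a(self) -> float:
        return self.k2 / (1.0 + self.bp_nd)


def simulate_srtm_tac(ref: TimeActivityCurve, truth: SRTMTruth) -> TimeActivityCurve:
    """Forward-simulate the SRTM operational equation at the frame level.

    tissue = R1*ref + (k2 - R1*k2a) * (ref ⊗ e^{-k2a t}), with the
    convolution term computed by the same fine-grid basis machinery the
    fitter uses, so fit error reflects only the theta3 grid resolution.
    """
    b = srtm_basis(ref, np.array([truth.k2a]))[0]
    act = truth.r1 * ref.activity + (truth.k2 - truth.r1 * truth.k2a) * b
    return TimeActivityCurve(ref.schedule, act)


def add_frame_noise(tac: TimeActivityCurve, scale: float,
                    seed=None) -> TimeActivityCurve:
    """Frame-weighted Gaussian noise, SD = scale * sqrt(max(a,0)/duration).

    The variance model reflects count statistics: longer frames and lower
    activity give better-determined frame means.  ``seed`` may be an int or
    a ``numpy.random.Generator``.
    """
    if scale < 0:
        raise ValueError("noise scale must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sd = scale * np.sqrt(np.maximum(tac.activity, 0.0) / tac.schedule.frame_durations)
    return TimeActivityCurve(tac.schedule, tac.activity + rng.normal(0.0, 1.0, sd.shape) * sd)


# ---------------------------------------------------------------------------
# Cohort generator


@dataclass(frozen=True)
class ROISpec:
    """Population means/SDs of the three PET measures for one region."""

    ki_mean: float
    ki_sd: float
    bp_mean: float
    bp_sd: float
    release_mean: float   # fraction of baseline BP_ND displaced, in [0, 1)
    release_sd: float
    volume_mean: float    # mm^3
    volume_sd: float


# Defaults: healthy-adult striatal values (Ki in 1/min, BP_ND unitless,
# release as a fraction, volumes in mm^3).
DEFAULT_ROIS: dict[str, ROISpec] = {
    "whole_striatum": ROISpec(0.015, 0.002, 2.19, 0.18, 0.0878, 0.0423, 7097.0, 0.0),
    "dorsal_caudate": ROISpec(0.019, 0.002, 3.02, 0.27, 0.0748, 0.0378, 2042.0, 377.0),
    "dorsal_putamen": ROISpec(0.024, 0.002, 3.85, 0.27, 0.0963, 0.0588, 3759.0, 608.0),
    "ventral_striatum": ROISpec(0.018, 0.002, 2.61, 0.22, 0.0812, 0.0413, 1788.0, 330.0),
}

# latent measures entering the cross-subject correlation structure
_MEASURES = ("ki", "bp", "release", "weight")

_DEFAULT_CORR = np.array([
    [1.00, 0.46, -0.01, 0.0],
    [0.46, 1.00, 0.00, 0.0],
    [-0.01, 0.00, 1.00, 0.0],
    [0.00, 0.00, 0.00, 1.0],
])


@dataclass(frozen=True)
class CohortSpec:
    """Population-level description of a synthetic multi-tracer cohort.

    ``corr`` is the cross-measure correlation matrix over the latent
    (ki, bp, release, weight) factors shared across regions: each subject
    draws one latent z per measure, and every region's value is
    mean + sd * z for that region.  Release fractions are mapped through a
    Gaussian copula onto a truncated normal on [0, 0.9] whose parameters
    are moment-matched so the *truncated* distribution has exactly the
    requested mean and SD.
    """

    n_subjects: int = 40
    rois: dict[str, ROISpec] = field(default_factory=lambda: dict(DEFAULT_ROIS))
    corr: np.ndarray = field(default_factory=lambda: _DEFAULT_CORR.copy())
    noise_scale: float = 0.05
    mgkg_mean: float = 0.46   # methylphenidate dose per body weight
    mgkg_sd: float = 0.08
    dose_mg: float = 30.0
    r1: float = 1.0           # SRTM delivery ratio, shared truth
    k2: float = 0.3           # 1/min
    fmt_v: float = 0.5        # Patlak intercept truth
    release_bounds: tuple[float, float] = (0.0, 0.9)

    def __post_init__(self):
        c = np.asarray(self.corr, dtype=float)
        if c.shape != (4, 4) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("corr must be symmetric 4x4 with unit diagonal")
        if np.min(np.linalg.eigvalsh(c)) < -1e-10:
            raise ValueError("corr must be positive semi-definite")
        for name, r in self.rois.items():
            if min(r.ki_sd, r.bp_sd, r.release_sd, r.volume_sd) < 0:
                raise ValueError(f"negative SD in ROI {name!r}")
            if not (0 <= r.release_mean < 1):
                raise ValueError(f"release mean outside [0, 1) in ROI {name!r}")
        object.__setattr__(self, "corr", c)

    def with_corr(self, ki_bp: float | None = None,
                  ki_release: float | None = None) -> "CohortSpec":
        c = self.corr.copy()
        if ki_bp is not None:
            c[0, 1] = c[1, 0] = ki_bp
        if ki_release is not None:
            c[0, 2] = c[2, 0] = ki_release
        return replace(self, corr=c)


def _matched_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Truncated-normal parameters whose truncated moments equal (mean, sd)."""
    if sd == 0:
        return mean, 0.0
    def moments(p):
        mu, ls = p
        s = np.exp(ls)
        a, b = (lo - mu) / s, (hi - mu) / s
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return [m - mean, np.sqrt(v) - sd]
    sol = optimize.root(moments, [mean, np.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - well-posed for interior means
        raise RuntimeError("truncated-normal moment matching failed")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


@dataclass
class Cohort:
    """Simulated subjects: ground truth table plus per-subject TACs.

    ``truth`` is tidy (one row per subject x region) with columns
    subject, roi, ki_true, bp_true, release_true, bp_drug_true, weight_kg,
    volume_mm3.  ``tacs[(subject, roi)]`` maps to a dict with keys
    ``fmt``, ``rac_placebo``, ``rac_drug``; ``reference`` holds the shared
    noiseless reference TACs per tracer.
    """

    spec: CohortSpec
    seed: int
    truth: pd.DataFrame
    tacs: dict
    reference: dict

    @property
    def rois(self):
        return list(self.spec.rois)


def simulate_cohort(spec: CohortSpec, seed: int = 0,
                    generate_tacs: bool = True) -> Cohort:
    """Draw a cohort with the requested moments and correlation structure.

    Per subject: latent correlated z-scores set the true (Ki, baseline
    BP_ND, release fraction, body weight); each region's FMT TAC is built
    in graphical-exact mode at its true Ki, and the two raclopride TACs
    follow the SRTM forward model at baseline BP_ND and at
    baseline*(1 - release).  Frame noise at ``spec.noise_scale`` is added
    to the tissue TACs; the reference TACs are kept noiseless (in practice
    the large reference region has far higher SNR than striatal tissue).
    """
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    L = np.linalg.cholesky(spec.corr + 1e-12 * np.eye(4))
    z = rng.standard_normal((n, 4)) @ L.T  # columns follow _MEASURES order

    lo, hi = spec.release_bounds
    # body weight via the fixed-dose mg/kg distribution
    mgkg = np.clip(spec.mgkg_mean + spec.mgkg_sd * z[:, 3], 0.1, None)
    weight = spec.dose_mg / mgkg

    ref_fmt = simulate_reference_tac(FengInput(), 0.1, 0.1, make_frame_schedule("FMT"))
    ref_rac = simulate_reference_tac(FengInput(), 0.1, 0.1, make_frame_schedule("RAC"))

    rows = []
    tacs = {}
    u_release = stats.norm.cdf(z[:, 2])
    for roi, r in spec.rois.items():
        ki = r.ki_mean + r.ki_sd * z[:, 0]
        bp = r.bp_mean + r.bp_sd * z[:, 1]
        if np.any(ki <= 0) or np.any(bp <= 0):
            raise ValueError(f"ROI {roi!r}: drew non-positive Ki or BP_ND; "
                             "means are too close to zero for the given SDs")
        if r.release_sd > 0:
            mu, s = _matched_truncnorm(r.release_mean, r.release_sd, lo, hi)
            a, b = (lo - mu) / s, (hi - mu) / s
            release = stats.truncnorm.ppf(u_release, a, b, loc=mu, scale=s)
        else:
            release = np.full(n, r.release_mean)
        volume = np.maximum(r.volume_mean + r.volume_sd * rng.standard_normal(n), 1.0)
        for i in range(n):
            bp_drug = bp[i] * (1.0 - release[i])
            if generate_tacs:
                fmt = simulate_irreversible_tac(ref_fmt, ki=ki[i], v=spec.fmt_v)
                plc = simulate_srtm_tac(ref_rac, SRTMTruth(spec.r1, spec.k2, bp[i]))
                drg = simulate_srtm_tac(ref_rac, SRTMTruth(spec.r1, spec.k2, bp_drug))
                tacs[(i, roi)] = {
                    "fmt": add_frame_noise(fmt, spec.noise_scale, rng),
                    "rac_placebo": add_frame_noise(plc, spec.noise_scale, rng),
                    "rac_drug": add_frame_noise(drg, spec.noise_scale, rng),
                }
            rows.append({
                "subject": i, "roi": roi, "ki_true": ki[i], "bp_true": bp[i],
                "release_true": release[i], "bp_drug_true": bp_drug,
                "weight_kg": weight[i], "volume_mm3": volume[i],
            })
    truth = pd.DataFrame(rows)
    return Cohort(spec=spec, seed=seed, truth=truth, tacs=tacs,
                  reference={"fmt": ref_fmt, "rac": ref_rac})


def simulate_reference_stability_data(n_subjects: int, change_fraction: float = 0.0,
                                      bp_ref: float = 0.4, noise_scale: float = 0.02,
                                      seed: int = 0):
    """Paired scan-1/scan-2 TACs of a candidate reference region.

    Emulates the sanity check that a challenge drug leaves the reference
    region itself unchanged: the cerebellar region is treated as a *target*
    quantified against an alternate (occipital-like) reference.  Scan 2's
    true BP_ND is shifted by ``change_fraction`` (0 = stable).  Returns
    (scan1_tacs, scan2_tacs, ref_tac).
    """
    rng = np.random.default_rng(seed)
    sched = make_frame_schedule("RAC")
    ref = simulate_reference_tac(FengInput(), 0.1, 0.1, sched)
    s1, s2 = [], []
    for _ in range(n_subjects):
        t1 = simulate_srtm_tac(ref, SRTMTruth(1.0, 0.3, bp_ref))
        t2 = simulate_srtm_tac(ref, SRTMTruth(1.0, 0.3, bp_ref * (1.0 - change_fraction)))
        s1.append(add_frame_noise(t1, noise_scale, rng))
        s2.append(add_frame_noise(t2, noise_scale, rng))
    return s1, s2, ref


# ---------------------------------------------------------------------------
# Voxel phantoms


@dataclass(frozen=True)
class PhantomSpec:
    """Labelled grid with piecewise-constant true values and a Gaussian PSF.

    ``labels`` is an integer volume (0 = background); ``values`` maps each
    label (including 0 if the background is hot) to its true parametric
    value; ``fwhm_mm`` is the isotropic PSF width.
    """

    labels: np.ndarray
    values: dict[int, float]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    fwhm_mm: float = 4.0

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be integer")
        if np.any(np.asarray(self.voxel_size_mm) <= 0):
            raise ValueError("voxel size must be positive")
        if self.fwhm_mm < 0:
            raise ValueError("FWHM must be >= 0")
        missing = set(np.unique(lab[lab > 0])) - set(self.values)
        if missing:
            raise ValueError(f"labels without values: {sorted(missing)}")


@dataclass(frozen=True)
class Phantom:
    labels: np.ndarray
    truth: np.ndarray
    observed: np.ndarray
    voxel_size_mm: tuple[float, float, float]


def simulate_phantom(spec: PhantomSpec) -> Phantom:
    """Piecewise-constant true map plus its PSF-blurred observation."""
    truth = np.zeros(spec.labels.shape, dtype=float)
    for lab, val in spec.values.items():
        truth[spec.labels == lab] = val
    if spec.fwhm_mm == 0:
        observed = truth.copy()
    else:
        sigma = [spec.fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v
                 for v in spec.voxel_size_mm]
        observed = psf_blur(truth, sigma)
    return Phantom(labels=spec.labels.copy(), truth=truth, observed=observed,
                   voxel_size_mm=spec.voxel_size_mm)
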