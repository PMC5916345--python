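"""Uniform fine-time-grid numerics shared by the simulators and fitters.

Convolution with a decaying exponential is the workhorse of reference-tissue
kinetics.  On a uniform grid with the input taken piecewise-linear between
samples, the convolution integral has a closed-form one-step recurrence that
is exact for that interpolant, so the only discretisation error is the
piecewise-linear approximation of the input itself.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from .frames import FrameSchedule, TimeActivityCurve


def fine_grid(t_end: float, dt: float) -> np.ndarray:
    """Uniform grid 0..t_end inclusive; t_end must be a multiple of dt."""
    n = int(round(t_end / dt))
    if abs(n * dt - t_end) > 1e-9:
        raise ValueError(f"t_end={t_end} is not a multiple of dt={dt}")
    return np.arange(n + 1) * dt


def expconv(f: np.ndarray, lam: float, dt: float) -> np.ndarray:
    """(f ⊗ exp(-lam*t)) on a uniform grid, exact for piecewise-linear f.

    Recurrence: y[i] = E*y[i-1] + c1*f[i-1] + c2*f[i] with
    E = exp(-lam*dt), A = (1-E)/lam, B = (1 - E*(1+lam*dt))/lam**2,
    c1 = B/dt, c2 = A - B/dt; y[0] = 0.  For lam -> 0 this reduces to the
    cumulative trapezoid rule (c1 = c2 = dt/2).
    """
    f = np.asarray(f, dtype=float)
    if lam < 0:
        raise ValueError("decay rate must be >= 0")
    if lam * dt < 1e-12:
        c1 = c2 = dt / 2.0
        E = 1.0 - lam * dt
    else:
        E = np.exp(-lam * dt)
        A = (1.0 - E) / lam
        B = (1.0 - E * (1.0 + lam * dt)) / lam**2
        c1 = B / dt
        c2 = A - B / dt
    # lfilter implements z[i] = E*z[i-1] + c2*f[i] + c1*f[i-1] with z[-1]=0,
    # which equals the recurrence except z[0] = c2*f[0] instead of 0.
    z = lfilter([c2, c1], [1.0, -E], f)
    if f[0] != 0.0:
        z = z - c2 * f[0] * E ** np.arange(f.size)
    else:
        z[0] = 0.0
    return z


def frame_average(t: np.ndarray, y: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average a fine-grid curve over each frame (trapezoid / duration).

    Frame edges must coincide with grid points.
    """
    dt = t[1] - t[0]
    out = np.empty(schedule.n_frames)
    for i, (s, e) in enumerate(zip(schedule.frame_starts, schedule.frame_ends)):
        i0 = int(round(s / dt))
        i1 = int(round(e / dt))
        if abs(i0 * dt - s) > 1e-6 or abs(i1 * dt - e) > 1e-6 or i1 >= t.size:
            raise ValueError("frame edges must lie on the fine grid")
        out[i] = np.trapezoid(y[i0:i1 + 1], dx=dt) / (e - s)
    return out


def fine_curve_from_frames(tac: TimeActivityCurve, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct a continuous curve from frame values.

    Linear interpolation through (0, 0) and the (midpoint, activity) pairs,
    held constant after the last midpoint.  This is the convention both the
    forward SRTM simulator and the basis-function fitter use, so that the
    two sides share a single discretisation of the reference input.
    """
    t = fine_grid(tac.schedule.total_duration, dt)
    xp = np.concatenate([[0.0], tac.midpoints])
    fp = np.concatenate([[0.0], tac.activity])
    return t, np.interp(t, xp, fp)
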