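"""Synthetic fields and voltage movies with closed-form ground truth.

These fixtures exercise the spectral operator, the biomarkers and the phase
analysis without running full tissue simulations: a sine eigenmode for the
operator, a travelling rectangular pulse for conduction-velocity checks,
and a rigidly rotating spiral whose tip location, chirality and rotation
rate are known analytically.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sine_field", "plane_wave_movie", "spiral_movie"]


def sine_field(N: int = 128, L: float = 2.0, k0: float | None = None,
               mode: int = 1) -> tuple:
    """sin(k0 x) sampled on a periodic grid of N points over length L.

    k0 defaults to the ``mode``-th periodic wavenumber 2*pi*mode/L, for
    which the field is an exact eigenfunction of the periodic spectral
    operator.  Returns (x, field, k0).
    """
    x = np.arange(N) * (L / N)
    if k0 is None:
        k0 = 2.0 * np.pi * mode / L
    return x, np.sin(k0 * x), k0


def plane_wave_movie(c: float = 63.0, L: float = 2.0, N: int = 128,
                     dt_frame: float = 0.05, duration: float = 60.0,
                     width: float = 0.5, v_rest: float = -81.0,
                     v_peak: float = 20.0, edge: float = 0.02) -> tuple:
    """Rectangular depolarization pulse travelling at speed c (cm/s).

    V(x, t) = rest + (peak - rest) * pulse(x - c t), with ``edge``-cm
    linear ramps so threshold crossings interpolate cleanly.  Returns
    (times_ms, V[frame, node], x_cm).
    """
    x = (np.arange(N) + 0.5) * (L / N)
    times = np.arange(0.0, duration, dt_frame)
    c_cm_ms = c / 1000.0
    front = x[None, :] - c_cm_ms * times[:, None]     # pulse coordinate
    up = np.clip((0.0 - front) / edge, 0.0, 1.0)
    down = np.clip((front + width) / edge, 0.0, 1.0)
    pulse = np.minimum(up, down)
    V = v_rest + (v_peak - v_rest) * pulse
    return times, V, x


def spiral_movie(N: int = 64, L: float = 4.0, period: float = 100.0,
                 duration: float = 500.0, dt_frame: float = 1.0,
                 wavelength: float = 2.0, center: tuple | None = None,
                 chirality: int = 1, v_rest: float = -70.0,
                 amplitude: float = 50.0, drift: tuple = (0.0, 0.0)) -> tuple:
    """Archimedean spiral V = rest + A cos(chi*theta - omega t + 2 pi r / lambda).

    The phase singularity sits at ``center`` (defaults to the domain
    center), optionally drifting linearly at ``drift`` (cm/ms).  Rotation
    rate omega = 2*pi/period.  Returns (times_ms, V[frame, ny, nx], dx_cm).
    """
    dx = L / N
    xs = (np.arange(N) + 0.5) * dx
    X, Y = np.meshgrid(xs, xs)
    times = np.arange(0.0, duration, dt_frame)
    omega = 2.0 * np.pi / period
    if center is None:
        center = (L / 2.0, L / 2.0)
    frames = np.empty((len(times), N, N))
    for i, t in enumerate(times):
        cx = center[0] + drift[0] * t
        cy = center[1] + drift[1] * t
        theta = np.arctan2(Y - cy, X - cx)
        r = np.hypot(X - cx, Y - cy)
        frames[i] = v_rest + amplitude * np.cos(
            chirality * theta - omega * t + 2.0 * np.pi * r / wavelength)
    return times, frames, dx
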