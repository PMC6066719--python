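"""Electrophysiological biomarkers: activation times, APD90, CV, dAPD.

Conventions: activation is the upward crossing of -40 mV (linear
interpolation between samples, 50 ms refractory lockout); APD90 is measured
from activation to 90% repolarization relative to the pre-upstroke
diastolic potential; CV is measured between the nodes at L/3 and 2L/3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "activation_times", "apd90", "conduction_velocity", "apd_dispersion",
    "peak_current_profiles", "RestitutionCurve", "APDProfile",
    "ACTIVATION_THRESHOLD",
]

ACTIVATION_THRESHOLD = -40.0    # mV
REFRACTORY_LOCKOUT = 50.0       # ms


def activation_times(times: np.ndarray, V: np.ndarray,
                     threshold: float = ACTIVATION_THRESHOLD,
                     lockout: float = REFRACTORY_LOCKOUT) -> np.ndarray:
    """Upward threshold crossings of a voltage trace (ms, interpolated)."""
    times = np.asarray(times, dtype=float)
    V = np.asarray(V, dtype=float)
    below = V[:-1] < threshold
    above = V[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    acts = []
    last = -np.inf
    for i in idx:
        frac = (threshold - V[i]) / (V[i + 1] - V[i])
        t = times[i] + frac * (times[i + 1] - times[i])
        if t - last >= lockout:
            acts.append(t)
            last = t
    return np.asarray(acts)


def apd90(times: np.ndarray, V: np.ndarray, activation: float,
          rest_window: float = 20.0, level: float = 0.9) -> float | None:
    """Action-potential duration at ``level`` (default 90%) repolarization.

    The repolarization target is peak - level*(peak - V_rest) with V_rest the
    diastolic potential just before the upstroke (minimum over the
    ``rest_window`` ms preceding activation).  Returns None when the AP has
    not repolarized by the end of the trace.
    """
    times = np.asarray(times, dtype=float)
    V = np.asarray(V, dtype=float)
    if not times[0] <= activation <= times[-1]:
        raise ValueError("activation time outside the trace")
    pre = (times >= activation - rest_window) & (times <= activation)
    if not pre.any():
        raise ValueError("no samples before activation")
    v_rest = V[pre].min()
    after = times >= activation
    t_a = times[after]
    v_a = V[after]
    # AP window: until the next activation (or trace end)
    nxt = activation_times(t_a[1:], v_a[1:])
    if len(nxt):
        stop = np.searchsorted(t_a, nxt[0])
        t_a, v_a = t_a[:stop], v_a[:stop]
    peak = v_a.max()
    target = peak - level * (peak - v_rest)
    ipk = int(np.argmax(v_a))
    below = np.nonzero(v_a[ipk:] <= target)[0]
    if not len(below):
        return None
    i = ipk + below[0]
    if i == 0:
        return 0.0
    frac = (v_a[i - 1] - target) / (v_a[i - 1] - v_a[i])
    t90 = t_a[i - 1] + frac * (t_a[i] - t_a[i - 1])
    return float(t90 - activation)


def conduction_velocity(result, fractions=(1.0 / 3.0, 2.0 / 3.0)) -> float | None:
    """Plane-wave CV (cm/s) between two probe nodes of a SimResult.

    The probes are expected to sit at the given fractions of the strand
    (first two recorded probes).  Returns None when either probe never
    activates; raises on non-monotone activation order (reentry crossing
    the probes).
    """
    if result.probe_V.shape[0] < 2:
        raise ValueError("need two recorded probe traces")
    a1 = activation_times(result.probe_times, result.probe_V[0])
    a2 = activation_times(result.probe_times, result.probe_V[1])
    if not len(a1) or not len(a2):
        return None
    if a2[0] <= a1[0]:
        raise ValueError("non-monotone activation between probes")
    dist = abs(result.probe_idx[1] - result.probe_idx[0]) * result.config.dx
    return float(dist / ((a2[0] - a1[0]) / 1000.0))


@dataclass
class APDProfile:
    """Per-node APD90 with global and local dispersion.

    global_dapd = max(APD) - min(APD); local_dapd = min(APD) - APD <= 0.
    """

    node_index: np.ndarray
    apd: np.ndarray

    @property
    def global_dapd(self) -> float:
        return float(self.apd.max() - self.apd.min())

    @property
    def local_dapd(self) -> np.ndarray:
        return self.apd.min() - self.apd


@dataclass
class RestitutionCurve:
    """(coupling interval, APD, CV, propagated) points of an S1-S2 scan."""

    ci: np.ndarray = field(default_factory=lambda: np.empty(0))
    apd: np.ndarray = field(default_factory=lambda: np.empty(0))
    cv: np.ndarray = field(default_factory=lambda: np.empty(0))
    propagated: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))


def apd_dispersion(result, beat: int = -1, edge_exclude: int = 5) -> APDProfile:
    """Per-node APD90 profile of one beat of a strand movie.

    ``edge_exclude`` nodes at each boundary are dropped to suppress
    mirror-boundary artifacts.  The movie sampling stride bounds the APD
    resolution; run with a fine stride for dispersion maps.
    """
    V = result.V
    if V.ndim != 2:
        raise ValueError("apd_dispersion expects a 1-D strand movie")
    n_nodes = V.shape[1]
    sel = np.arange(edge_exclude, n_nodes - edge_exclude)
    apds = np.full(len(sel), np.nan)
    for k, n in enumerate(sel):
        acts = activation_times(result.times, V[:, n])
        if not len(acts):
            continue
        a = acts[beat] if -len(acts) <= beat < len(acts) else acts[-1]
        val = apd90(result.times, V[:, n], a)
        if val is not None:
            apds[k] = val
    good = np.isfinite(apds)
    if not good.all():
        warnings.warn("partial propagation: APD profile restricted to "
                      f"{int(good.sum())}/{len(sel)} nodes", stacklevel=2)
    return APDProfile(node_index=sel[good], apd=apds[good])


def peak_current_profiles(result, currents=("I_Na", "I_to", "I_Kur", "I_CaL")) -> dict:
    """Per-node peak current magnitudes tracked during the run (pA/pF)."""
    from ._kernels import CURRENT_NAMES

    if result.peaks is None:
        raise ValueError("run was recorded without peak tracking "
                         "(RecordSpec.peaks=True)")
    tracked = ("I_Na", "I_to", "I_Kur", "I_CaL")
    out = {}
    for name in currents:
        if name not in tracked:
            raise ValueError(f"peak tracking covers {tracked}, not {name}")
        out[name] = result.peaks[tracked.index(name)].copy()
    return out
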