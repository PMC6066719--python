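"""Courtemanche human atrial membrane model with chronic-AF remodeling.

The module exposes the 1998 Courtemanche-Ramirez-Nattel (CRN) formalism —
21 state variables, 12 membrane currents plus the acetylcholine-activated
potassium current I_KACh — together with the chronic atrial fibrillation
(CAF) electrical remodeling used throughout the package:

* g_to and g_CaL scaled by 0.65,
* g_Kur scaled by 0.49,
* g_K1 scaled by 2.1,
* I_KACh (Kneller et al. dose-response) active at [ACh] = 5 nM.

Currents are expressed per unit membrane capacitance (pA/pF), so the
single-cell voltage equation is ``dV/dt = -I_total + I_stim`` (mV/ms).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels as K
from ._kernels import CURRENT_NAMES, N_PARAM, N_STATE, STATE_NAMES

__all__ = [
    "MembraneState", "IonicParameters", "CurrentsRecord", "Trace",
    "resting_state", "apply_caf_remodeling", "i_kach", "ionic_currents",
    "step_cell", "pace_cell", "STATE_NAMES", "CURRENT_NAMES",
]

#: Published CRN resting initial conditions (quiescent steady state).
_REST = np.array([
    -81.18,        # V (mV)
    2.908e-3,      # m
    9.649e-1,      # h
    9.775e-1,      # j
    3.043e-2,      # oa
    9.992e-1,      # oi
    4.966e-3,      # ua
    9.986e-1,      # ui
    3.296e-5,      # xr
    1.869e-2,      # xs
    1.367e-4,      # d
    9.996e-1,      # f
    7.755e-1,      # fca
    0.0,           # u
    1.0,           # v
    9.992e-1,      # w
    11.17,         # Nai (mM)
    139.0,         # Ki (mM)
    1.013e-4,      # Cai (mM)
    1.488,         # Ca_up (mM)
    1.488,         # Ca_rel (mM)
])

GATE_SLICE = slice(1, 16)


@dataclass
class MembraneState:
    """State of one atrial cell: V, 15 gates, 5 concentrations."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_STATE,):
            raise ValueError(f"expected {N_STATE} state variables, got {self.values.shape}")

    def __getattr__(self, name):
        if name in STATE_NAMES:
            return self.values[STATE_NAMES.index(name)]
        raise AttributeError(name)

    def copy(self) -> "MembraneState":
        return MembraneState(self.values.copy())

    def validate(self) -> None:
        v = self.values
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite membrane state")
        gates = v[GATE_SLICE]
        if gates.min() < -1e-9 or gates.max() > 1.0 + 1e-9:
            warnings.warn("gate variable outside [0, 1]", stacklevel=2)
        if np.any(v[16:] <= 0):
            raise ValueError("non-positive intracellular concentration")


def resting_state() -> MembraneState:
    """Quiescent CRN steady state (published initial conditions)."""
    return MembraneState(_REST.copy())


@dataclass(frozen=True)
class IonicParameters:
    """Maximal conductances (nS/pF), pump/exchanger maxima and modifiers."""

    g_Na: float = 7.8
    g_to: float = 0.1652
    g_Kur_scale: float = 1.0          # multiplies the V-dependent g_Kur(V)
    g_Kr: float = 0.029411765
    g_Ks: float = 0.12941176
    g_CaL: float = 0.12375
    g_K1: float = 0.09
    g_bNa: float = 0.0006744375
    g_bCa: float = 0.001131
    I_NaK_max: float = 0.59933874     # pA/pF
    I_NaCa_max: float = 1600.0        # pA/pF
    I_pCa_max: float = 0.275          # pA/pF
    I_up_max: float = 0.005           # mM/ms
    C: float = 100.0                  # pF
    ACh: float = 0.0                  # nM
    remodeled: bool = False
    #: hold intracellular Na+ and K+ fixed (standard practice for long
    #: AF-substrate simulations; prevents slow rate-dependent drift)
    clamp_na_k: bool = True

    def __post_init__(self):
        for name in ("g_Na", "g_to", "g_Kur_scale", "g_Kr", "g_Ks", "g_CaL",
                     "g_K1", "g_bNa", "g_bCa", "ACh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.C <= 0:
            raise ValueError("membrane capacitance must be positive")

    def as_array(self) -> np.ndarray:
        """Pack into the flat parameter vector used by the numba kernels."""
        p = np.zeros(N_PARAM)
        p[K.P_GNA] = self.g_Na
        p[K.P_GTO] = self.g_to
        p[K.P_GKUR_SCALE] = self.g_Kur_scale
        p[K.P_GKR] = self.g_Kr
        p[K.P_GKS] = self.g_Ks
        p[K.P_GCAL] = self.g_CaL
        p[K.P_GK1] = self.g_K1
        p[K.P_GBNA] = self.g_bNa
        p[K.P_GBCA] = self.g_bCa
        p[K.P_INAK_MAX] = self.I_NaK_max
        p[K.P_INACA_MAX] = self.I_NaCa_max
        p[K.P_IPCA_MAX] = self.I_pCa_max
        p[K.P_IUP_MAX] = self.I_up_max
        p[K.P_GKACH_DOSE] = _kach_dose_factor(self.ACh)
        p[K.P_CM] = self.C
        p[K.P_CLAMP_NAK] = 1.0 if self.clamp_na_k else 0.0
        return p


# CAF remodeling factors (experimentally motivated conductance scalings).
CAF_FACTORS = {"g_to": 0.65, "g_CaL": 0.65, "g_Kur_scale": 0.49, "g_K1": 2.1}
CAF_ACH_NM = 5.0


def apply_caf_remodeling(params: IonicParameters, ach_nm: float = CAF_ACH_NM) -> IonicParameters:
    """Return a CAF-remodeled parameter set (g_to, g_CaL x0.65; g_Kur x0.49;
    g_K1 x2.1; I_KACh enabled at ``ach_nm`` nanomolar acetylcholine).

    Raises ValueError if the parameters are already remodeled.
    """
    if params.remodeled:
        raise ValueError("parameters already carry CAF remodeling")
    return replace(
        params,
        g_to=params.g_to * CAF_FACTORS["g_to"],
        g_CaL=params.g_CaL * CAF_FACTORS["g_CaL"],
        g_Kur_scale=params.g_Kur_scale * CAF_FACTORS["g_Kur_scale"],
        g_K1=params.g_K1 * CAF_FACTORS["g_K1"],
        ACh=ach_nm,
        remodeled=True,
    )


def _kach_dose_factor(ach_nm: float) -> float:
    """Saturating acetylcholine dose-response of the I_KACh conductance.

    The Kneller et al. fit takes [ACh] in micromolar; the public interface
    uses nanomolar.
    """
    if ach_nm < 0:
        raise ValueError("ACh concentration must be non-negative")
    if ach_nm == 0:
        return 0.0
    ach_um = ach_nm * 1e-3
    return 10.0 / (1.0 + 9.13652 / ach_um ** 0.477811)


def i_kach(V: float, E_K: float, ACh_nM: float) -> float:
    """Acetylcholine-activated inward-rectifier K+ current (pA/pF)."""
    dose = _kach_dose_factor(ACh_nM)
    rect = 0.0517 + 0.4516 / (1.0 + math.exp((V + 59.53) / 17.18))
    return dose * rect * (V - E_K)


@dataclass
class CurrentsRecord:
    """All membrane currents (pA/pF) at one instant."""

    values: dict
    timestamp: float = 0.0

    def __getitem__(self, name):
        return self.values[name]

    @property
    def I_total(self):
        return self.values["I_total"]


def ionic_currents(state: MembraneState, params: IonicParameters,
                   timestamp: float = 0.0) -> CurrentsRecord:
    """Evaluate every membrane current at the given state (no time step)."""
    if not np.all(np.isfinite(state.values)):
        raise ValueError("non-finite membrane state")
    S = state.values.reshape(N_STATE, 1).copy()
    cur = np.zeros((K.N_CURRENT, 1))
    peaks = np.zeros((4, 1))
    # dt = 0 evaluates currents without advancing the state
    K.step_nodes(S, 0.0, np.zeros(1), params.as_array(), cur, True, peaks, False)
    vals = {name: float(cur[i, 0]) for i, name in enumerate(CURRENT_NAMES)}
    return CurrentsRecord(vals, timestamp)


def step_cell(state: MembraneState, I_stim: float, dt: float,
              params: IonicParameters) -> MembraneState:
    """One forward-Euler step of the full 21-variable system.

    ``I_stim`` is in pA/pF, positive depolarizing.  Raises RuntimeError on
    numerical instability (|V| > 200 mV).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    S = state.values.reshape(N_STATE, 1).copy()
    cur = np.zeros((K.N_CURRENT, 1))
    peaks = np.zeros((4, 1))
    bad = K.step_nodes(S, dt, np.full(1, float(I_stim)), params.as_array(),
                       cur, False, peaks, False)
    if bad >= 0:
        raise RuntimeError("membrane integration unstable: |V| > 200 mV")
    new = MembraneState(S[:, 0])
    gates = new.values[GATE_SLICE]
    if gates.min() < -1e-6 or gates.max() > 1.0 + 1e-6:
        warnings.warn("gate variable left [0, 1]", stacklevel=2)
    return new


@dataclass
class Trace:
    """Sampled voltage trace of a paced cell."""

    times: np.ndarray            # ms
    V: np.ndarray                # mV
    stim_times: np.ndarray       # onsets of the delivered stimuli (ms)
    final_state: MembraneState
    captured: bool = True


def pace_cell(params: IonicParameters, bcl: float, duration: float,
              stim_amplitude: float, stim_duration: float = 2.0,
              dt: float = 0.01, sample_dt: float = 0.1,
              initial_state: MembraneState | None = None) -> Trace:
    """Pace a single cell at basic cycle length ``bcl`` (ms) for ``duration``.

    Returns the sampled V(t) trace, stimulus onsets and the final state
    (used as tissue initial condition).  Loss of 1:1 capture is flagged on
    the returned trace.
    """
    if bcl <= stim_duration:
        raise ValueError("bcl must exceed the stimulus duration")
    state = (initial_state or resting_state()).copy()
    S = state.values.reshape(N_STATE, 1).copy()
    n_steps = int(round(duration / dt))
    period_steps = int(round(bcl / dt))
    dur_steps = int(round(stim_duration / dt))
    sample_every = max(1, int(round(sample_dt / dt)))
    n_samples = (n_steps + sample_every - 1) // sample_every
    v_out = np.empty(n_samples)
    bad = K.pace_cell_kernel(S, params.as_array(), dt, n_steps, period_steps,
                             dur_steps, float(stim_amplitude), sample_every, v_out)
    if bad >= 0:
        raise RuntimeError(f"pacing unstable at t = {bad * dt:.2f} ms")
    times = np.arange(n_samples) * sample_every * dt
    stim_times = np.arange(0.0, duration, bcl)
    # 1:1 capture check: one upstroke (crossing of -40 mV) per stimulus
    from .biomarkers import activation_times
    acts = activation_times(times, v_out)
    captured = len(acts) == len(stim_times)
    return Trace(times, v_out, stim_times, MembraneState(S[:, 0]), captured)
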