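"""Monodomain tissue simulation by operator splitting.

Reaction (Courtemanche kinetics, forward Euler) and diffusion (exponential
spectral propagator of the complex fractional order operator) are advanced
alternately each time step.  Diffusion acts on the voltage field only;
gates and concentrations are purely local.  Lie (reaction-then-diffusion)
splitting is the default; Strang splitting is available behind a flag.

There is no randomness anywhere: identical configurations produce
bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _kernels as K
from .courtemanche import IonicParameters, MembraneState
from .fractional import (CALIBRATION_K_SCALE, DEALIAS_FRAC, DiffusionOperator,
                         FractionalOrder, SpectralGrid, diffusion_propagator)

__all__ = [
    "StrandConfig", "SheetConfig", "StimulusSpec", "RecordSpec",
    "TissueState", "SimResult", "initialize_tissue", "step_tissue",
    "run_simulation", "calibrate_kappa", "measure_strand_cv",
    "PropagationError",
]


class PropagationError(RuntimeError):
    pass


@dataclass(frozen=True)
class StrandConfig:
    """1-D atrial strand: length L (cm) sampled at N nodes."""

    L: float = 2.0
    N: int = 128
    dt: float = 0.01                    # ms
    kappa: float = 0.40                 # cm^2/s
    order: FractionalOrder = field(default_factory=FractionalOrder)
    splitting: str = "lie"
    #: wavenumber unit scale of the fractional symbol; the default reproduces
    #: the published kappa <-> CV calibration (see fractional.CALIBRATION_K_SCALE)
    k_scale: float = CALIBRATION_K_SCALE
    #: 2/3-rule spectral low-pass of the semi-spectral scheme (None disables)
    lowpass_frac: float | None = DEALIAS_FRAC

    def __post_init__(self):
        if self.L <= 0 or self.N < 16:
            raise ValueError("need L > 0 and N >= 16")
        if not 0 < self.dt <= 0.05:
            raise ValueError("dt must lie in (0, 0.05] ms")

    @property
    def dx(self) -> float:
        return self.L / self.N

    def grid(self) -> SpectralGrid:
        return SpectralGrid(N=self.N, dx=self.dx, ndim=1)

    @property
    def n_nodes(self) -> int:
        return self.N

    def node_positions(self) -> np.ndarray:
        """Node centers (cm), half-sample offset matching the mirror extension."""
        return (np.arange(self.N) + 0.5) * self.dx


@dataclass(frozen=True)
class SheetConfig:
    """2-D square atrial sheet, N x N nodes at spacing dx = dy (cm)."""

    N: int = 128
    dx: float = 0.03215
    dt: float = 0.01
    kappa: float = 0.40
    order: FractionalOrder = field(default_factory=FractionalOrder)
    splitting: str = "lie"
    k_scale: float = CALIBRATION_K_SCALE
    lowpass_frac: float | None = DEALIAS_FRAC

    def __post_init__(self):
        if self.N < 16 or self.dx <= 0:
            raise ValueError("need N >= 16 and dx > 0")
        if not 0 < self.dt <= 0.05:
            raise ValueError("dt must lie in (0, 0.05] ms")

    @property
    def L(self) -> float:
        return self.N * self.dx

    def grid(self) -> SpectralGrid:
        return SpectralGrid(N=self.N, dx=self.dx, ndim=2)

    @property
    def n_nodes(self) -> int:
        return self.N * self.N

    def node_positions(self) -> tuple:
        x = (np.arange(self.N) + 0.5) * self.dx
        return x, x.copy()


@dataclass
class StimulusSpec:
    """Rectangular current pulse applied to a set of nodes.

    amplitude is in pA/pF (conventionally a multiple of the diastolic
    threshold), duration in ms, onsets in ms from simulation start.
    region is a boolean mask over the flattened node array.
    """

    region: np.ndarray
    amplitude: float
    onset_times: Sequence[float]
    duration: float = 2.0

    def __post_init__(self):
        self.region = np.asarray(self.region, dtype=bool).ravel()
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if not self.region.any():
            raise ValueError("stimulus region is empty")


@dataclass
class RecordSpec:
    """What to sample during a run.

    movie_stride: V-frame sampling interval (ms); probes: flat node indices
    sampled at every time step; currents at the probe nodes are stored every
    ``current_stride`` ms when ``currents`` is set; ``peaks`` tracks running
    per-node peak magnitudes of I_Na, I_to, I_Kur, I_CaL.
    """

    movie_stride: float = 1.0
    probes: Sequence[int] = ()
    currents: bool = False
    current_stride: float = 0.1
    peaks: bool = False


@dataclass
class TissueState:
    """Fields of membrane states on a grid (flattened node axis)."""

    S: np.ndarray               # (21, n_nodes)
    shape: tuple                # grid shape, e.g. (N,) or (N, N)

    def copy(self) -> "TissueState":
        return TissueState(self.S.copy(), self.shape)

    @property
    def V(self) -> np.ndarray:
        return self.S[0].reshape(self.shape)


@dataclass
class SimResult:
    """Sampled output of one tissue run."""

    times: np.ndarray           # movie frame times (ms)
    V: np.ndarray               # (n_frames, *shape) voltage movie (mV)
    probe_idx: np.ndarray
    probe_times: np.ndarray     # full-resolution times (ms)
    probe_V: np.ndarray         # (n_probes, n_steps+1)
    final_state: TissueState
    config: object
    stim_onsets: np.ndarray
    propagation_failure: bool = False
    peaks: np.ndarray | None = None          # (4, n_nodes)
    current_times: np.ndarray | None = None
    probe_currents: np.ndarray | None = None  # (n_cframes, 14, n_probes)

    @property
    def dx(self) -> float:
        return self.config.dx


def initialize_tissue(config, paced_cell_state: MembraneState) -> TissueState:
    """Replicate a (typically 60-s paced) single-cell state on every node."""
    vals = np.asarray(paced_cell_state.values, dtype=float)
    if vals.shape != (K.N_STATE,):
        raise ValueError("paced_cell_state does not match the membrane model")
    grid = config.grid()
    S = np.repeat(vals[:, None], config.n_nodes, axis=1)
    return TissueState(S, grid.shape())


def step_tissue(state: TissueState, dt: float, operator: DiffusionOperator,
                params_vec: np.ndarray, istim: np.ndarray, *,
                splitting: str = "lie",
                half_operator: DiffusionOperator | None = None,
                cur: np.ndarray | None = None, want_cur: bool = False,
                peaks: np.ndarray | None = None, want_peaks: bool = False) -> None:
    """One split step, in place.  Raises PropagationError on instability."""
    if cur is None:
        cur = np.zeros((K.N_CURRENT, 1))
    if peaks is None:
        peaks = np.zeros((4, 1))
    if splitting == "strang":
        if half_operator is None:
            raise ValueError("strang splitting needs the half-step operator")
        state.S[0] = half_operator(state.V).ravel()
    bad = K.step_nodes(state.S, dt, istim, params_vec, cur, want_cur, peaks, want_peaks)
    if bad >= 0:
        raise PropagationError(f"instability at node {bad}")
    op = half_operator if splitting == "strang" else operator
    state.S[0] = op(state.V).ravel()


def run_simulation(config, params: IonicParameters, stimuli: Sequence[StimulusSpec],
                   duration: float, record: RecordSpec | None = None,
                   initial_state: TissueState | None = None,
                   paced_cell_state: MembraneState | None = None,
                   reaction: bool = True) -> SimResult:
    """Time-loop driver for strand and sheet simulations.

    The initial condition is either an explicit TissueState or a single-cell
    state tiled over the grid.  Deterministic: no RNG anywhere.
    """
    record = record or RecordSpec()
    if initial_state is not None:
        state = initial_state.copy()
    elif paced_cell_state is not None:
        state = initialize_tissue(config, paced_cell_state)
    else:
        raise ValueError("provide initial_state or paced_cell_state")
    grid = config.grid()
    M = config.n_nodes
    dt = config.dt
    pvec = params.as_array()

    operator = diffusion_propagator(grid, config.order, config.kappa, dt,
                                    k_scale=config.k_scale,
                                    lowpass_frac=config.lowpass_frac)
    half_operator = None
    if config.splitting == "strang":
        half_operator = diffusion_propagator(grid, config.order, config.kappa,
                                             dt / 2.0, k_scale=config.k_scale,
                                             lowpass_frac=config.lowpass_frac)

    n_steps = int(round(duration / dt))
    movie_every = max(1, int(round(record.movie_stride / dt)))
    n_frames = n_steps // movie_every + 1
    movie = np.empty((n_frames,) + grid.shape())
    frame_times = np.empty(n_frames)

    probe_idx = np.asarray(record.probes, dtype=int)
    probe_V = np.empty((len(probe_idx), n_steps + 1))
    probe_times = np.arange(n_steps + 1) * dt

    want_cur = record.currents and len(probe_idx) > 0
    cur = np.zeros((K.N_CURRENT, M if want_cur else 1))
    cur_every = max(1, int(round(record.current_stride / dt))) if want_cur else 0
    n_cframes = (n_steps // cur_every + 1) if want_cur else 0
    probe_cur = np.empty((n_cframes, K.N_CURRENT, len(probe_idx))) if want_cur else None
    cur_times = (np.arange(n_cframes) * cur_every * dt) if want_cur else None

    peaks = np.zeros((4, M if record.peaks else 1))

    # stimulus schedule as step-indexed on/off events
    events = []   # (step, mask, +/-amp)
    onsets = []
    for stim in stimuli:
        if stim.region.size != M:
            raise ValueError("stimulus region does not match the grid")
        for t0 in stim.onset_times:
            s0 = int(round(t0 / dt))
            s1 = int(round((t0 + stim.duration) / dt))
            if s0 > n_steps:
                continue
            events.append((s0, stim.region, stim.amplitude))
            events.append((s1, stim.region, -stim.amplitude))
            onsets.append(t0)
    events.sort(key=lambda e: e[0])
    onsets = np.asarray(sorted(onsets))
    istim = np.zeros(M)

    movie[0] = state.V
    frame_times[0] = 0.0
    if len(probe_idx):
        probe_V[:, 0] = state.S[0, probe_idx]
    if want_cur:
        K.step_nodes(state.S.copy(), 0.0, istim, pvec, cur, True, peaks, False)
        probe_cur[0] = cur[:, probe_idx]

    strang = config.splitting == "strang"
    ev = 0
    fi = 1
    ci = 1
    for step in range(n_steps):
        while ev < len(events) and events[ev][0] == step:
            _, mask, amp = events[ev]
            istim[mask] += amp
            ev += 1
        if strang:
            state.S[0] = half_operator(state.V).ravel()
        if reaction:
            bad = K.step_nodes(state.S, dt, istim, pvec, cur, want_cur,
                               peaks, record.peaks)
            if bad >= 0:
                raise PropagationError(
                    f"instability at node {bad}, t = {(step + 1) * dt:.2f} ms")
        elif np.any(istim):
            state.S[0] += dt * istim
        state.S[0] = (half_operator if strang else operator)(state.V).ravel()
        if len(probe_idx):
            probe_V[:, step + 1] = state.S[0, probe_idx]
        if want_cur and (step + 1) % cur_every == 0 and ci < n_cframes:
            probe_cur[ci] = cur[:, probe_idx]
            ci += 1
        if (step + 1) % movie_every == 0 and fi < n_frames:
            movie[fi] = state.V
            frame_times[fi] = (step + 1) * dt
            fi += 1

    result = SimResult(
        times=frame_times[:fi], V=movie[:fi], probe_idx=probe_idx,
        probe_times=probe_times, probe_V=probe_V,
        final_state=state, config=config, stim_onsets=onsets,
        peaks=peaks if record.peaks else None,
        current_times=cur_times, probe_currents=probe_cur,
    )
    result.propagation_failure = _propagation_failed(result, stimuli)
    return result


def _propagation_failed(result: SimResult, stimuli) -> bool:
    """True if no node outside (and away from) the stimulated regions ever
    crossed -40 mV after the first stimulus."""
    if not len(result.stim_onsets) or not len(result.times):
        return False
    stim_mask = np.zeros(result.V[0].size, dtype=bool)
    for s in stimuli:
        stim_mask |= s.region
    far = ~stim_mask
    if not far.any():
        return False
    after = result.times >= result.stim_onsets[0]
    vmax = result.V[after].reshape(after.sum(), -1)[:, far].max() if after.any() else -np.inf
    return bool(vmax < -40.0)


def left_edge_mask(config, n_nodes: int = 3) -> np.ndarray:
    """Stimulation mask covering the left boundary (first nodes / column)."""
    if isinstance(config, StrandConfig):
        m = np.zeros(config.N, dtype=bool)
        m[:n_nodes] = True
        return m
    m = np.zeros((config.N, config.N), dtype=bool)
    m[:, :n_nodes] = True
    return m.ravel()


def measure_strand_cv(config: StrandConfig, params: IonicParameters,
                      init_cell: MembraneState, amplitude: float,
                      duration: float = 400.0) -> float | None:
    """Plane-wave CV (cm/s) between L/3 and 2L/3 after one left-edge stimulus.

    Returns None if the wave does not reach both probes (propagation failure).
    """
    from .biomarkers import activation_times

    i1 = int(round(config.N / 3.0))
    i2 = int(round(2.0 * config.N / 3.0))
    stim = StimulusSpec(region=left_edge_mask(config), amplitude=amplitude,
                        onset_times=[0.0])
    rec = RecordSpec(movie_stride=5.0, probes=(i1, i2))
    res = run_simulation(config, params, [stim], duration, rec,
                         paced_cell_state=init_cell)
    a1 = activation_times(res.probe_times, res.probe_V[0])
    a2 = activation_times(res.probe_times, res.probe_V[1])
    if not len(a1) or not len(a2):
        return None
    dist = (i2 - i1) * config.dx                 # cm
    dt_act = (a2[0] - a1[0]) / 1000.0            # s
    if dt_act <= 0:
        return None
    return dist / dt_act


def calibrate_kappa(alpha: float, target_cv: float, config: StrandConfig,
                    params: IonicParameters, init_cell: MembraneState,
                    amplitude: float, tol: float = 0.5,
                    bracket: tuple = (0.02, 40.0), max_iter: int = 60) -> float:
    """Bisect kappa until the plane-wave CV matches target_cv (cm/s).

    Calibration is defined for beta = 0 and non-remodeled parameters.
    CV grows monotonically with kappa, so plain bisection on kappa applies.
    """
    order = FractionalOrder(alpha=alpha, beta=0.0)
    base = replace(config, order=order)

    def cv_at(kap):
        return measure_strand_cv(replace(base, kappa=kap), params, init_cell, amplitude)

    lo, hi = bracket
    # excessive kappa dissipates the stimulus before capture: shrink the
    # upper bracket until the wave propagates at all
    cv_hi = cv_at(hi)
    for _ in range(12):
        if cv_hi is not None:
            break
        hi *= 0.6
        cv_hi = cv_at(hi)
    if cv_hi is None or cv_hi < target_cv:
        raise PropagationError("upper kappa bracket too slow for the target CV")
    cv_lo = cv_at(lo)
    if cv_lo is not None and cv_lo > target_cv:
        raise PropagationError("lower kappa bracket already too fast")
    for _ in range(max_iter):
        mid = math_sqrt_mid(lo, hi)
        cv = cv_at(mid)
        if cv is not None and abs(cv - target_cv) <= tol:
            return mid
        if cv is None:          # capture lost again: too diffusive
            hi = mid
        elif cv < target_cv:
            lo = mid
        else:
            hi = mid
    raise PropagationError("kappa bisection did not converge")


def math_sqrt_mid(lo: float, hi: float) -> float:
    """Geometric midpoint; CV scales roughly with sqrt(kappa)."""
    return float(np.sqrt(lo * hi))
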