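"""Stimulation protocols: threshold search, S1-S2 cross-field, VW, restitution.

The cross-field protocol entrains the sheet with S1 plane waves from the
left edge (basic cycle length 400 ms), then delivers a single premature S2
over the lower-left quadrant.  The S2 timing is referenced to the last S1:
the coupling interval (CI) is the S2 onset minus the last S1 onset.  The
physiologically useful CI range surrounds the moment when the last S1
repolarization wave clears the domain midline.

The vulnerable window (VW) is the width, in ms, of the CI range for which
the S2 triggers a rotor sustained for at least two rotations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .biomarkers import activation_times, apd90, conduction_velocity, RestitutionCurve
from .courtemanche import IonicParameters, MembraneState
from .phase import link_filament, phase_movie, find_singularities, sustained_rotor
from .tissue import (RecordSpec, SheetConfig, StimulusSpec, StrandConfig,
                     left_edge_mask, run_simulation)

__all__ = [
    "CrossFieldProtocol", "VWResult", "find_diastolic_threshold",
    "run_crossfield", "vulnerable_window", "restitution_protocol",
    "classify_episode", "lower_left_quadrant_mask",
]

#: midline repolarization criterion for timing S2 (mV)
REPOL_THRESHOLD = -70.0


@dataclass
class CrossFieldProtocol:
    """S1-S2 cross-field stimulation parameters."""

    s1_bcl: float = 400.0
    s1_count: int = 2
    coupling_interval: float = 150.0      # ms, S2 onset minus last S1 onset
    stim_duration: float = 2.0
    amplitude: float = 44.0               # pA/pF (2x diastolic threshold)

    def __post_init__(self):
        if self.coupling_interval <= 0:
            raise ValueError("coupling interval must be positive")
        if self.s1_count < 1:
            raise ValueError("need at least one S1")


@dataclass
class VWResult:
    """Vulnerable-window scan outcome."""

    ci_values: np.ndarray
    sustained: np.ndarray
    rotations: np.ndarray

    @property
    def ci_min(self) -> float | None:
        s = self.ci_values[self.sustained]
        return float(s.min()) if len(s) else None

    @property
    def ci_max(self) -> float | None:
        s = self.ci_values[self.sustained]
        return float(s.max()) if len(s) else None

    @property
    def vw(self) -> float:
        """VW width (ms) = max - min sustaining CI; 0 when nothing sustains."""
        if not self.sustained.any():
            return 0.0
        return float(self.ci_max - self.ci_min)


def lower_left_quadrant_mask(config: SheetConfig) -> np.ndarray:
    """S2 region: the lower-left quadrant, adjacent to the S1 (left) edge."""
    m = np.zeros((config.N, config.N), dtype=bool)
    half = config.N // 2
    m[:half, :half] = True
    return m.ravel()


def find_diastolic_threshold(config, params: IonicParameters,
                             init_cell: MembraneState,
                             stim_duration: float = 2.0,
                             rel_tol: float = 0.01,
                             bracket: tuple = (0.5, 100.0)) -> float:
    """Minimal 2-ms pulse amplitude (pA/pF) that elicits a propagated AP.

    Bisection to 1% relative precision; capture means a node >= 1 cm from
    the stimulus crosses -40 mV.  Capture is monotone in amplitude over the
    bracket (strength-response), which bisection relies on.
    """
    probe = _far_probe_index(config)
    region = left_edge_mask(config)

    def captures(amp: float) -> bool:
        stim = StimulusSpec(region=region, amplitude=amp, onset_times=[0.0],
                            duration=stim_duration)
        rec = RecordSpec(movie_stride=50.0, probes=(probe,))
        res = run_simulation(config, params, [stim], 150.0, rec,
                             paced_cell_state=init_cell)
        return len(activation_times(res.probe_times, res.probe_V[0])) > 0

    lo, hi = bracket
    if captures(lo):
        raise ValueError("lower bracket already captures")
    if not captures(hi):
        raise ValueError("no capture at bracket top")
    while (hi - lo) / hi > rel_tol:
        mid = 0.5 * (lo + hi)
        if captures(mid):
            hi = mid
        else:
            lo = mid
    return hi


def _far_probe_index(config) -> int:
    """A node >= 1 cm from the left edge (flat index)."""
    n_off = int(np.ceil(1.0 / config.dx)) + 1
    if isinstance(config, StrandConfig):
        return min(config.N - 2, n_off)
    return (config.N // 2) * config.N + min(config.N - 2, n_off)


def run_crossfield(protocol: CrossFieldProtocol, config: SheetConfig,
                   params: IonicParameters, init_cell: MembraneState,
                   post_s2: float = 600.0, record: RecordSpec | None = None,
                   initial_state=None):
    """One S1-S2 cross-field episode.

    S1 plane waves from the left edge; S2 over the lower-left quadrant at
    the configured coupling interval after the last S1.  The episode runs
    for ``post_s2`` ms beyond the S2 onset.  S2 must not precede the end of
    the last S1 pulse.
    """
    last_s1 = (protocol.s1_count - 1) * protocol.s1_bcl
    t_s2 = last_s1 + protocol.coupling_interval
    if t_s2 < last_s1 + protocol.stim_duration:
        raise ValueError("S2 scheduled before the last S1 pulse ends")
    s1 = StimulusSpec(region=left_edge_mask(config), amplitude=protocol.amplitude,
                      onset_times=[i * protocol.s1_bcl for i in range(protocol.s1_count)],
                      duration=protocol.stim_duration)
    s2 = StimulusSpec(region=lower_left_quadrant_mask(config),
                      amplitude=protocol.amplitude, onset_times=[t_s2],
                      duration=protocol.stim_duration)
    record = record or RecordSpec(movie_stride=2.0)
    return run_simulation(config, params, [s1, s2], t_s2 + post_s2, record,
                          paced_cell_state=init_cell, initial_state=initial_state)


def midline_repolarization_time(result, threshold: float = REPOL_THRESHOLD) -> float | None:
    """Time at which the last repolarization wave clears the domain midline.

    Operationally: after the last stimulus, wait for the wave to activate
    the midline column (max V > -40 mV), then return the first time its
    maximum V falls back below ``threshold``.  None if that never happens.
    """
    mid = result.V.shape[2] // 2
    col_max = result.V[:, :, mid].max(axis=1)
    t0 = result.stim_onsets[-1] if len(result.stim_onsets) else 0.0
    active = np.nonzero((result.times >= t0) & (col_max > -40.0))[0]
    if not len(active):
        return None
    idx = np.nonzero((result.times > result.times[active[0]]) & (col_max < threshold))[0]
    return float(result.times[idx[0]]) if len(idx) else None


def classify_episode(result, min_rotations: float = 2.0,
                     analysis_start: float | None = None) -> tuple:
    """Phase-analyse an episode movie: (sustained?, rotations, filaments)."""
    t = result.times
    sel = np.ones(len(t), dtype=bool)
    if analysis_start is not None:
        sel = t >= analysis_start
    movie = phase_movie(t[sel], result.V[sel], dx=result.config.dx)
    tips = [find_singularities(movie.phase[i], movie.dx, t=movie.times[i])
            for i in range(movie.phase.shape[0])]
    filaments = link_filament(tips)
    ok, rot = sustained_rotor(filaments, movie, min_rotations)
    return ok, rot, filaments


def vulnerable_window(config: SheetConfig, params: IonicParameters,
                      init_cell: MembraneState, ci_range: tuple,
                      ci_step: float = 1.0,
                      protocol: CrossFieldProtocol | None = None,
                      post_s2: float = 600.0,
                      runner: Callable | None = None,
                      min_rotations: float = 2.0) -> VWResult:
    """Scan S2 coupling intervals and classify each episode.

    ``runner(ci) -> SimResult`` may be injected (e.g. for testing the scan
    logic); by default each CI runs a full cross-field episode.  Episodes
    sustaining >= min_rotations rotor rotations mark the CI as vulnerable.
    """
    proto = protocol or CrossFieldProtocol()
    if runner is None:
        def runner(ci):
            return run_crossfield(replace(proto, coupling_interval=ci),
                                  config, params, init_cell, post_s2=post_s2)
    cis = np.arange(ci_range[0], ci_range[1] + 0.5 * ci_step, ci_step)
    sustained = np.zeros(len(cis), dtype=bool)
    rotations = np.zeros(len(cis))
    for i, ci in enumerate(cis):
        res = runner(float(ci))
        t_s2 = res.stim_onsets[-1] if len(res.stim_onsets) else 0.0
        ok, rot, _ = classify_episode(res, min_rotations, analysis_start=t_s2)
        sustained[i] = ok
        rotations[i] = rot
    return VWResult(ci_values=cis, sustained=sustained, rotations=rotations)


def restitution_protocol(config: StrandConfig, params: IonicParameters,
                         init_cell: MembraneState, ci_values: Sequence[float],
                         amplitude: float, s1_bcl: float = 1000.0,
                         s1_count: int = 10) -> RestitutionCurve:
    """S1-S2 restitution on the strand.

    A train of ``s1_count`` S1 at BCL ``s1_bcl`` is followed by a premature
    S2 at each coupling interval (descending scan); APD and CV are read at
    the node at 2L/3 from the stimulated edge when the S2 wave propagates.
    Non-propagated S2 beats yield absent points, not errors.
    """
    i_probe = int(round(2.0 * config.N / 3.0))
    i_cv1 = int(round(config.N / 3.0))
    region = left_edge_mask(config)
    t_last_s1 = (s1_count - 1) * s1_bcl
    out_ci, out_apd, out_cv, out_prop = [], [], [], []
    for ci in sorted(ci_values, reverse=True):
        onsets = [i * s1_bcl for i in range(s1_count)] + [t_last_s1 + ci]
        stim = StimulusSpec(region=region, amplitude=amplitude, onset_times=onsets)
        rec = RecordSpec(movie_stride=50.0, probes=(i_cv1, i_probe))
        res = run_simulation(config, params, [stim], t_last_s1 + ci + 500.0, rec,
                             paced_cell_state=init_cell)
        t = res.probe_times
        acts = activation_times(t, res.probe_V[1])
        s2_acts = acts[acts > t_last_s1 + ci]
        if not len(s2_acts):
            out_ci.append(ci); out_apd.append(np.nan); out_cv.append(np.nan)
            out_prop.append(False)
            continue
        a2 = s2_acts[0]
        apd = apd90(t, res.probe_V[1], a2)
        a1_acts = activation_times(t, res.probe_V[0])
        a1_s2 = a1_acts[a1_acts > t_last_s1 + ci]
        cv = np.nan
        if len(a1_s2) and a2 > a1_s2[0]:
            dist = (i_probe - i_cv1) * config.dx
            cv = dist / ((a2 - a1_s2[0]) / 1000.0)
        out_ci.append(ci)
        out_apd.append(np.nan if apd is None else apd)
        out_cv.append(cv)
        out_prop.append(True)
    order = np.argsort(out_ci)
    return RestitutionCurve(ci=np.asarray(out_ci)[order],
                            apd=np.asarray(out_apd)[order],
                            cv=np.asarray(out_cv)[order],
                            propagated=np.asarray(out_prop)[order])
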