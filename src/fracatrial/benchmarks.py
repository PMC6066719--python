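"""Canonical benchmark drivers for the published study conditions.

Each function runs one complete, self-contained protocol from scratch —
single-cell pacing, strand conduction, strand APD mapping, or a cross-field
rotor episode — and returns the measured biomarker(s).  These are the
protocols behind the reported single-cell, strand and rotor numbers; the
acceptance script and the acceptance test suite both call them.

Everything here is deterministic: there is no randomness anywhere in the
simulator.
"""

from __future__ import annotations

import numpy as np

from .biomarkers import activation_times, apd90
from .courtemanche import IonicParameters, MembraneState, Trace, \
    apply_caf_remodeling, pace_cell
from .fractional import FractionalOrder
from .protocols import CrossFieldProtocol, find_diastolic_threshold, run_crossfield
from .tissue import (RecordSpec, SheetConfig, StimulusSpec, StrandConfig,
                     left_edge_mask, measure_strand_cv, run_simulation)

__all__ = [
    "single_cell_diastolic_threshold", "paced_cell_run", "last_beat_biomarkers",
    "strand_threshold", "strand_cv", "strand_mid_apd", "rotor_episode",
    "PACE_BCL", "PACE_DURATION",
]

PACE_BCL = 400.0          # ms, tissue-initialization pacing rate
PACE_DURATION = 60_000.0  # ms


def single_cell_diastolic_threshold(params: IonicParameters,
                                    stim_duration: float = 2.0) -> float:
    """Minimal 2-ms amplitude (pA/pF) that fires an AP from rest (1% rel.)."""
    lo, hi = 0.5, 100.0
    while (hi - lo) / hi > 0.01:
        mid = 0.5 * (lo + hi)
        tr = pace_cell(params, bcl=1e9, duration=100.0, stim_amplitude=mid,
                       stim_duration=stim_duration)
        if tr.V.max() > 0.0:
            hi = mid
        else:
            lo = mid
    return hi


def paced_cell_run(params: IonicParameters, bcl: float = PACE_BCL,
                   duration: float = PACE_DURATION) -> Trace:
    """Pace a cell at 2x its diastolic threshold (the standard protocol)."""
    amp = 2.0 * single_cell_diastolic_threshold(params)
    return pace_cell(params, bcl=bcl, duration=duration, stim_amplitude=amp)


def last_beat_biomarkers(trace: Trace) -> tuple:
    """(APD90 of the final AP, diastolic V just before the final stimulus)."""
    acts = activation_times(trace.times, trace.V)
    rest_idx = int(np.searchsorted(trace.times, trace.stim_times[-1])) - 1
    return (apd90(trace.times, trace.V, acts[-1]),
            float(trace.V[rest_idx]))


def strand_threshold(params: IonicParameters, init_cell: MembraneState,
                     kappa: float = 0.40) -> float:
    """Diastolic threshold of the reference strand at gamma = 2 + j0."""
    cfg = StrandConfig(kappa=kappa, order=FractionalOrder(2.0, 0.0))
    return find_diastolic_threshold(cfg, params, init_cell)


def strand_cv(params: IonicParameters, init_cell: MembraneState,
              alpha: float, beta: float, kappa: float,
              amplitude: float) -> float | None:
    """Plane-wave CV (cm/s) between L/3 and 2L/3 of the 2-cm/128-node strand;
    None when the wave fails to propagate."""
    cfg = StrandConfig(kappa=kappa, order=FractionalOrder(alpha, beta))
    return measure_strand_cv(cfg, params, init_cell, amplitude=amplitude,
                             duration=300.0)


def strand_mid_apd(params: IonicParameters, init_cell: MembraneState,
                   alpha: float, beta: float, kappa: float, amplitude: float,
                   bcl: float = 1000.0, n_beats: int = 10) -> float:
    """Mid-cell APD90 of the last beat of a BCL-paced strand run.

    The published strand protocol paces the left edge at BCL 1000 ms over a
    10-s evolution and reads the middle cell.
    """
    cfg = StrandConfig(kappa=kappa, order=FractionalOrder(alpha, beta))
    stim = StimulusSpec(region=left_edge_mask(cfg), amplitude=amplitude,
                        onset_times=[i * bcl for i in range(n_beats)])
    rec = RecordSpec(movie_stride=20.0, probes=(cfg.N // 2,))
    res = run_simulation(cfg, params, [stim], n_beats * bcl, rec,
                         paced_cell_state=init_cell)
    t, v = res.probe_times, res.probe_V[0]
    acts = activation_times(t, v)
    return apd90(t, v, acts[-1])


def rotor_episode(params: IonicParameters, init_cell: MembraneState,
                  alpha: float, beta: float, kappa: float = 0.40,
                  coupling_interval: float = 118.0, N: int = 64,
                  post_s2: float = 500.0, amplitude: float = 44.0):
    """S1-S2 cross-field episode on the reduced (half-resolution) sheet.

    Returns (SimResult, sustained?, rotations, filaments).  The default
    coupling interval sits inside the vulnerable window of the standard
    diffusion case on this grid.
    """
    from .protocols import classify_episode

    cfg = SheetConfig(N=N, dx=0.03215 * 128 / N, kappa=kappa,
                      order=FractionalOrder(alpha, beta))
    proto = CrossFieldProtocol(s1_count=1, coupling_interval=coupling_interval,
                               amplitude=amplitude)
    res = run_crossfield(proto, cfg, params, init_cell, post_s2=post_s2)
    ok, rot, filaments = classify_episode(
        res, analysis_start=res.stim_onsets[-1] + 20.0)
    return res, ok, rot, filaments
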