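"""Shared fixtures: paced single-cell states and stimulus amplitudes.

The expensive 60-s pacing runs (the canonical tissue initial conditions)
are computed once per session and shared across test modules.
"""

import numpy as np
import pytest

from fracatrial.courtemanche import (IonicParameters, apply_caf_remodeling,
                                     pace_cell)

PACE_BCL = 400.0
PACE_DURATION = 60_000.0


@pytest.fixture(scope="session")
def baseline_params():
    return IonicParameters()


@pytest.fixture(scope="session")
def caf_params(baseline_params):
    return apply_caf_remodeling(baseline_params)


from fracatrial.benchmarks import single_cell_diastolic_threshold as \
    single_cell_threshold


@pytest.fixture(scope="session")
def baseline_amplitude(baseline_params):
    """Twice the diastolic threshold of the non-remodeled cell (pA/pF)."""
    return 2.0 * single_cell_threshold(baseline_params)


@pytest.fixture(scope="session")
def caf_amplitude(caf_params):
    return 2.0 * single_cell_threshold(caf_params)


@pytest.fixture(scope="session")
def paced_baseline(baseline_params, baseline_amplitude):
    """Non-remodeled cell paced 60 s at BCL 400 ms (full trace + end state)."""
    return pace_cell(baseline_params, bcl=PACE_BCL, duration=PACE_DURATION,
                     stim_amplitude=baseline_amplitude)


@pytest.fixture(scope="session")
def paced_caf(caf_params, caf_amplitude):
    """CAF-remodeled cell paced 60 s at BCL 400 ms."""
    return pace_cell(caf_params, bcl=PACE_BCL, duration=PACE_DURATION,
                     stim_amplitude=caf_amplitude)


def last_beat_biomarkers(trace):
    """(APD90, diastolic V before the last stimulus) of a paced trace."""
    from fracatrial.biomarkers import activation_times, apd90

    acts = activation_times(trace.times, trace.V)
    rest_idx = np.searchsorted(trace.times, trace.stim_times[-1]) - 1
    return apd90(trace.times, trace.V, acts[-1]), float(trace.V[rest_idx])
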