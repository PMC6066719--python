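"""Hilbert-phase maps, phase-singularity tracking and rotor-tip metrics.

The rotor tip is located as a phase singularity: a point where the phase of
the analytic (Hilbert-transformed) voltage signal is undefined and the
winding number of the phase around a 2x2 plaquette of nodes is +/-2*pi.
Tips are linked across frames into filaments — the (x, y, t) trajectory of
the tip — whose planar extent is summarized by the maximal tip displacement

    D = max_{j,k} sqrt((x_j - x_k)^2 + (y_j - y_k)^2),

the maximum Euclidean distance between any two filament points projected on
the tissue plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert
from scipy.spatial.distance import pdist

__all__ = [
    "PhaseMovie", "TipPoint", "Filament", "phase_movie",
    "find_singularities", "link_filament", "max_tip_displacement",
    "count_rotations", "sustained_rotor",
]

WINDING_EPS = 0.1          # plaquette winding threshold: |sum| >= pi*(2 - eps)
MAX_TIP_JUMP = 0.3         # cm per frame for nearest-neighbour linking


@dataclass
class PhaseMovie:
    """Per-node instantaneous phase in (-pi, pi] plus frame times (ms)."""

    times: np.ndarray
    phase: np.ndarray            # (n_frames, ny, nx)
    dx: float                    # node spacing (cm)
    mask: np.ndarray | None = None   # nodes with undefined phase


@dataclass(frozen=True)
class TipPoint:
    x: float                     # cm
    y: float                     # cm
    t: float                     # ms
    charge: int                  # +1 / -1 (chirality)


@dataclass
class Filament:
    """Time-ordered rotor-tip trajectory; gaps between frames are allowed."""

    points: list = field(default_factory=list)

    def append(self, p: TipPoint) -> None:
        if self.points and p.t <= self.points[-1].t:
            raise ValueError("filament times must increase strictly")
        self.points.append(p)

    def __len__(self):
        return len(self.points)

    @property
    def xy(self) -> np.ndarray:
        return np.array([(p.x, p.y) for p in self.points])

    @property
    def times(self) -> np.ndarray:
        return np.array([p.t for p in self.points])

    @property
    def duration(self) -> float:
        return self.points[-1].t - self.points[0].t if len(self.points) > 1 else 0.0

    def mean_position(self) -> tuple:
        xy = self.xy
        return float(xy[:, 0].mean()), float(xy[:, 1].mean())


def phase_movie(times: np.ndarray, V: np.ndarray, dx: float) -> PhaseMovie:
    """Instantaneous phase of every node's de-meaned voltage time series.

    V has shape (n_frames, ny, nx) (or (n_frames, n_nodes)).  Each node's
    trace is de-meaned and Hilbert-transformed along time; the phase is
    angle(V - <V> + i*Im H[V]).  Nodes with (numerically) constant traces
    have no defined phase and are masked.
    """
    V = np.asarray(V, dtype=float)
    times = np.asarray(times, dtype=float)
    shape = V.shape[1:]
    flat = V.reshape(V.shape[0], -1)
    demeaned = flat - flat.mean(axis=0, keepdims=True)
    const = np.ptp(demeaned, axis=0) < 1e-9
    analytic = hilbert(demeaned, axis=0)
    phase = np.angle(analytic)
    phase[:, const] = 0.0
    mask = const.reshape(shape)
    return PhaseMovie(times=times, phase=phase.reshape(V.shape), dx=dx,
                      mask=mask if mask.any() else None)


def _wrap(dphi: np.ndarray) -> np.ndarray:
    return (dphi + np.pi) % (2.0 * np.pi) - np.pi


def find_singularities(phase_frame: np.ndarray, dx: float,
                       t: float = 0.0, eps: float = WINDING_EPS) -> list:
    """Phase singularities of one 2-D phase frame.

    The wrapped phase differences are summed around every 2x2 plaquette;
    windings of magnitude >= pi*(2 - eps) mark a tip at the plaquette
    center, with charge = sign of the winding.  Node (i, j) sits at
    ((j + 0.5) dx, (i + 0.5) dx).
    """
    p = np.asarray(phase_frame)
    if p.ndim != 2:
        raise ValueError("phase frame must be 2-D")
    d1 = _wrap(p[:-1, 1:] - p[:-1, :-1])     # right along top edge
    d2 = _wrap(p[1:, 1:] - p[:-1, 1:])       # down along right edge
    d3 = _wrap(p[1:, :-1] - p[1:, 1:])       # left along bottom edge
    d4 = _wrap(p[:-1, :-1] - p[1:, :-1])     # up along left edge
    winding = d1 + d2 + d3 + d4
    ii, jj = np.nonzero(np.abs(winding) >= np.pi * (2.0 - eps))
    tips = []
    for i, j in zip(ii, jj):
        tips.append(TipPoint(x=float((j + 1.0) * dx), y=float((i + 1.0) * dx),
                             t=float(t), charge=int(np.sign(winding[i, j]))))
    return tips


def link_filament(tips_per_frame: list, frame_times: np.ndarray | None = None,
                  max_jump: float = MAX_TIP_JUMP) -> list:
    """Greedy nearest-neighbour association of tips across frames.

    Tips in consecutive frames closer than ``max_jump`` (cm) continue a
    track; unmatched tips open new filaments.  Returns filaments sorted by
    decreasing length.
    """
    open_tracks: list = []
    done: list = []
    for frame in tips_per_frame:
        unmatched = list(frame)
        still_open = []
        # match existing tracks to the nearest available tip
        for track in open_tracks:
            last = track.points[-1]
            best, best_d = None, max_jump
            for tip in unmatched:
                d = np.hypot(tip.x - last.x, tip.y - last.y)
                if d <= best_d and tip.charge == last.charge:
                    best, best_d = tip, d
            if best is not None:
                track.append(best)
                unmatched.remove(best)
                still_open.append(track)
            else:
                done.append(track)
        for tip in unmatched:
            f = Filament()
            f.append(tip)
            still_open.append(f)
        open_tracks = still_open
    done.extend(open_tracks)
    return sorted(done, key=len, reverse=True)


def max_tip_displacement(filament: Filament) -> float:
    """Tip displacement metric D (cm): maximal pairwise planar distance."""
    if not len(filament):
        raise ValueError("empty filament")
    xy = filament.xy
    if len(xy) < 2:
        return 0.0
    return float(pdist(xy).max())


def count_rotations(filament: Filament, movie: PhaseMovie) -> float:
    """Number of rotations of the rotor around the filament.

    The phase at the node nearest the filament's temporal-mean position is
    unwrapped over the filament's lifetime; the total advance divided by
    2*pi is the rotation count.  A filament spanning fewer than 2 frames
    counts zero rotations.
    """
    if len(filament) < 2:
        return 0.0
    x0, y0 = filament.mean_position()
    ny, nx = movie.phase.shape[1:]
    j = min(nx - 1, max(0, int(round(x0 / movie.dx - 0.5))))
    i = min(ny - 1, max(0, int(round(y0 / movie.dx - 0.5))))
    if movie.mask is not None and movie.mask[i, j]:
        # fall back to the nearest unmasked neighbour
        free = np.argwhere(~movie.mask)
        d = (free[:, 0] - i) ** 2 + (free[:, 1] - j) ** 2
        i, j = free[np.argmin(d)]
    t0, t1 = filament.times[0], filament.times[-1]
    sel = (movie.times >= t0) & (movie.times <= t1)
    trace = np.unwrap(movie.phase[sel, i, j])
    return float(abs(trace[-1] - trace[0]) / (2.0 * np.pi))


def sustained_rotor(filaments: list, movie: PhaseMovie,
                    min_rotations: float = 2.0) -> tuple:
    """Classify an episode: does a persistent singularity complete at least
    ``min_rotations`` rotations?  Returns (bool, best rotation count).

    Both conditions are required: a singularity track must persist AND the
    local phase must advance by >= min_rotations full turns during the
    track's lifetime (plane waves crossing a point also advance the phase
    but carry no singularity).
    """
    best = 0.0
    for f in filaments:
        if len(f) < 2:
            continue
        r = count_rotations(f, movie)
        best = max(best, r)
        if r >= min_rotations:
            return True, r
    return False, best
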