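"""Run configuration (YAML), result persistence (npz) and CSV summaries."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .courtemanche import IonicParameters, MembraneState, apply_caf_remodeling
from .fractional import FractionalOrder
from .tissue import SheetConfig, SimResult, StrandConfig, TissueState

__all__ = [
    "load_config", "save_config", "config_hash", "build_configs",
    "save_result", "load_result", "trace_to_csv", "tips_to_csv",
]

_KNOWN_KEYS = {
    "grid": {"kind", "L", "N", "dx", "dt", "splitting"},
    "order": {"alpha", "beta"},
    "kappa": {"value", "k_scale", "lowpass_frac"},
    "cell": {"caf", "ach_nm", "clamp_na_k"},
    "protocol": {"name", "bcl", "duration", "amplitude", "stim_duration",
                 "s1_count", "coupling_interval", "ci_min", "ci_max", "ci_step",
                 "post_s2"},
    "recording": {"movie_stride", "probes", "currents", "peaks"},
    "output": {"dir", "prefix"},
}


def load_config(path) -> dict:
    """Load and schema-check a run configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    for section, keys in cfg.items():
        if section not in _KNOWN_KEYS:
            raise ValueError(f"unknown config section '{section}'")
        unknown = set(keys or {}) - _KNOWN_KEYS[section]
        if unknown:
            raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
    return cfg


def save_config(cfg: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def build_configs(cfg: dict):
    """Resolve a config dict into (tissue_config, ionic_params)."""
    g = cfg.get("grid", {})
    o = cfg.get("order", {})
    k = cfg.get("kappa", {})
    order = FractionalOrder(alpha=float(o.get("alpha", 2.0)),
                            beta=float(o.get("beta", 0.0)))
    common = dict(order=order, dt=float(g.get("dt", 0.01)),
                  kappa=float(k.get("value", 0.40)),
                  splitting=g.get("splitting", "lie"))
    if "k_scale" in k:
        common["k_scale"] = float(k["k_scale"])
    if "lowpass_frac" in k:
        lf = k["lowpass_frac"]
        common["lowpass_frac"] = None if lf is None else float(lf)
    kind = g.get("kind", "strand")
    if kind == "strand":
        tissue = StrandConfig(L=float(g.get("L", 2.0)), N=int(g.get("N", 128)),
                              **common)
    elif kind == "sheet":
        tissue = SheetConfig(N=int(g.get("N", 128)), dx=float(g.get("dx", 0.03215)),
                             **common)
    else:
        raise ValueError(f"unknown grid kind '{kind}'")
    c = cfg.get("cell", {})
    params = IonicParameters(clamp_na_k=bool(c.get("clamp_na_k", True)))
    if c.get("caf", False):
        params = apply_caf_remodeling(params, ach_nm=float(c.get("ach_nm", 5.0)))
    return tissue, params


def save_result(result: SimResult, path) -> None:
    """Persist a SimResult as a compressed npz container (round-trips)."""
    payload = dict(
        times=result.times, V=result.V, probe_idx=result.probe_idx,
        probe_times=result.probe_times, probe_V=result.probe_V,
        final_S=result.final_state.S,
        final_shape=np.asarray(result.final_state.shape),
        stim_onsets=result.stim_onsets,
        propagation_failure=np.asarray(result.propagation_failure),
    )
    if result.peaks is not None:
        payload["peaks"] = result.peaks
    if result.probe_currents is not None:
        payload["probe_currents"] = result.probe_currents
        payload["current_times"] = result.current_times
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, **payload)


def load_result(path, config=None) -> SimResult:
    with np.load(path) as z:
        return SimResult(
            times=z["times"], V=z["V"], probe_idx=z["probe_idx"],
            probe_times=z["probe_times"], probe_V=z["probe_V"],
            final_state=TissueState(z["final_S"], tuple(int(v) for v in z["final_shape"])),
            config=config, stim_onsets=z["stim_onsets"],
            propagation_failure=bool(z["propagation_failure"]),
            peaks=z["peaks"] if "peaks" in z else None,
            current_times=z["current_times"] if "current_times" in z else None,
            probe_currents=z["probe_currents"] if "probe_currents" in z else None,
        )


def trace_to_csv(times: np.ndarray, V: np.ndarray, path) -> None:
    """Two-column time (ms) / V (mV) CSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_ms": times, "V_mV": V}).to_csv(path, index=False)


def tips_to_csv(filaments, path) -> None:
    """Rotor-tip tracks as tidy CSV: t, x, y, charge, track_id."""
    rows = []
    for tid, f in enumerate(filaments):
        for p in f.points:
            rows.append((p.t, p.x, p.y, p.charge, tid))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["t_ms", "x_cm", "y_cm", "charge", "track_id"]) \
        .to_csv(path, index=False)
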