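"""File formats, configuration, manifests and synthetic test fixtures.

All outputs are plain delimited text: a header row preceded by
'#'-prefixed metadata lines (dt, stride, seed, ...), so files are
diff-able and self-describing.  Parameter sets serialise to flat
key/value YAML using the conventional symbol names (C, gCa, ..., kc,
g1Ca, ..., NBK).
"""

from __future__ import annotations

import datetime
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .events import Event
from .model_core import CHANNEL_TYPES, ModelParameters
from .simulate import Trace

__all__ = [
    "write_trace",
    "read_trace",
    "write_events",
    "read_events",
    "write_params",
    "read_params",
    "params_to_dict",
    "params_from_dict",
    "make_fixture",
    "write_manifest",
    "read_manifest",
]

TRACE_COLUMNS = ["t_ms", "V_mV", "Ca_uM", "m", "n", "s", "f",
                 "open_Ca", "open_K", "open_SK", "open_BK"]
EVENT_COLUMNS = ["t_start", "t_end", "duration_ms", "V_max_mV", "n_osc", "label"]

#: field name <-> config key (conventional symbol names)
_PARAM_KEYS = {
    "C": "C", "g_Ca": "gCa", "g_K": "gK", "g_SK": "gSK", "g_BK": "gBK",
    "g_l": "gl", "V_Ca": "VCa", "V_K": "VK", "V_l": "Vl",
    "tau_m": "taum", "tau_n": "taun", "tau_s": "taus", "tau_BK": "tauBK",
    "v_m": "vm", "s_m": "sm", "v_n": "vn", "s_n": "sn", "v_f": "vf", "s_f": "sf",
    "k_s": "ks", "f_c": "fc", "alpha": "alpha", "k_c": "kc",
    "g1_Ca": "g1Ca", "g1_K": "g1K", "g1_SK": "g1SK", "g1_BK": "g1BK",
    "N_Ca": "NCa", "N_K": "NK", "N_SK": "NSK", "N_BK": "NBK",
}
_KEY_TO_FIELD = {v: k for k, v in _PARAM_KEYS.items()}


# ----------------------------------------------------------------- traces

def write_trace(path, trace: Trace) -> None:
    """Write a trace as CSV with '#' metadata lines (full precision)."""
    path = Path(path)
    df = trace.to_dataframe()
    with open(path, "w") as fh:
        fh.write(f"# dt_ms={trace.dt!r}\n")
        fh.write(f"# stride={trace.stride}\n")
        fh.write(f"# seed={trace.seed}\n")
        fh.write(f"# transient_discard_ms={trace.transient_discard!r}\n")
        fh.write(f"# n_perturbations={trace.n_perturbations}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_metadata(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    return meta


def read_trace(path) -> Trace:
    """Read a trace written by :func:`write_trace`; exact roundtrip."""
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file {path} missing columns {missing}")
    if "dt_ms" in meta:
        dt = float(meta["dt_ms"])
    elif len(df) > 1:
        dt = float(np.diff(df["t_ms"].to_numpy()[:2])[0])
    else:
        raise ValueError(f"cannot infer dt from {path}")
    stride = int(meta.get("stride", 1))
    t = df["t_ms"].to_numpy()
    if len(t) > 1 and not np.allclose(np.diff(t), dt * stride, rtol=1e-9, atol=1e-12):
        raise ValueError(f"non-uniform time grid in {path}")
    open_counts = {}
    for ch in CHANNEL_TYPES:
        col = df[f"open_{ch}"]
        if col.notna().all() and len(col) > 0:
            open_counts[ch] = col.to_numpy().astype(np.int64)
    seed = meta.get("seed")
    return Trace(dt=dt, V=df["V_mV"].to_numpy(), Ca=df["Ca_uM"].to_numpy(),
                 m=df["m"].to_numpy(), n=df["n"].to_numpy(),
                 s=df["s"].to_numpy(), f=df["f"].to_numpy(),
                 open_counts=open_counts, stride=stride,
                 seed=None if seed in (None, "None") else int(seed),
                 transient_discard=float(meta.get("transient_discard_ms", 0.0)),
                 n_perturbations=int(meta.get("n_perturbations", 0)))


# ----------------------------------------------------------------- events

def write_events(path, events: Sequence[Event]) -> None:
    df = pd.DataFrame([dict(t_start=e.t_start, t_end=e.t_end,
                            duration_ms=e.duration, V_max_mV=e.V_max,
                            n_osc=e.n_oscillations, label=e.label)
                       for e in events], columns=EVENT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event file {path} missing columns {missing}")
    return df


# ------------------------------------------------------------- parameters

def params_to_dict(p: ModelParameters) -> dict:
    return {key: getattr(p, field) for field, key in _PARAM_KEYS.items()}


def params_from_dict(d: dict, base: Optional[ModelParameters] = None) -> ModelParameters:
    base = base or ModelParameters()
    unknown = set(d) - set(_KEY_TO_FIELD)
    if unknown:
        raise ValueError(f"unknown parameter keys {sorted(unknown)}")
    changes = {_KEY_TO_FIELD[k]: v for k, v in d.items()}
    return base.replace(**changes)


def write_params(path, p: ModelParameters) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(p), fh, sort_keys=False)


def read_params(path, base: Optional[ModelParameters] = None) -> ModelParameters:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return params_from_dict(data, base)


# ---------------------------------------------------------------- fixtures

def make_fixture(kind: str, rng: Optional[np.random.Generator] = None,
                 **params) -> Trace:
    """Synthetic voltage traces for exercising the event analysis.

    Kinds: ``square_pulse`` (one flat supra-threshold step of exact
    duration), ``spike_like`` (smooth sub-100 ms bump, no plateau
    oscillations), ``burst_with_oscillations`` (plateau with a known
    number of post-peak local maxima) and ``subthreshold_noise`` (never
    crosses the detection threshold).  Deterministic given the rng seed.
    """
    builders = {
        "square_pulse": _fixture_square_pulse,
        "spike_like": _fixture_spike_like,
        "burst_with_oscillations": _fixture_burst,
        "subthreshold_noise": _fixture_subthreshold,
    }
    if kind not in builders:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {sorted(builders)}")
    return builders[kind](rng=rng, **params)


def _as_trace(V: np.ndarray, dt: float) -> Trace:
    n = len(V)
    nan = np.full(n, np.nan)
    return Trace(dt=dt, V=V.astype(float), Ca=nan.copy(), m=nan.copy(),
                 n=nan.copy(), s=nan.copy(), f=nan.copy(), open_counts={},
                 stride=1, transient_discard=0.0)


def _fixture_square_pulse(rng=None, duration: float = 80.0, level: float = -20.0,
                          baseline: float = -60.0, t_on: float = 20.0,
                          total: float = 200.0, dt: float = 0.1) -> Trace:
    V = np.full(int(round(total / dt)) + 1, baseline)
    i_on = int(round(t_on / dt))
    i_off = i_on + int(round(duration / dt))
    # inclusive endpoints so first-to-last supra sample spans exactly `duration`
    V[i_on:i_off + 1] = level
    return _as_trace(V, dt)


def _fixture_spike_like(rng=None, width: float = 60.0, peak: float = -5.0,
                        baseline: float = -60.0, t_on: float = 20.0,
                        total: float = 200.0, dt: float = 0.1) -> Trace:
    """Raised-cosine bump: monotone rise then fall, width < 100 ms."""
    if width >= 100.0:
        raise ValueError("spike_like width must stay below 100 ms")
    t = np.arange(0.0, total + dt / 2, dt)
    V = np.full(t.shape, baseline)
    inside = (t >= t_on) & (t <= t_on + width)
    phase = (t[inside] - t_on) / width
    V[inside] = baseline + (peak - baseline) * np.sin(np.pi * phase) ** 2
    return _as_trace(V, dt)


def _fixture_burst(rng=None, n_osc: int = 3, plateau: float = -19.0,
                   osc_amp: float = 4.0, peak: float = -10.0,
                   baseline: float = -60.0, period: float = 30.0,
                   dt: float = 0.1) -> Trace:
    """Rise to a single peak, then ``n_osc`` plateau oscillations of
    amplitude ``osc_amp`` (prominence 2*osc_amp), then a fall."""
    rise_t = np.arange(0.0, 20.0, dt)
    rise = baseline + (peak - baseline) * np.sin(0.5 * np.pi * rise_t / 20.0)
    osc_t = np.arange(dt, n_osc * period + period / 2, dt)
    osc = plateau + osc_amp * np.cos(2 * np.pi * osc_t / period)
    fall_t = np.arange(dt, 20.0 + dt / 2, dt)
    fall = np.interp(fall_t, [0.0, 20.0], [osc[-1], baseline])
    pad = np.full(int(20.0 / dt), baseline)
    V = np.concatenate([pad, rise, osc, fall, pad])
    return _as_trace(V, dt)


def _fixture_subthreshold(rng=None, baseline: float = -60.0, sd: float = 2.0,
                          ceiling: float = -50.0, total: float = 1000.0,
                          dt: float = 0.1) -> Trace:
    rng = rng or np.random.default_rng(0)
    t = np.arange(0.0, total + dt / 2, dt)
    V = np.minimum(baseline + sd * rng.standard_normal(t.shape), ceiling)
    return _as_trace(V, dt)


# ---------------------------------------------------------------- manifest

def write_manifest(path, command: str, seed: Optional[int],
                   config: dict, outputs: Sequence[str] = ()) -> None:
    """Record everything needed to rerun a command bit-identically."""
    from . import __version__

    doc = dict(command=command, seed=seed, config=config,
               outputs=list(outputs), version=__version__,
               created=datetime.datetime.now(datetime.timezone.utc).isoformat())
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
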