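"""Configuration and result serialization.

All result files are plain CSV with a JSON sidecar (``<name>.meta.json``)
recording the configuration that produced them; reals are written with 17
significant digits so a read-back reproduces the float64 values bitwise.
Run configuration is a flat JSON object of documented keys; unknown keys
are rejected by name and invalid values raise with the field and the
violated constraint.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .analysis import BifurcationResult, LyapunovResult
from .control import ErrorTrajectory
from .frac_calc import OrderSpec
from .model import PRESETS, NeuronParams, resolve_preset
from .network import Raster
from .simulate import SimConfig, Trajectory, vo_presets

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_outputs",
    "read_trajectory",
]

_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class RunConfig:
    """Flat, fully serializable run configuration.

    Either ``preset`` or the four explicit parameters must be given.  The
    order is commensurate (``beta``), incommensurate (``beta1, beta2``) or
    variable (``vo_preset`` naming a registered profile).
    """

    preset: Optional[str] = None
    sigma: Optional[float] = None
    eta: Optional[float] = None
    psi: Optional[float] = None
    nu: Optional[float] = None
    I: float = 0.0
    beta: Optional[float] = None
    beta1: Optional[float] = None
    beta2: Optional[float] = None
    vo_preset: Optional[str] = None
    clip_policy: str = "clip"
    steps: int = 6000
    x0: float = -63.0
    y0: Optional[float] = None
    variant: Optional[str] = None
    memory: Optional[int] = None
    divergence_cap: float = 1e8
    reset_mode: str = "overwrite"
    seed: int = 0

    def neuron_params(self) -> NeuronParams:
        if self.preset is not None:
            return resolve_preset(self.preset, I=self.I)
        if None in (self.sigma, self.eta, self.psi, self.nu):
            raise ValueError(
                "RunConfig: either 'preset' or all of sigma/eta/psi/nu required"
            )
        return NeuronParams(self.sigma, self.eta, self.psi, self.nu, self.I)

    def order_spec(self) -> OrderSpec:
        if self.vo_preset is not None:
            return OrderSpec.variable(vo_presets(self.vo_preset),
                                      clip_policy=self.clip_policy)
        if self.beta1 is not None or self.beta2 is not None:
            b1 = 1.0 if self.beta1 is None else self.beta1
            b2 = 1.0 if self.beta2 is None else self.beta2
            return OrderSpec.incommensurate(b1, b2, self.clip_policy)
        return OrderSpec.commensurate(1.0 if self.beta is None else self.beta,
                                      self.clip_policy)

    def sim_config(self) -> SimConfig:
        return SimConfig(
            steps=self.steps, x0=self.x0, y0=self.y0, variant=self.variant,
            memory=self.memory, divergence_cap=self.divergence_cap,
            seed=self.seed, reset_mode=self.reset_mode,
        )


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def _validate(cfg: RunConfig) -> RunConfig:
    if cfg.preset is not None and cfg.preset not in PRESETS:
        raise ValueError(f"config field 'preset': unknown preset {cfg.preset!r} "
                         f"(known: {sorted(PRESETS)})")
    if cfg.clip_policy not in ("clip", "reject"):
        raise ValueError("config field 'clip_policy': must be 'clip' or 'reject'")
    if cfg.clip_policy == "reject":
        for name in ("beta", "beta1", "beta2"):
            v = getattr(cfg, name)
            if v is not None and not 0.0 < v <= 1.0:
                raise ValueError(
                    f"config field {name!r}: {v} outside (0, 1] with clip_policy='reject'"
                )
    if cfg.steps < 1:
        raise ValueError("config field 'steps': must be >= 1")
    if cfg.vo_preset is not None:
        vo_presets(cfg.vo_preset)  # raises listing the registry
    cfg.sim_config()               # SimConfig invariants
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a flat JSON run configuration."""
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config root must be a JSON object")
    unknown = sorted(set(raw) - _FIELDS)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return _validate(RunConfig(**raw))


def save_config(cfg: RunConfig, path) -> None:
    data = {k: v for k, v in dataclasses.asdict(cfg).items() if v is not None}
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def _meta_dict(meta: dict) -> dict:
    """JSON-safe view of a result's meta dictionary."""
    out = {}
    for k, v in meta.items():
        if isinstance(v, (NeuronParams, SimConfig)):
            out[k] = dataclasses.asdict(v)
        elif isinstance(v, OrderSpec):
            out[k] = {"mode": v.mode,
                      "beta": v.beta if v.is_constant() else "function",
                      "clip_policy": v.clip_policy}
        elif isinstance(v, np.ndarray):
            out[k] = v.tolist()
        elif isinstance(v, (str, int, float, bool, list, tuple, type(None))):
            out[k] = v
        else:
            out[k] = repr(v)
    return out


def _sidecar(path: Path, meta: dict, extra: dict | None = None) -> None:
    data = _meta_dict(meta)
    if extra:
        data.update(extra)
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(data, indent=2, sort_keys=True, default=str) + "\n"
    )


def write_outputs(result, path) -> Path:
    """Write a result object to CSV (+ JSON sidecar) at ``path``.

    Trajectory        -> step,x,y,spiked
    Raster            -> step,neuron_id            (sorted by step, id)
    BifurcationResult -> param,x_sample            (long format)
    LyapunovResult    -> step,zeta
    ErrorTrajectory   -> step,upsilon1,upsilon2
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(result, Trajectory):
        n = len(result.states)
        spiked = np.zeros(n, dtype=int)
        spiked[result.spikes] = 1
        df = pd.DataFrame({"step": np.arange(n), "x": result.x, "y": result.y,
                           "spiked": spiked})
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        _sidecar(path, result.meta, {"n0": result.n0, "resets": result.resets})
    elif isinstance(result, Raster):
        ev = result.events
        order = np.lexsort((ev[:, 1], ev[:, 0])) if len(ev) else []
        df = pd.DataFrame(ev[order] if len(ev) else np.empty((0, 2), int),
                          columns=["step", "neuron_id"])
        df.to_csv(path, index=False)
        _sidecar(path, result.meta,
                 {"n_steps": result.n_steps, "n_neurons": result.n_neurons})
    elif isinstance(result, BifurcationResult):
        rows_p, rows_x = [], []
        for v, xs in zip(result.grid, result.samples):
            rows_p.extend([v] * len(xs))
            rows_x.extend(xs.tolist())
        pd.DataFrame({"param": rows_p, "x_sample": rows_x}).to_csv(
            path, index=False, float_format=_FLOAT_FMT)
        _sidecar(path, result.meta, {"axis": result.axis, "n0": result.n0,
                                     "lyapunov": result.lyapunov})
    elif isinstance(result, LyapunovResult):
        pd.DataFrame({"step": np.arange(1, result.n_steps + 1),
                      "zeta": result.zeta_series}).to_csv(
            path, index=False, float_format=_FLOAT_FMT)
        _sidecar(path, result.meta, {"zeta_max": result.zeta_max,
                                     "renorm_interval": result.renorm_interval,
                                     "reliable": result.reliable})
    elif isinstance(result, ErrorTrajectory):
        pd.DataFrame({"step": np.arange(len(result.upsilon1)),
                      "upsilon1": result.upsilon1,
                      "upsilon2": result.upsilon2}).to_csv(
            path, index=False, float_format=_FLOAT_FMT)
        _sidecar(path, result.meta, {
            "error_matrix": result.error_matrix.tolist(),
            "eigenvalues": [[e.real, e.imag] for e in result.eigenvalues],
            "beta": result.beta, "stable": result.stable,
            "converged_step": result.converged_step,
        })
    else:
        raise TypeError(f"write_outputs: unsupported result type {type(result).__name__}")
    return path


def read_trajectory(path) -> Trajectory:
    """Read back a trajectory CSV written by :func:`write_outputs`."""
    df = pd.read_csv(path, float_precision="round_trip")
    states = df[["x", "y"]].to_numpy(dtype=float)
    spikes = df.loc[df["spiked"] == 1, "step"].to_numpy(dtype=int)
    meta_path = Path(path).with_suffix(Path(path).suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    n0 = meta.get("n0")
    return Trajectory(states=states, spikes=spikes, n0=n0, meta=meta)
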