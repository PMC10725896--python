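"""Chaos and firing-pattern diagnostics for fractional neuron trajectories.

* ``max_lyapunov`` — maximal Lyapunov exponent by the tangent-map
  (Jacobian) method: an infinitesimal perturbation is propagated through
  the *same* memory-kernel scheme as the state, with periodic norm
  renormalization; the exponent is the average log growth per step.  At
  ``beta = 1`` this reduces to the standard renormalization method for maps.
* ``bifurcation_sweep`` — post-transient state samples (and optionally the
  exponent) on a uniform parameter grid over the injected current or a
  fractional order.
* ``detect_spikes`` / ``classify_pattern`` — interspike-interval statistics
  and an operational classification of the qualitative firing labels
  (quiescent, tonic spiking, bursting, chattering, ...).
* ``divergence_step`` — first step at which a trajectory breaches the cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np

from .frac_calc import OrderSpec
from .model import NeuronParams
from .simulate import (
    SimConfig,
    System,
    Trajectory,
    _KernelState,
    integrate,
    neuron_system,
    simulate_commensurate,
    simulate_incommensurate,
)

__all__ = [
    "LyapunovResult",
    "BifurcationResult",
    "SpikeStats",
    "max_lyapunov",
    "bifurcation_sweep",
    "detect_spikes",
    "classify_pattern",
    "divergence_step",
]


@dataclass
class LyapunovResult:
    """Maximal-Lyapunov estimate with its running series."""

    zeta_series: np.ndarray
    zeta_max: float
    renorm_interval: int
    n_steps: int
    reliable: bool = True
    meta: dict = field(default_factory=dict)


def max_lyapunov(
    params: Optional[NeuronParams],
    order_spec: OrderSpec,
    config: SimConfig = SimConfig(),
    renorm_interval: int = 10,
    system: Optional[System] = None,
    z0: Optional[np.ndarray] = None,
    tangent_reset: bool = False,
) -> LyapunovResult:
    """Maximal Lyapunov exponent by fractional tangent-map propagation.

    The tangent pair follows the same incremental memory recursion as the
    state, with the Jacobian of the integrated variant evaluated along the
    trajectory:

        dz(n) = dz(n-1) + J(z(n-1)) dz(n-1) + sum_j dw_j J(z(j)) dz(j),

    renormalized to unit norm every ``renorm_interval`` steps (the whole
    tangent history is rescaled, which is exact for a linear recursion).
    Spike resets leave the tangent untouched by default — the reset map has
    no meaningful Jacobian; ``tangent_reset=True`` re-normalizes it to unit
    norm after each spike instead, discarding the growth accrued since the
    last renormalization.

    A ``system`` with a custom rhs/Jacobian may replace the neuron model
    (used by the engineered linear fixtures); otherwise the difference
    variant of the neuron map is used unless the config says otherwise.
    """
    if system is None:
        if params is None:
            raise ValueError("either params or system must be given")
        system = neuron_system(params, config.variant or "difference",
                               with_reset=config.apply_reset)
    if system.jac is None:
        raise ValueError("max_lyapunov requires a system with a Jacobian")
    steps = config.steps
    if steps < 100:
        raise ValueError("max_lyapunov: needs at least 100 steps")
    d = system.dim
    z = np.array(z0 if z0 is not None else config.initial_state(params), dtype=float)
    dz = np.full(d, 1.0 / math.sqrt(d))

    kernels = [_KernelState(steps) for _ in range(d)]
    F = np.empty((steps, d))
    T = np.empty((steps, d))           # Jacobian-tangent history
    zeta_series = np.empty(steps)
    log_sum = 0.0
    n_done = 0
    diverged = False

    for n in range(1, steps + 1):
        j = n - 1
        bx, by = order_spec.betas_at(j)
        betas = (bx, by) * (d // 2) if d % 2 == 0 else (bx,) * d
        F[j] = system.rhs(z)
        T[j] = system.jac(z).real @ dz
        delta = np.empty(d)
        tdelta = np.empty(d)
        for c in range(d):
            ks = kernels[c]
            ks.advance(betas[c])
            if j > 0:
                delta[c] = F[j, c] + float(np.dot(ks.dw[:j], F[:j, c]))
                tdelta[c] = T[j, c] + float(np.dot(ks.dw[:j], T[:j, c]))
            else:
                delta[c] = F[j, c]
                tdelta[c] = T[j, c]
        z = z + delta
        dz = dz + tdelta
        if not np.all(np.isfinite(z)) or np.any(np.abs(z) >= config.divergence_cap):
            diverged = True
            n_done = n - 1  # the breach step has no tangent estimate
            break
        if system.reset is not None:
            z_r, spiked = system.reset(z)
            if spiked:
                z = np.asarray(z_r, dtype=float)
                if tangent_reset:
                    g = np.linalg.norm(dz)
                    if g > 0:
                        dz /= g
                        T[: n] /= g
        if n % renorm_interval == 0:
            g = np.linalg.norm(dz)
            if g > 0 and np.isfinite(g):
                log_sum += math.log(g)
                dz /= g
                T[:n] /= g
        cur = np.linalg.norm(dz)
        zeta_series[j] = (log_sum + (math.log(cur) if cur > 0 else -np.inf)) / n
        n_done = n

    zeta_series = zeta_series[:n_done]
    zeta_max = float(zeta_series[-1]) if n_done else float("nan")
    return LyapunovResult(
        zeta_series=zeta_series,
        zeta_max=zeta_max,
        renorm_interval=renorm_interval,
        n_steps=n_done,
        reliable=not (diverged and n_done < 100),
        meta={"order_spec": order_spec, "config": config, "diverged": diverged},
    )


Axis = Literal["I", "beta", "beta1", "beta2"]


@dataclass
class BifurcationResult:
    """Per-grid-point post-transient samples along one parameter axis."""

    axis: Axis
    grid: np.ndarray
    samples: list                      # list of 1-D arrays of x values
    lyapunov: Optional[list] = None    # per-point zeta_max, if requested
    n0: Optional[list] = None          # per-point divergence step or None
    meta: dict = field(default_factory=dict)


def bifurcation_sweep(
    params: NeuronParams,
    axis: Axis,
    rng: tuple[float, float],
    delta: float = 0.005,
    order_spec: OrderSpec = OrderSpec.commensurate(1.0),
    config: SimConfig = SimConfig(steps=600),
    with_lyapunov: bool = False,
    transient_frac: float = 0.6,
    max_samples: int = 400,
) -> BifurcationResult:
    """Sweep the injected current or a fractional order on a uniform grid.

    For each grid value the matching simulator (commensurate or
    incommensurate, from ``order_spec.mode``) is run; the first
    ``transient_frac`` of the steps is discarded and at most
    ``max_samples`` of the remaining membrane-potential values recorded.
    Diverging points get empty samples and their divergence step.
    """
    lo, hi = rng
    if hi < lo or delta <= 0:
        raise ValueError("bifurcation_sweep: need a nonempty range and delta > 0")
    npts = int(round((hi - lo) / delta)) + 1
    grid = lo + delta * np.arange(npts)

    samples, lyap, n0s = [], [], []
    for v in grid:
        p = params
        if order_spec.mode == "incommensurate":
            b1, b2 = order_spec.beta
        else:
            b1 = b2 = order_spec.beta if order_spec.mode == "commensurate" else 1.0
        if axis == "I":
            p = params.with_current(float(v))
        elif axis == "beta":
            b1 = b2 = float(v)
        elif axis == "beta1":
            b1 = float(v)
        elif axis == "beta2":
            b2 = float(v)
        else:
            raise ValueError(f"unknown axis {axis!r}")
        b1 = min(1.0, max(1e-3, b1))
        b2 = min(1.0, max(1e-3, b2))
        if order_spec.mode == "incommensurate" or axis in ("beta1", "beta2"):
            traj = simulate_incommensurate(p, b1, b2, config)
            spec_here = OrderSpec.incommensurate(b1, b2)
        else:
            traj = simulate_commensurate(p, b1, config)
            spec_here = OrderSpec.commensurate(b1)
        n0s.append(traj.n0)
        if traj.n0 is not None:
            samples.append(np.empty(0))
        else:
            cut = int(transient_frac * traj.n_steps)
            xs = traj.x[cut + 1:]
            if len(xs) > max_samples:
                idx = np.linspace(0, len(xs) - 1, max_samples).round().astype(int)
                xs = xs[idx]
            samples.append(xs.copy())
        if with_lyapunov:
            if traj.n0 is not None:
                lyap.append(float("nan"))
            else:
                lyap.append(max_lyapunov(p, spec_here, config).zeta_max)
    return BifurcationResult(
        axis=axis,
        grid=grid,
        samples=samples,
        lyapunov=lyap if with_lyapunov else None,
        n0=n0s,
        meta={"delta": delta, "order_spec": order_spec, "config": config,
              "transient_frac": transient_frac},
    )


@dataclass
class SpikeStats:
    """Spike timing statistics of one trajectory."""

    spike_steps: np.ndarray
    isis: np.ndarray
    isi_cv: float
    bursts: list = field(default_factory=list)
    pattern: Optional[str] = None


def detect_spikes(
    trajectory, threshold: float = 30.0
) -> SpikeStats:
    """Spike steps, interspike intervals and their coefficient of variation.

    For a ``Trajectory`` whose integrator ran with the reset rule, the
    recorded reset events *are* the spikes.  For a bare voltage array (or a
    reset-free trajectory) spikes are upward threshold crossings.
    """
    if isinstance(trajectory, Trajectory):
        cfg = trajectory.meta.get("config")
        resets_on = cfg.apply_reset if isinstance(cfg, SimConfig) else True
        if resets_on:
            steps = np.asarray(trajectory.spikes, dtype=int)
        else:
            steps = _upward_crossings(trajectory.x, threshold)
    else:
        steps = _upward_crossings(np.asarray(trajectory, dtype=float), threshold)
    isis = np.diff(steps).astype(float)
    if len(isis) and isis.mean() > 0:
        cv = float(isis.std() / isis.mean())
    else:
        cv = 0.0
    stats = SpikeStats(spike_steps=steps, isis=isis, isi_cv=cv)
    if len(steps):
        stats.bursts = _group_bursts(steps, isis)
    return stats


def _upward_crossings(x: np.ndarray, threshold: float) -> np.ndarray:
    above = x >= threshold
    cross = above[1:] & ~above[:-1]
    steps = np.flatnonzero(cross) + 1
    if len(x) and above[0]:
        steps = np.concatenate([[0], steps])
    return steps.astype(int)


def _group_bursts(steps: np.ndarray, isis: np.ndarray, burst_ratio: float = 5.0) -> list:
    """Group spike indices into bursts: intra-burst ISI <= mean(ISI)/ratio.

    The mean (not the median) sets the scale: in a strongly bursting train
    most intervals are the short intra-burst ones, so the median itself is
    short and would never separate bursts, while the mean feels the long
    inter-burst gaps.
    """
    if len(steps) < 2:
        return [list(range(len(steps)))]
    thr = float(np.mean(isis)) / burst_ratio
    groups = [[0]]
    for i, gap in enumerate(isis):
        if gap <= thr:
            groups[-1].append(i + 1)
        else:
            groups.append([i + 1])
    return groups


def classify_pattern(
    stats: SpikeStats,
    burst_ratio: float = 5.0,
    min_burst: int = 3,
    tonic_cv: float = 0.15,
) -> str:
    """Operational firing-pattern label from spike statistics.

    quiescent (no spikes) / sparse (< 3) / tonic_spiking (ISI CV below
    ``tonic_cv``) / bursting (>= 2 bursts of >= ``min_burst`` spikes, bursts
    separated by gaps > mean ISI / ``burst_ratio``) / chattering
    (bursting with mean burst length >= 2 * ``min_burst``) / irregular.
    The label and the burst grouping are stored back on ``stats``.
    """
    n = len(stats.spike_steps)
    if n == 0:
        label = "quiescent"
        stats.bursts = []
    elif n < 3:
        label = "sparse"
    elif stats.isi_cv < tonic_cv:
        label = "tonic_spiking"
    else:
        groups = _group_bursts(stats.spike_steps, stats.isis, burst_ratio)
        stats.bursts = groups
        big = [g for g in groups if len(g) >= min_burst]
        if len(big) >= 2:
            mean_len = float(np.mean([len(g) for g in big]))
            label = "chattering" if mean_len >= 2 * min_burst else "bursting"
        else:
            label = "irregular"
    stats.pattern = label
    return label


def divergence_step(trajectory, cap: float = 1e8) -> Optional[int]:
    """First step whose potential magnitude reaches ``cap``; None if bounded.

    A ``Trajectory`` already carries its divergence step from the
    integrator; bare arrays are scanned against ``cap``.
    """
    if isinstance(trajectory, Trajectory):
        return trajectory.n0
    x = np.asarray(trajectory, dtype=float)
    hits = np.flatnonzero(~np.isfinite(x) | (np.abs(x) >= cap))
    return int(hits[0]) if len(hits) else None
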