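"""Excitatory/inhibitory ensembles of fractional-order Izhikevich neurons.

The construction follows the classical randomized cortical ensemble: a
4:1 excitatory/inhibitory split, heterogeneous per-neuron parameters drawn
from the standard distributions (excitatory neurons interpolate between
regular spiking and chattering, inhibitory between fast spiking and
low-threshold spiking), all-to-all synaptic weights uniform in (0, 0.5)
from excitatory sources and (-1, 0) from inhibitory sources, and
independent per-step thalamic noise (gaussian, scale 5 for excitatory and
2 for inhibitory targets).  Every constant is overridable through
:class:`NetworkConfig`.

Each neuron integrates the direct-variant fractional scheme (shared or
per-neuron order), with input current

    I_i(n) = thalamic_i(n) + sum_j w_ij * [j spiked at step n-1],

the synchronous-update coupling of the classical ensemble.  At order 1 the
scheme reduces step for step to the memoryless classical update
``v <- v + (0.04 v^2 + 5 v + 140 - u + I)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .frac_calc import OrderSpec

__all__ = [
    "NetworkConfig",
    "Network",
    "Raster",
    "PopulationStats",
    "build_network",
    "simulate_network",
    "simulate_network_classical",
    "raster_stats",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Ensemble construction and run settings."""

    n_total: int = 1000
    exc_fraction: float = 0.8
    exc_weight_range: tuple = (0.0, 0.5)
    inh_weight_range: tuple = (-1.0, 0.0)
    exc_noise_scale: float = 5.0
    inh_noise_scale: float = 2.0
    steps: int = 1000
    seed: int = 0
    x_peak: float = 30.0
    divergence_cap: float = 1e8

    def __post_init__(self):
        if self.n_total < 2:
            raise ValueError("NetworkConfig: n_total must be >= 2")
        if not 0.0 < self.exc_fraction < 1.0:
            raise ValueError("NetworkConfig: exc_fraction must be in (0, 1)")


@dataclass
class Network:
    """Built ensemble: per-neuron parameters and the weight matrix.

    ``weights[i, j]`` is the synaptic weight from source j onto target i.
    The first ``n_exc`` neurons are excitatory.
    """

    config: NetworkConfig
    n_exc: int
    n_inh: int
    sigma: np.ndarray
    eta: np.ndarray
    psi: np.ndarray
    nu: np.ndarray
    weights: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return self.n_exc + self.n_inh


@dataclass
class Raster:
    """Sorted (step, neuron_id) spike events of one ensemble run."""

    events: np.ndarray          # shape (n_events, 2), sorted by (step, id)
    n_steps: int
    n_neurons: int
    meta: dict = field(default_factory=dict)

    def per_neuron_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_neurons, dtype=int)
        if len(self.events):
            ids, c = np.unique(self.events[:, 1], return_counts=True)
            counts[ids] = c
        return counts

    def spike_matrix(self) -> np.ndarray:
        """Dense binary (n_steps, n_neurons) spike indicator."""
        m = np.zeros((self.n_steps, self.n_neurons), dtype=bool)
        if len(self.events):
            m[self.events[:, 0], self.events[:, 1]] = True
        return m


def build_network(config: NetworkConfig = NetworkConfig(), seed: Optional[int] = None) -> Network:
    """Construct the randomized E/I ensemble (deterministic per seed)."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE1]))
    n = config.n_total
    ne = int(round(config.exc_fraction * n))
    ni = n - ne
    re = rng.uniform(size=ne)
    ri = rng.uniform(size=ni)
    sigma = np.concatenate([np.full(ne, 0.02), 0.02 + 0.08 * ri])
    eta = np.concatenate([np.full(ne, 0.2), 0.25 - 0.05 * ri])
    psi = np.concatenate([-65.0 + 15.0 * re ** 2, np.full(ni, -65.0)])
    nu = np.concatenate([8.0 - 6.0 * re ** 2, np.full(ni, 2.0)])
    lo_e, hi_e = config.exc_weight_range
    lo_i, hi_i = config.inh_weight_range
    W = np.empty((n, n))
    W[:, :ne] = rng.uniform(lo_e, hi_e, size=(n, ne))
    W[:, ne:] = rng.uniform(lo_i, hi_i, size=(n, ni))
    return Network(config=config, n_exc=ne, n_inh=ni, sigma=sigma, eta=eta,
                   psi=psi, nu=nu, weights=W, seed=seed)


def _thalamic(net: Network, steps: int, seed: int) -> np.ndarray:
    """Per-step gaussian drive, (steps, n); deterministic per seed."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A]))
    scale = np.concatenate([
        np.full(net.n_exc, net.config.exc_noise_scale),
        np.full(net.n_inh, net.config.inh_noise_scale),
    ])
    return rng.standard_normal((steps, net.n)) * scale


def simulate_network(
    net: Network,
    order_spec: OrderSpec = OrderSpec.commensurate(1.0),
    steps: Optional[int] = None,
    seed: Optional[int] = None,
    base_current: float = 0.0,
    noise: Optional[np.ndarray] = None,
) -> Raster:
    """Integrate the coupled ensemble under the fractional memory scheme.

    Shared-order specification (the default reading of the ensemble runs);
    the order attached to history index j applies to every neuron's kernel.
    Divergent neurons are clamped at the divergence cap and listed under
    ``meta['divergent']``; the run itself continues.
    """
    steps = net.config.steps if steps is None else steps
    seed = net.seed if seed is None else seed
    n = net.n
    cap = net.config.divergence_cap
    if noise is None:
        noise = _thalamic(net, steps, seed)
    x = np.concatenate([np.full(net.n_exc, -65.0), np.full(net.n_inh, -65.0)])
    y = net.eta * x
    Fx = np.empty((steps, n))
    Fy = np.empty((steps, n))
    # running kernel weights shared across neurons, one stream per variable
    wx = np.empty(steps); bx_hist = np.empty(steps)
    wy = np.empty(steps); by_hist = np.empty(steps)
    events_step: list[int] = []
    events_id: list[int] = []
    spiked_prev = np.zeros(n, dtype=bool)
    divergent = np.zeros(n, dtype=bool)

    for nstep in range(1, steps + 1):
        j = nstep - 1
        bx, by = order_spec.betas_at(j)
        if j > 0:
            k = np.arange(j - 1, -1, -1, dtype=float)
            dwx = wx[:j] * ((bx_hist[:j] - 1.0) / (k + 1.0))
            dwy = wy[:j] * ((by_hist[:j] - 1.0) / (k + 1.0))
            wx[:j] += dwx
            wy[:j] += dwy
        bx_hist[j] = bx; by_hist[j] = by
        wx[j] = 1.0; wy[j] = 1.0
        I_in = base_current + noise[j] + net.weights[:, spiked_prev].sum(axis=1)
        Fx[j] = 0.04 * x * x - y + 5.0 * x + 140.0 + I_in
        Fy[j] = net.sigma * (net.eta * x - y)
        if j > 0:
            x = x + Fx[j] + dwx @ Fx[:j]
            y = y + Fy[j] + dwy @ Fy[:j]
        else:
            x = x + Fx[j]
            y = y + Fy[j]
        bad = ~np.isfinite(x) | (np.abs(x) >= cap) | ~np.isfinite(y) | (np.abs(y) >= cap)
        if bad.any():
            divergent |= bad
            x = np.clip(np.nan_to_num(x, nan=cap, posinf=cap, neginf=-cap), -cap, cap)
            y = np.clip(np.nan_to_num(y, nan=cap, posinf=cap, neginf=-cap), -cap, cap)
        spiked = x >= net.config.x_peak
        if spiked.any():
            x[spiked] = net.psi[spiked]
            y[spiked] += net.nu[spiked]
            ids = np.flatnonzero(spiked)
            events_step.extend([nstep] * len(ids))
            events_id.extend(ids.tolist())
        spiked_prev = spiked

    events = np.column_stack([events_step, events_id]).astype(int) if events_step \
        else np.empty((0, 2), dtype=int)
    return Raster(
        events=events, n_steps=steps + 1, n_neurons=n,
        meta={"order_spec": order_spec, "seed": seed,
              "divergent": np.flatnonzero(divergent).tolist(),
              "base_current": base_current},
    )


def simulate_network_classical(
    net: Network,
    steps: Optional[int] = None,
    seed: Optional[int] = None,
    base_current: float = 0.0,
    noise: Optional[np.ndarray] = None,
) -> Raster:
    """Memoryless (order-1) reference: plain synchronous Euler-style update.

    Independent of the memory-kernel machinery; used to cross-check the
    fractional integrator at order 1.
    """
    steps = net.config.steps if steps is None else steps
    seed = net.seed if seed is None else seed
    n = net.n
    cap = net.config.divergence_cap
    if noise is None:
        noise = _thalamic(net, steps, seed)
    x = np.full(n, -65.0)
    y = net.eta * x
    events_step: list[int] = []
    events_id: list[int] = []
    spiked_prev = np.zeros(n, dtype=bool)
    for nstep in range(1, steps + 1):
        j = nstep - 1
        I_in = base_current + noise[j] + net.weights[:, spiked_prev].sum(axis=1)
        fx = 0.04 * x * x - y + 5.0 * x + 140.0 + I_in
        fy = net.sigma * (net.eta * x - y)
        x = x + fx
        y = y + fy
        x = np.clip(np.nan_to_num(x, nan=cap, posinf=cap, neginf=-cap), -cap, cap)
        y = np.clip(np.nan_to_num(y, nan=cap, posinf=cap, neginf=-cap), -cap, cap)
        spiked = x >= net.config.x_peak
        if spiked.any():
            x[spiked] = net.psi[spiked]
            y[spiked] += net.nu[spiked]
            ids = np.flatnonzero(spiked)
            events_step.extend([nstep] * len(ids))
            events_id.extend(ids.tolist())
        spiked_prev = spiked
    events = np.column_stack([events_step, events_id]).astype(int) if events_step \
        else np.empty((0, 2), dtype=int)
    return Raster(events=events, n_steps=steps + 1, n_neurons=n,
                  meta={"seed": seed, "classical": True})


@dataclass
class PopulationStats:
    """Firing rates and a variance-based synchrony index in [0, 1]."""

    rates: np.ndarray               # spikes per step, per neuron
    population_rate: np.ndarray     # fraction of neurons spiking, per bin
    synchrony_index: float


def raster_stats(raster: Raster, bin: int = 1) -> PopulationStats:
    """Population statistics of a spike raster.

    The synchrony index is the variance of the population-averaged spike
    indicator divided by the mean single-neuron indicator variance (the
    standard population-coherence measure), clipped to [0, 1]: 1 when all
    neurons spike at exactly the same steps, ~1/N for independent spiking.
    """
    if len(raster.events) == 0:
        return PopulationStats(
            rates=np.zeros(raster.n_neurons),
            population_rate=np.zeros(max(1, raster.n_steps // bin)),
            synchrony_index=0.0,
        )
    m = raster.spike_matrix().astype(float)
    if bin > 1:
        nb = m.shape[0] // bin
        m = m[: nb * bin].reshape(nb, bin, -1).sum(axis=1)
    rates = raster.per_neuron_counts() / max(1, raster.n_steps - 1)
    pop = m.mean(axis=1)
    var_pop = pop.var()
    var_ind = m.var(axis=0).mean()
    idx = float(np.clip(var_pop / var_ind, 0.0, 1.0)) if var_ind > 0 else 0.0
    return PopulationStats(rates=rates, population_rate=pop, synchrony_index=idx)
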