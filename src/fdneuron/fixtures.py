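"""Deterministic synthetic fixtures for tests and demonstrations.

Every fixture is a pure function of ``(name, seed)`` (plus explicit
keyword parameters): spike trains with prescribed interspike-interval
patterns, a Bernoulli raster, engineered linear systems for the Lyapunov
machinery, and a small E/I network.
"""

from __future__ import annotations

import numpy as np

from .network import Network, NetworkConfig, Raster, build_network
from .simulate import System

__all__ = ["make_fixture", "FIXTURES"]


def _tonic_train(seed: int, isi: int = 7, n_spikes: int = 40) -> np.ndarray:
    """Spike steps with constant interspike interval (CV = 0)."""
    return 10 + isi * np.arange(n_spikes)


def _burst_train(seed: int, n_bursts: int = 6) -> np.ndarray:
    """Spike steps with ISI pattern (2, 2, 2, 40) repeated: clean bursts."""
    isis = np.tile([2, 2, 2, 40], n_bursts)[:-1]
    return 5 + np.concatenate([[0], np.cumsum(isis)])


def _bernoulli_raster(seed: int, n_neurons: int = 50, n_steps: int = 500,
                      p: float = 0.02) -> Raster:
    """Independent Bernoulli spiking — an asynchronous reference raster."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB0]))
    m = rng.uniform(size=(n_steps, n_neurons)) < p
    steps, ids = np.nonzero(m)
    events = np.column_stack([steps, ids]).astype(int)
    return Raster(events=events, n_steps=n_steps, n_neurons=n_neurons,
                  meta={"fixture": "bernoulli_raster", "p": p, "seed": seed})


def _linear_map(seed: int, lam: float = 0.5) -> System:
    """Engineered linear system whose one-step map is ``z -> lam * z``.

    Expressed in difference form (rhs = (lam - 1) z, Jacobian (lam - 1) I)
    so that at order 1 the memory scheme iterates the map exactly and the
    maximal Lyapunov exponent is log(lam).
    """
    lam = float(lam)
    return System(
        rhs=lambda z: (lam - 1.0) * z,
        dim=2,
        jac=lambda z: (lam - 1.0) * np.eye(2),
        reset=None,
    )


def _tiny_network(seed: int, n: int = 10) -> Network:
    """Small E/I ensemble with the standard 4:1 split."""
    return build_network(NetworkConfig(n_total=n, steps=200, seed=seed))


FIXTURES = {
    "tonic_train": _tonic_train,
    "burst_train": _burst_train,
    "bernoulli_raster": _bernoulli_raster,
    "linear_map": _linear_map,
    "tiny_network": _tiny_network,
}


def make_fixture(name: str, seed: int = 0, **kwargs):
    """Build a named deterministic fixture."""
    try:
        fn = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return fn(seed, **kwargs)
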