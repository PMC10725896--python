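"""Discrete fractional-calculus primitives.

Everything downstream (the fractional neuron integrators, the tangent-map
Lyapunov estimator, the controllers) is built on four small operations:

* the *falling factorial* ``t^(beta) = Gamma(t+1)/Gamma(t+1-beta)``, the
  discrete analogue of the power function;
* the memory-kernel weight ``w_k(beta) = Gamma(k+beta)/(Gamma(beta)Gamma(k+1))``,
  i.e. the falling factorial kernel of the fractional sum already divided by
  ``Gamma(beta)``;
* the fractional sum of order ``beta`` (a discrete convolution against those
  weights); and
* the Caputo-like delta difference of order ``beta`` in (0, 1], which is the
  fractional sum of order ``1-beta`` applied to the first difference.

All Gamma ratios are evaluated in log space (``scipy.special.gammaln`` with
explicit sign tracking) or by the stable multiplicative recurrence
``w_{k+1} = w_k (k+beta)/(k+1)``; direct Gamma quotients overflow beyond
arguments of ~170 and are never used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence, Union

import numpy as np
from scipy.special import gammaln, gammasgn

__all__ = [
    "OrderSpec",
    "KernelRow",
    "falling_factorial",
    "kernel_weight",
    "kernel_row",
    "fractional_sum",
    "caputo_delta",
]


def _is_nonpositive_int(v: float) -> bool:
    return v <= 0 and float(v).is_integer()


def falling_factorial(t: float, beta: float) -> float:
    """Falling factorial ``t^(beta) = Gamma(t+1) / Gamma(t+1-beta)``.

    Computed as ``exp(lgamma(t+1) - lgamma(t+1-beta))`` with the sign of
    each Gamma factor tracked separately, so large arguments do not
    overflow and negative non-integer arguments keep the correct sign.

    Raises
    ------
    ValueError
        If ``t+1`` or ``t+1-beta`` sits on a pole of the Gamma function
        (a non-positive integer); the message names the offending argument.
    """
    a, b = t + 1.0, t + 1.0 - beta
    for name, v in (("t+1", a), ("t+1-beta", b)):
        if _is_nonpositive_int(v):
            raise ValueError(
                f"falling_factorial: Gamma pole at {name} = {v!r} "
                f"(non-positive integer)"
            )
    sign = gammasgn(a) * gammasgn(b)
    return float(sign * math.exp(gammaln(a) - gammaln(b)))


def kernel_weight(k: int, beta: float) -> float:
    """Memory-kernel weight ``w_k(beta) = Gamma(k+beta)/(Gamma(beta) Gamma(k+1))``.

    This is the discrete kernel ``(xi-u-1)^(beta-1)/Gamma(beta)`` of the
    fractional sum expressed as a function of the lag ``k = xi-u-1``.
    ``w_0 = 1`` exactly and for ``beta = 1`` every weight is 1 (no memory).
    """
    if k < 0:
        raise ValueError(f"kernel_weight: lag k must be >= 0, got {k}")
    if not 0.0 < beta <= 1.0:
        raise ValueError(f"kernel_weight: beta must be in (0, 1], got {beta}")
    return float(math.exp(gammaln(k + beta) - gammaln(beta) - gammaln(k + 1)))


@dataclass(frozen=True)
class KernelRow:
    """A row of memory-kernel weights ``w_0 .. w_{length-1}`` for one order."""

    beta: float
    weights: np.ndarray = field(repr=False)

    @property
    def length(self) -> int:
        return len(self.weights)

    def __post_init__(self):
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))


def kernel_row(n: int, beta: float) -> KernelRow:
    """Weights of lags ``0..n-1`` by the recurrence ``w_{k+1} = w_k (k+beta)/(k+1)``.

    The multiplicative recurrence is exact in the ratio sense and never
    forms a large Gamma value, so rows up to ``n ~ 1e6`` are safe.
    """
    if n < 1:
        raise ValueError(f"kernel_row: n must be >= 1, got {n}")
    if not 0.0 < beta <= 1.0:
        raise ValueError(f"kernel_row: beta must be in (0, 1], got {beta}")
    k = np.arange(n - 1, dtype=float)
    factors = (k + beta) / (k + 1.0)
    w = np.concatenate([[1.0], np.cumprod(factors)])
    return KernelRow(beta=beta, weights=w)


def fractional_sum(f: Sequence[float], beta: float) -> np.ndarray:
    """Fractional sum of order ``beta > 0`` of a finite sequence.

    Returns the array whose entry ``i`` is ``sum_{k=0}^{i} w_k(beta) f[i-k]``,
    the value of the fractional sum on its natural domain point ``a+beta+i``
    with starting point ``a = 0``.  For ``beta = 1`` this is the cumulative
    sum of ``f``; for the unit sequence it equals ``xi^(beta)/Gamma(beta+1)``.

    The accumulation is a ``numpy`` dot product per entry (pairwise
    summation), ascending lag, which keeps the decaying-weight sums
    accurate.
    """
    if beta <= 0:
        raise ValueError(f"fractional_sum: beta must be > 0, got {beta}")
    f = np.asarray(f, dtype=float)
    n = len(f)
    if n == 0:
        return np.empty(0)
    # weights for beta > 1 are still given by the same Gamma-ratio recurrence
    k = np.arange(n - 1, dtype=float)
    w = np.concatenate([[1.0], np.cumprod((k + beta) / (k + 1.0))])
    out = np.empty(n)
    for i in range(n):
        out[i] = np.dot(w[: i + 1], f[i::-1])
    return out


def caputo_delta(f: Sequence[float], beta: float) -> np.ndarray:
    """Caputo-like delta difference of order ``beta`` in (0, 1].

    The fractional sum of order ``1-beta`` applied to the first difference
    of ``f``; for ``beta = 1`` it is the plain first difference.  The result
    has length ``len(f) - 1``.
    """
    if not 0.0 < beta <= 1.0:
        raise ValueError(f"caputo_delta: beta must be in (0, 1], got {beta}")
    f = np.asarray(f, dtype=float)
    if len(f) < 2:
        raise ValueError("caputo_delta: sequence length must be >= 2")
    df = np.diff(f)
    if beta == 1.0:
        return df
    return fractional_sum(df, 1.0 - beta)


ClipPolicy = Literal["clip", "reject"]
OrderLike = Union[float, tuple, Callable[[int], float]]


@dataclass(frozen=True)
class OrderSpec:
    """Fractional-order specification for an integrator run.

    ``mode`` selects between a single shared order (*commensurate*), one
    order per state variable (*incommensurate*) and a step-dependent order
    function (*variable*).  Every effective order must land in (0, 1]; with
    ``clip_policy='clip'`` out-of-range values are clipped into the interval
    (the published variable-order presets occasionally exceed 1), with
    ``'reject'`` they raise.
    """

    mode: Literal["commensurate", "incommensurate", "variable"]
    beta: OrderLike
    clip_policy: ClipPolicy = "clip"

    _EPS = 1e-12

    @classmethod
    def commensurate(cls, beta: float, clip_policy: ClipPolicy = "clip") -> "OrderSpec":
        return cls("commensurate", float(beta), clip_policy)

    @classmethod
    def incommensurate(
        cls, beta1: float, beta2: float, clip_policy: ClipPolicy = "clip"
    ) -> "OrderSpec":
        return cls("incommensurate", (float(beta1), float(beta2)), clip_policy)

    @classmethod
    def variable(cls, beta_fn, beta2_fn=None, clip_policy: ClipPolicy = "clip") -> "OrderSpec":
        """Variable order; ``beta2_fn`` defaults to the same function for y."""
        return cls("variable", (beta_fn, beta_fn if beta2_fn is None else beta2_fn), clip_policy)

    def _coerce(self, value: float) -> float:
        if 0.0 < value <= 1.0:
            return float(value)
        if self.clip_policy == "reject":
            raise ValueError(
                f"OrderSpec: effective order {value!r} outside (0, 1] "
                f"with clip_policy='reject'"
            )
        return float(min(1.0, max(self._EPS, value)))

    def betas_at(self, step: int) -> tuple[float, float]:
        """Effective (beta_x, beta_y) attached to history index ``step``."""
        if self.mode == "commensurate":
            b = self._coerce(self.beta)
            return b, b
        if self.mode == "incommensurate":
            b1, b2 = self.beta
            return self._coerce(b1), self._coerce(b2)
        f1, f2 = self.beta
        return self._coerce(float(f1(step))), self._coerce(float(f2(step)))

    def is_constant(self) -> bool:
        return self.mode in ("commensurate", "incommensurate")
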