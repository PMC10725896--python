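"""The discrete Izhikevich neuron map and its local analysis.

The model is the two-variable spiking neuron

    x' = 0.04 x^2 + 5 x + 140 - y + I        (membrane potential, mV)
    y' = sigma (eta x - y)                   (recovery variable)

with the hard reset ``x >= x_peak  =>  x <- psi, y <- y + nu`` at the spike
cutoff ``x_peak = 30`` mV.  Two right-hand-side *variants* appear in the
fractional-difference formulation:

* ``direct``      — the map right-hand side as written above;
* ``difference``  — the first difference of the map, i.e. the same
  expressions minus ``x`` and ``y`` respectively.  This is the form that the
  commensurate Caputo-like scheme integrates.

This module provides the vector field, the reset rule, parameter presets,
fixed points of the nullcline system, the Jacobian, the fractional
stability test for discrete linear systems of order ``beta`` in (0, 1]
(eigenvalue-argument/modulus region), the saddle-node current and the
trace-zero (Hopf-type) analysis.

A note on presets.  The bursting parameter set is printed in the source
literature as ``(sigma, eta) = (0.2, 2)``, yet every worked fixed-point and
eigenvalue number there follows from ``(0.02, 0.2)`` — the classical
regular-spiking values.  ``B1`` therefore resolves to the *effective* set
``(0.02, 0.2, -55, 4)``; the printed set is kept as ``B1_printed``.  The
trace-zero analysis conversely is algebraically consistent with
``(0.2, 2)`` and uses those values by default.
"""

from __future__ import annotations

import cmath
import logging
from dataclasses import dataclass, field
from typing import Dict, Literal, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "NeuronParams",
    "PRESETS",
    "resolve_preset",
    "FormVariant",
    "FixedPoint",
    "SpectralResult",
    "HopfAnalysis",
    "rhs",
    "rhs_jacobian",
    "apply_reset",
    "fixed_points",
    "jacobian",
    "eigen_stability",
    "in_stability_region",
    "saddle_node_current",
    "hopf_analysis",
]

FormVariant = Literal["direct", "difference"]

X_PEAK_DEFAULT = 30.0


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich parameters.

    sigma : recovery time-scale (dimensionless)
    eta   : recovery sensitivity (dimensionless)
    psi   : post-spike reset voltage (mV)
    nu    : post-spike recovery increment (dimensionless)
    I     : injected current
    x_peak: spike cutoff voltage (mV), 30 by default
    """

    sigma: float
    eta: float
    psi: float
    nu: float
    I: float = 0.0
    x_peak: float = X_PEAK_DEFAULT

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"NeuronParams: sigma must be > 0, got {self.sigma}")
        if not np.isfinite(self.x_peak):
            raise ValueError("NeuronParams: x_peak must be finite")
        if self.psi >= self.x_peak:
            raise ValueError(
                f"NeuronParams: reset voltage psi={self.psi} must lie below "
                f"the spike cutoff x_peak={self.x_peak}"
            )

    def with_current(self, I: float) -> "NeuronParams":
        return NeuronParams(self.sigma, self.eta, self.psi, self.nu, I, self.x_peak)


#: Named parameter sets (sigma, eta, psi, nu).  ``B1`` is the effective
#: bursting set (see module docstring); ``B1_printed`` the published one.
PRESETS: Dict[str, Tuple[float, float, float, float]] = {
    "B1": (0.02, 0.2, -55.0, 4.0),
    "B1_effective": (0.02, 0.2, -55.0, 4.0),
    "B1_printed": (0.2, 2.0, -55.0, 4.0),
    "B2": (0.02, 0.2, -56.0, -16.0),
    "B2_printed": (0.02, 0.2, -56.0, -16.0),
    "network_mod": (0.1, 0.2, -65.0, 8.0),
}


def resolve_preset(name: str, I: float = 0.0) -> NeuronParams:
    """Look up a named preset; unknown names list the registry."""
    try:
        sigma, eta, psi, nu = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    if name in ("B1", "B1_effective"):
        logger.info(
            "preset %s resolves to effective parameters (sigma, eta, psi, nu) = "
            "(0.02, 0.2, -55, 4); the published set (0.2, 2, -55, 4) is "
            "available as 'B1_printed'",
            name,
        )
    return NeuronParams(sigma, eta, psi, nu, I)


def rhs(state, params: NeuronParams, variant: FormVariant = "direct"):
    """Vector field of the chosen variant at ``state = (x, y)``.

    direct:      (0.04 x^2 + 5x + 140 - y + I,  sigma(eta x - y))
    difference:  the same minus (x, y).
    Complex states are accepted (fixed-point residual checks use them).
    """
    x, y = state
    fx = 0.04 * x * x - y + 5.0 * x + 140.0 + params.I
    fy = params.sigma * (params.eta * x - y)
    if variant == "difference":
        fx -= x
        fy -= y
    elif variant != "direct":
        raise ValueError(f"unknown variant {variant!r}")
    return fx, fy


def rhs_jacobian(state, params: NeuronParams, variant: FormVariant = "direct") -> np.ndarray:
    """Jacobian of ``rhs`` with respect to (x, y) at ``state``."""
    x = state[0]
    J = np.array(
        [[0.08 * x + 5.0, -1.0], [params.sigma * params.eta, -params.sigma]],
        dtype=complex if np.iscomplexobj(np.asarray(state)) else float,
    )
    if variant == "difference":
        J[0, 0] -= 1.0
        J[1, 1] -= 1.0
    return J


def apply_reset(state, params: NeuronParams):
    """Hard spike-reset rule.  Returns ``((x, y), spiked)``.

    If the membrane potential has reached the cutoff, the potential is reset
    to ``psi`` and the recovery variable incremented by ``nu``.
    """
    x, y = state
    if x >= params.x_peak:
        return (params.psi, y + params.nu), True
    return (x, y), False


@dataclass(frozen=True)
class FixedPoint:
    """Equilibrium of the nullcline system; complex-capable.

    ``branch`` labels the quadratic root: 'minus' is the more negative
    (lower-voltage) root, 'plus' the other, 'double' a coalesced pair.
    """

    x_star: complex
    y_star: complex
    branch: Literal["plus", "minus", "double"]
    variant: FormVariant = "direct"

    def as_tuple(self) -> Tuple[complex, complex]:
        return self.x_star, self.y_star


def fixed_points(
    params: NeuronParams,
    variant: FormVariant = "direct",
    recovery_slope: float | None = None,
) -> list[FixedPoint]:
    """Equilibria from the nullclines, both quadratic roots (complex allowed).

    For the direct variant the nullclines are ``y = slope * x`` and
    ``0.04 x^2 + 5x + 140 + I - y = 0`` so that

        0.04 x^2 + (5 - slope) x + 140 + I = 0.

    ``recovery_slope`` defaults to ``eta``; it is a separate argument because
    published worked examples use slope 0.2 with the recovery nullcline
    regardless of the quoted ``eta``.  For the difference variant the
    modified nullclines ``y = sigma*slope/(sigma+1) * x`` and
    ``0.04 x^2 + 4x + 140 + I - y = 0`` are used.
    """
    slope = params.eta if recovery_slope is None else recovery_slope
    if variant == "direct":
        y_slope = slope
        b = 5.0 - y_slope
    elif variant == "difference":
        y_slope = params.sigma * slope / (params.sigma + 1.0)
        b = 4.0 - y_slope
    else:
        raise ValueError(f"unknown variant {variant!r}")
    a, c = 0.04, 140.0 + params.I
    disc = b * b - 4.0 * a * c
    if abs(disc) < 1e-12:
        x = -b / (2.0 * a)
        return [FixedPoint(x, y_slope * x, "double", variant)]
    sq = cmath.sqrt(complex(disc))
    roots = [(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)]
    out = []
    for x, br in zip(roots, ("minus", "plus")):
        if abs(x.imag) < 1e-12:
            x = x.real
        out.append(FixedPoint(x, y_slope * x, br, variant))
    return out


def jacobian(fp: FixedPoint, params: NeuronParams, variant: FormVariant = "direct") -> np.ndarray:
    """Jacobian of the chosen variant's vector field at a fixed point.

    Direct variant: ``[[0.08 x* + 5, -1], [sigma eta, -sigma]]``.
    """
    return rhs_jacobian((fp.x_star, fp.y_star), params, variant)


def _region_threshold(arg: float, beta: float) -> float:
    """Modulus bound of the order-beta stability region at argument ``arg``."""
    c = 2.0 * np.cos(abs(abs(arg) - np.pi) / (2.0 - beta))
    if c <= 0.0:
        return 0.0
    return float(c ** beta)


def in_stability_region(eig: complex, beta: float) -> bool:
    """Membership test for the asymptotic-stability region of a linear
    Caputo-like delta system of order ``beta``:

        |s| < (2 cos(|arg s - pi| / (2 - beta)))^beta   and   |arg s| > beta pi / 2.

    At ``beta = 1`` the region is the disk ``|s + 1| < 1``.
    """
    if not 0.0 < beta <= 1.0:
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    a = abs(cmath.phase(complex(eig)))
    if a <= beta * np.pi / 2.0:
        return False
    return abs(eig) < _region_threshold(a, beta)


@dataclass
class SpectralResult:
    """Jacobian spectrum and fractional stability verdict at one equilibrium."""

    jacobian: np.ndarray
    eigenvalues: np.ndarray          # sorted: descending real, then imag
    min_abs_arg: float               # min over eigenvalues of |arg|
    beta_crit: float                 # (2/pi) * min_abs_arg, clipped to [0, 2]
    beta: float | None = None
    stable: bool | None = None
    per_eigen_stable: list = field(default_factory=list)

    def stable_at(self, beta: float) -> bool:
        return all(in_stability_region(e, beta) for e in self.eigenvalues)


def eigen_stability(J: np.ndarray, beta: float | None = None) -> SpectralResult:
    """Eigenvalues of ``J`` and their order-``beta`` stability classification.

    ``beta_crit = (2/pi) min|arg s|`` is the argument-condition threshold:
    the equilibrium can only satisfy the argument condition for orders below
    it.  Eigenvalues are sorted by descending real part, ties broken by
    descending imaginary part.
    """
    J = np.asarray(J)
    if J.shape != (2, 2) or not np.all(np.isfinite(J.ravel().astype(complex).view(float))):
        raise ValueError("eigen_stability: J must be a finite 2x2 matrix")
    eig = np.linalg.eigvals(J.astype(complex))
    order = np.lexsort((-eig.imag, -eig.real))
    eig = eig[order]
    if np.all(np.abs(eig.imag) < 1e-12):
        eig = eig.real.astype(complex)
    min_arg = float(min(abs(cmath.phase(e)) for e in eig))
    res = SpectralResult(
        jacobian=J,
        eigenvalues=eig,
        min_abs_arg=min_arg,
        beta_crit=float(np.clip(2.0 / np.pi * min_arg, 0.0, 2.0)),
    )
    if beta is not None:
        res.beta = beta
        res.per_eigen_stable = [in_stability_region(e, beta) for e in eig]
        res.stable = all(res.per_eigen_stable)
    return res


def saddle_node_current(params: NeuronParams, recovery_slope: float | None = None) -> float:
    """Injected current at which the two equilibria coalesce.

    Zero-discriminant condition of the fixed-point quadratic:
    ``(5 - slope)^2 = 4 * 0.04 * (140 + I)``; slope 0.2 gives I = 4.
    """
    slope = params.eta if recovery_slope is None else recovery_slope
    return (5.0 - slope) ** 2 / 0.16 - 140.0


@dataclass
class HopfAnalysis:
    """Trace-zero (Hopf-type) analysis of the fixed-point spectrum.

    With the recovery nullcline ``y = eta x`` the characteristic polynomial
    at an equilibrium is

        g1(s, I) = s^2 + (sigma - 0.08 x* - 5) s + (sigma eta - 5 sigma - 0.08 sigma x*),

    and the eigenvalues are ``phi1 +/- i phi2`` with
    ``phi1 = -0.5 (sigma - 0.08 x* - 5)``.  The trace criterion
    ``h(I) = -(sigma - 0.08 x* - 5)`` vanishes where the conjugate pair sits
    on the imaginary axis; for ``sigma = 0.2`` it reads ``4.8 + 0.08 x*``,
    so the critical equilibrium is ``x* = -60`` and, on the lower branch of
    ``0.04 x^2 + (5 - eta) x + 140 + I = 0`` with ``eta = 2``, the critical
    current is I = -104 where the pair is ``+/- 0.6 i``.
    """

    x_star_crit: float
    I_critical: float
    g1_coeffs: tuple           # (1, linear, constant) at x_star_crit
    eigen_at_crit: tuple
    transversality: bool
    dphi1_dI: float
    x_star_at_I: complex
    phi1_at_I: float
    phi2_at_I: float
    h_at_I: float


def _hopf_x_star(params: NeuronParams, I: float, branch: str = "minus") -> complex:
    a, b, c = 0.04, 5.0 - params.eta, 140.0 + I
    sq = cmath.sqrt(complex(b * b - 4 * a * c))
    x = (-b - sq) / (2 * a) if branch == "minus" else (-b + sq) / (2 * a)
    return x.real if abs(x.imag) < 1e-12 else x


def hopf_analysis(params: NeuronParams, I: float | None = None, branch: str = "minus") -> HopfAnalysis:
    """Trace-zero analysis at the given current (default: the current of the run).

    Solves ``h = 0`` for the critical equilibrium voltage, maps it back to
    the critical current on the chosen root branch, and evaluates the
    characteristic polynomial, the eigenvalue parts ``phi1, phi2`` and the
    transversality condition ``d phi1 / dI != 0`` there.  A complex
    equilibrium (radicand negative) is a valid output, not an error.
    """
    sigma, eta = params.sigma, params.eta
    if I is None:
        I = params.I
    # h(x*) = -(sigma - 0.08 x* - 5) = 0
    x_crit = (sigma - 5.0) / 0.08
    # current at which the chosen branch passes through x_crit
    I_crit = -(0.04 * x_crit * x_crit + (5.0 - eta) * x_crit + 140.0)
    lin = sigma - 0.08 * x_crit - 5.0            # = 0 at x_crit by construction
    const = sigma * eta - 5.0 * sigma - 0.08 * sigma * x_crit
    disc = lin * lin - 4.0 * const
    sq = cmath.sqrt(complex(disc))
    eig_crit = ((-lin + sq) / 2.0, (-lin - sq) / 2.0)

    def phi1_of_I(cur: float) -> float:
        xs = _hopf_x_star(params, cur, branch)
        return float((-0.5 * (sigma - 0.08 * xs - 5.0)).real)

    hstep = 1e-6
    dphi1 = (phi1_of_I(I_crit + hstep) - phi1_of_I(I_crit - hstep)) / (2 * hstep)

    xs = _hopf_x_star(params, I, branch)
    lin_I = sigma - 0.08 * xs - 5.0
    const_I = sigma * eta - 5.0 * sigma - 0.08 * sigma * xs
    phi1 = complex(-0.5 * lin_I).real
    # imaginary part of the conjugate pair: 0.5 sqrt(4*const - lin^2) when positive
    disc_I = complex(lin_I * lin_I - 4.0 * const_I)
    phi2 = abs(cmath.sqrt(disc_I).imag) / 2.0 if (disc_I.real < 0 or disc_I.imag != 0) else 0.0
    return HopfAnalysis(
        x_star_crit=float(x_crit),
        I_critical=float(I_crit),
        g1_coeffs=(1.0, float(lin), float(const)),
        eigen_at_crit=eig_crit,
        transversality=bool(abs(dphi1) > 1e-12),
        dphi1_dI=float(dphi1),
        x_star_at_I=xs,
        phi1_at_I=phi1,
        phi2_at_I=phi2,
        h_at_I=float(complex(-(sigma - 0.08 * xs - 5.0)).real),
    )
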