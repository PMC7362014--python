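"""Particle scattering functions for touched-bead wormlike chains.

The normalized single-chain form factor ``P(k)`` (``P(0) = 1``) of a
semiflexible chain crosses over from Gaussian-coil behaviour at low
scattering wavenumber ``k`` to rigid-rod behaviour at high ``k``.  The
crossover parametrization used here blends the Debye coil function and
the rod function with a sharp switch ``exp(-xi^-5)`` in a crossover
variable ``xi`` that is linear in ``k``:

    P(k) = [(1 - e^{-xi^-5}) P_coil + e^{-xi^-5} P_rod] * Gamma * F0b^2(k d_b)

``F0b`` is the sphere form-factor amplitude of one bead (finite chain
thickness), and ``Gamma`` is a residual correction factor tabulated by
the original authors of the parametrization; coefficient sets are
pluggable through :class:`CrossoverCoefficients` (the default set is the
documented unity correction, exact at k -> 0 where acceptance-level
quantities live).

For the excluded-volume-perturbed chain the coil branch is evaluated at
the perturbed radius of gyration and the crossover variable changes to
``xi'``; the rod branch is unaffected by excluded volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy.special import sici

from .chain import ChainDimensions, WormlikeParams

__all__ = [
    "CrossoverCoefficients",
    "debye",
    "rod",
    "thickness_factor",
    "crossover_xi",
    "crossover_xi_prime",
    "blend_weight",
    "pk_unperturbed",
    "pk_perturbed",
    "ps_exv_coil",
]

# blend weight exp(-xi^-5) under/overflow guards
_XI_LO = 1e-2   # weight < exp(-1e10): identically 0
_XI_HI = 1e3    # weight > exp(-1e-15): identically 1


def _as_array(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("argument must be non-negative")
    return arr


def debye(u) -> np.ndarray | float:
    """Debye function ``2(e^-u + u - 1)/u^2`` of ``u = <S^2> k^2``."""
    arr = _as_array(u)
    out = np.empty_like(arr)
    small = arr < 1e-4
    a = arr[small]
    out[small] = 1.0 - a / 3.0 + a * a / 12.0
    a = arr[~small]
    out[~small] = 2.0 * (np.expm1(-a) + a) / (a * a)
    return out if out.ndim else float(out)

def rod(v) -> np.ndarray | float:
    """Rigid-rod form factor ``(2/v^2)[v Si(v) + cos v - 1]`` of ``v = L k``."""
    arr = _as_array(v)
    out = np.empty_like(arr)
    small = arr < 1e-3
    a = arr[small]
    out[small] = 1.0 - a * a / 36.0
    a = arr[~small]
    si, _ = sici(a)
    out[~small] = 2.0 * (a * si + np.cos(a) - 1.0) / (a * a)
    return out if out.ndim else float(out)

def thickness_factor(x) -> np.ndarray | float:
    """Sphere form-factor amplitude ``F0b(x) = (24/x^3)[sin(x/2) - (x/2)cos(x/2)]``
    of ``x = k d_b``; enters the chain form factor squared."""
    arr = _as_array(x)
    out = np.empty_like(arr)
    small = arr < 1e-3
    a = arr[small]
    out[small] = 1.0 - a * a / 40.0
    a = arr[~small]
    y = a / 2.0
    out[~small] = 24.0 * (np.sin(y) - y * np.cos(y)) / a ** 3
    return out if out.ndim else float(out)


def ps_exv_coil(x) -> np.ndarray | float:
    """Excluded-volume coil scattering function of Pedersen–Schurtenberger.

    ``x = <S^2>^{1/2} k``.  Crosses over smoothly (tanh switch at
    x ~ 1.5) from the Debye function to the swollen-coil power law
    ``C1 x^{-1/nu} + C2 x^{-2/nu} + C3 x^{-3/nu}`` with nu = 0.585.
    Optional alternative to the Debye coil branch for strongly perturbed
    chains.
    """
    nu = 0.585
    c1, c2, c3 = 1.2220, 0.4288, -1.651
    arr = _as_array(x)
    w = 0.5 * (1.0 + np.tanh((arr - 1.523) / 0.1477))
    power = np.zeros_like(arr)
    pos = arr > 0
    a = arr[pos]
    power[pos] = (
        c1 * a ** (-1.0 / nu) + c2 * a ** (-2.0 / nu) + c3 * a ** (-3.0 / nu)
    )
    out = (1.0 - w) * debye(arr * arr) + w * power
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CrossoverCoefficients:
    """Named, versioned coefficient set for the crossover corrections.

    ``gamma(k, N, xi)`` and ``gamma_prime(k, N, xi_prime)`` must both
    tend to 1 as k -> 0.  The shipped default is the unity correction
    (Gamma = Gamma' = 1); published tables can be supplied by
    constructing an instance with the appropriate callables.
    """

    name: str = "unity"
    citation: str = "identity correction; exact in the k -> 0 limit"
    gamma: Callable[[np.ndarray, float, np.ndarray], np.ndarray] = field(
        default=lambda k, N, xi: np.ones_like(np.asarray(k, dtype=float))
    )
    gamma_prime: Callable[[np.ndarray, float, np.ndarray], np.ndarray] = field(
        default=lambda k, N, xi: np.ones_like(np.asarray(k, dtype=float))
    )


UNITY_COEFFICIENTS = CrossoverCoefficients()


def crossover_xi(k, dims: ChainDimensions, params: WormlikeParams) -> np.ndarray | float:
    """Unperturbed crossover variable ``xi = (pi/2N)(<S^2>_0/(2q)^2)(2qk)``."""
    arr = _as_array(k)
    two_q = 2.0 * params.q
    out = (math.pi / (2.0 * dims.N)) * (dims.S2_0 / two_q ** 2) * (two_q * arr)
    return out if np.ndim(out) else float(out)


def crossover_xi_prime(
    k, dims: ChainDimensions, params: WormlikeParams, S2_perturbed: float
) -> np.ndarray | float:
    """Perturbed crossover variable
    ``xi' = (pi/1.103N)^{3/2} (<S^2>^{1/2}/2q)^{2.564} (2qk)``."""
    arr = _as_array(k)
    two_q = 2.0 * params.q
    pref = (math.pi / (1.103 * dims.N)) ** 1.5
    out = pref * (math.sqrt(S2_perturbed) / two_q) ** 2.564 * (two_q * arr)
    return out if np.ndim(out) else float(out)


def blend_weight(xi) -> np.ndarray | float:
    """Coil/rod switch ``exp(-xi^-5)``: 0 at low k (coil), 1 at high k (rod)."""
    arr = np.asarray(xi, dtype=float)
    out = np.zeros_like(arr)
    hi = arr > _XI_HI
    out[hi] = 1.0
    mid = (arr >= _XI_LO) & ~hi
    out[mid] = np.exp(-arr[mid] ** -5)
    return out if out.ndim else float(out)


def _pk(
    k,
    dims: ChainDimensions,
    params: WormlikeParams,
    S2_coil: float,
    xi,
    gamma_values,
    coil: Literal["debye", "ps_exv"],
) -> np.ndarray | float:
    arr = _as_array(k)
    if coil == "debye":
        p_coil = debye(S2_coil * arr * arr)
    else:
        p_coil = ps_exv_coil(math.sqrt(S2_coil) * arr)
    p_rod = rod(dims.L * arr)
    w = blend_weight(xi)
    f0b = thickness_factor(params.d_b * arr)
    out = ((1.0 - w) * p_coil + w * p_rod) * gamma_values * f0b * f0b
    return out if np.ndim(out) else float(out)


def pk_unperturbed(
    k,
    dims: ChainDimensions,
    params: WormlikeParams,
    coefficients: CrossoverCoefficients = UNITY_COEFFICIENTS,
) -> np.ndarray | float:
    """Unperturbed touched-bead wormlike-chain form factor; P(0) = 1."""
    arr = _as_array(k)
    xi = crossover_xi(arr, dims, params)
    gam = coefficients.gamma(arr, dims.N, np.asarray(xi, dtype=float))
    return _pk(k, dims, params, dims.S2_0, xi, gam, "debye")


def pk_perturbed(
    k,
    dims: ChainDimensions,
    params: WormlikeParams,
    S2_perturbed: float,
    coefficients: CrossoverCoefficients = UNITY_COEFFICIENTS,
    coil: Literal["debye", "ps_exv"] = "debye",
) -> np.ndarray | float:
    """Excluded-volume-perturbed form factor; coil branch at the perturbed
    radius, rod branch unchanged; P(0) = 1."""
    if S2_perturbed < dims.S2_0 * (1.0 - 1e-12):
        raise ValueError(
            "S2_perturbed must be >= unperturbed S2_0 (excluded volume only expands)"
        )
    arr = _as_array(k)
    xi = crossover_xi_prime(arr, dims, params, S2_perturbed)
    gam = coefficients.gamma_prime(arr, dims.N, np.asarray(xi, dtype=float))
    return _pk(k, dims, params, S2_perturbed, xi, gam, coil)
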