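"""Quasi-two-parameter (QTP) excluded-volume theory for semiflexible chains.

In the QTP scheme the intramolecular excluded-volume expansion of a
wormlike chain is controlled by a single scaled variable

    z~ = (3/4) K(N) * z,      z = (3/(2 pi))^{3/2} (B / 2q) N^{1/2},

where ``N = L/2q`` is the Kuhn statistical number, ``B`` the
excluded-volume strength (reduced here by the Kuhn length ``2q``), and
``K(N)`` a stiffness scale factor that switches the perturbation off for
short, rod-like chains (K -> 0 as N -> 0) and tends to 4/3 in the coil
limit.  The radius expansion factor ``alpha_S(z~)`` then multiplies the
unperturbed radius of gyration:

    <S^2>^{1/2} = alpha_S(z~) <S^2>_0^{1/2}.

The closed forms used are the standard ones of the QTP literature:
the Yamakawa–Shimada–Stockmayer piecewise K(N) and the Domb–Barrett
expansion factor.  All coefficients live in the constants block below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .chain import ChainDimensions, WormlikeParams, chain_dimensions, unperturbed_s2

__all__ = [
    "ExcludedVolumeState",
    "stiffness_factor_K",
    "scaled_z",
    "expansion_factor",
    "excluded_volume_state",
    "perturbed_s2",
    "thickness_corrected_s2",
]

# --- QTP constants -------------------------------------------------------
# K(N), algebraic branch (N > seam):   4/3 - 2.711 N^{-1/2} + (7/6) N^{-1}
# K(N), exponential branch (N <= seam): N^{-1/2} exp(-6.611/N + 0.9198 + 0.03516 N)
# Domb-Barrett: alpha_S^2 = [1 + 10 z~ + (70 pi/9 + 10/3) z~^2 + 8 pi^{3/2} z~^3]^{2/15}
#                           * [0.933 + 0.067 exp(-0.85 z~ - 1.39 z~^2)]
_K_SEAM = 6.0
_K_A1 = 2.711
_K_A2 = 7.0 / 6.0
_K_E1 = 6.611
_K_E2 = 0.9198
_K_E3 = 0.03516
_DB_C2 = 70.0 * math.pi / 9.0 + 10.0 / 3.0
_DB_C3 = 8.0 * math.pi ** 1.5
_Z_PREFACTOR = (3.0 / (2.0 * math.pi)) ** 1.5


@dataclass(frozen=True)
class ExcludedVolumeState:
    """Scaled excluded-volume parameter, stiffness factor and alpha_S."""

    z_tilde: float
    K_N: float
    alpha_S: float


def stiffness_factor_K(N: float) -> float:
    """Stiffness scale factor K(N); 4/3 in the coil limit, -> 0 as N -> 0."""
    if not N > 0 or not math.isfinite(N):
        raise ValueError(f"N must be positive and finite, got {N!r}")
    if N > _K_SEAM:
        return 4.0 / 3.0 - _K_A1 / math.sqrt(N) + _K_A2 / N
    return math.exp(-_K_E1 / N + _K_E2 + _K_E3 * N) / math.sqrt(N)


def scaled_z(params: WormlikeParams, N: float) -> float:
    """Scaled excluded-volume parameter z~; zero iff B = 0."""
    if not N > 0:
        raise ValueError(f"N must be positive, got {N!r}")
    z = _Z_PREFACTOR * (params.B / (2.0 * params.q)) * math.sqrt(N)
    return 0.75 * stiffness_factor_K(N) * z


def expansion_factor(z_tilde: float) -> float:
    """Domb–Barrett radius expansion factor alpha_S(z~) >= 1."""
    if z_tilde < 0 or not math.isfinite(z_tilde):
        raise ValueError(f"z_tilde must be >= 0 and finite, got {z_tilde!r}")
    zt = z_tilde
    poly = 1.0 + 10.0 * zt + _DB_C2 * zt * zt + _DB_C3 * zt ** 3
    damp = 0.933 + 0.067 * math.exp(-0.85 * zt - 1.39 * zt * zt)
    return math.sqrt(poly ** (2.0 / 15.0) * damp)


def excluded_volume_state(dims: ChainDimensions, params: WormlikeParams) -> ExcludedVolumeState:
    zt = scaled_z(params, dims.N)
    return ExcludedVolumeState(
        z_tilde=zt, K_N=stiffness_factor_K(dims.N), alpha_S=expansion_factor(zt)
    )


def perturbed_s2(dims: ChainDimensions, params: WormlikeParams) -> float:
    """Perturbed mean-square radius of gyration alpha_S^2 <S^2>_0 (nm^2)."""
    state = excluded_volume_state(dims, params)
    return state.alpha_S ** 2 * dims.S2_0


def thickness_corrected_s2(dims: ChainDimensions, params: WormlikeParams) -> float:
    """<S^2> of the touched-bead chain: alpha_S^2 <S^2>_0 + (3/20) d_b^2.

    The additive bead term is the radius of gyration of a single sphere of
    diameter ``d_b``; it dominates for oligomers (L of order d_b) and is
    negligible (<0.1%) for long chains.
    """
    return perturbed_s2(dims, params) + 0.15 * params.d_b ** 2


def perturbed_s2_from_mass(M_w: float, params: WormlikeParams) -> float:
    """Convenience: perturbed <S^2> directly from molecular weight."""
    return perturbed_s2(chain_dimensions(M_w, params), params)
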