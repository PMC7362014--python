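"""Wormlike-chain parameterization and unperturbed chain dimensions.

The Kratky–Porod (wormlike) chain is a continuous semiflexible filament
characterized by its contour length ``L`` and persistence length ``q``.
A real polymer is mapped onto it through the molar mass per unit contour
length ``M_L`` (so ``L = M_w / M_L``), and finite chain thickness is
represented by decorating the contour with touched beads of diameter
``d_b``.  Intramolecular excluded volume is parameterized by the
excluded-volume strength ``B`` of the (quasi-)two-parameter theory.

Units are fixed package-wide: lengths in nm, molar masses in g/mol,
concentrations in g/cm^3, second virial coefficients in cm^3 g^-2 mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "WormlikeParams",
    "SampleSpec",
    "ChainDimensions",
    "contour_length",
    "unperturbed_s2",
    "chain_dimensions",
    "characteristic_ratio",
    "characteristic_ratio_infinite",
]

# Below this L/q the closed form for <S^2>_0 cancels catastrophically
# (relative error ~ 24 eps / x^4); the Taylor series, summed to machine
# precision, is used instead.  At the seam the direct branch is still good
# to ~1e-11 relative, so the branches agree to better than 1e-10.
_SERIES_THRESHOLD = 0.2


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0 or not math.isfinite(value):
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class WormlikeParams:
    """Parameter vector of one touched-bead wormlike chain species.

    Attributes
    ----------
    M_L : float
        Molar mass per unit contour length, g mol^-1 nm^-1.
    q : float
        Persistence length, nm.
    B : float
        Excluded-volume strength, nm.  ``B = 0`` means the unperturbed
        (theta-state) chain.
    d_b : float
        Bead (chain) diameter of the touched-bead model, nm.
    """

    M_L: float
    q: float
    B: float = 0.0
    d_b: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(M_L=self.M_L, q=self.q, d_b=self.d_b)
        if self.B < 0 or not math.isfinite(self.B):
            raise ValueError(f"B must be >= 0 and finite, got {self.B!r}")


@dataclass(frozen=True)
class SampleSpec:
    """Measured sample metadata.

    The model itself is monodisperse; ``polydispersity`` (M_w/M_n) is
    carried as metadata only, matching common practice of fitting a
    single-M_w model to narrow-distribution standards.
    """

    M_w: float
    c: float = 0.0
    polydispersity: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(M_w=self.M_w)
        if self.c < 0:
            raise ValueError(f"concentration must be >= 0, got {self.c!r}")
        if self.polydispersity < 1:
            raise ValueError(
                f"polydispersity M_w/M_n must be >= 1, got {self.polydispersity!r}"
            )


@dataclass(frozen=True)
class ChainDimensions:
    """Derived geometry of one chain: contour length, Kuhn number, <S^2>_0."""

    L: float
    N: float = field(default=0.0)
    S2_0: float = field(default=0.0)


def contour_length(M_w: float, M_L: float) -> float:
    """Contour length ``L = M_w / M_L`` in nm."""
    _require_positive(M_w=M_w, M_L=M_L)
    return M_w / M_L


def unperturbed_s2(L: float, q: float) -> float:
    """Mean-square radius of gyration of the unperturbed wormlike chain (nm^2).

    Benoit–Doty formula::

        <S^2>_0 = qL/3 - q^2 + (2q^3/L) [1 - (q/L)(1 - e^{-L/q})]

    Interpolates between the rod limit ``L^2/12`` (L << q) and the coil
    limit ``qL/3`` (L >> q).  Evaluated by Taylor series in ``L/q`` for
    ``L/q < 1e-2`` where the closed form cancels catastrophically.
    """
    _require_positive(L=L, q=q)
    x = L / q
    if x < _SERIES_THRESHOLD:
        # <S^2>_0 = L^2 sum_{n>=0} 2 (-x)^n / (n+4)!
        #         = L^2 [1/12 - x/60 + x^2/360 - ...], summed to eps
        term = 1.0 / 12.0
        total = term
        n = 1
        while abs(term) > 1e-17 * total:
            term *= -x / (n + 4)
            total += term
            n += 1
        return L * L * total
    return q * L / 3.0 - q * q + (2.0 * q ** 3 / L) * (
        1.0 - (q / L) * (1.0 - math.exp(-x))
    )


def chain_dimensions(M_w: float, params: WormlikeParams) -> ChainDimensions:
    """Contour length, Kuhn statistical number and <S^2>_0 for one sample."""
    L = contour_length(M_w, params.M_L)
    N = L / (2.0 * params.q)
    return ChainDimensions(L=L, N=N, S2_0=unperturbed_s2(L, params.q))


def characteristic_ratio(M: float, S2_0: float, b_u: float, M_0: float) -> float:
    """Characteristic ratio ``C_n = 6 M_0 <S^2>_0 / (b_u^2 M)``.

    Ratio of the actual unperturbed mean-square dimensions to those of a
    freely jointed chain of ``n = M/M_0`` virtual bonds of length ``b_u``
    (for a sugar backbone, the O–O distance across a glucosidic linkage).
    """
    _require_positive(M=M, S2_0=S2_0, b_u=b_u, M_0=M_0)
    return 6.0 * M_0 * S2_0 / (b_u * b_u * M)


def characteristic_ratio_infinite(
    M_L: float, q: float, b_u: float, M_0: float
) -> float:
    """Infinite-molecular-weight characteristic ratio ``C_inf``.

    In the coil limit ``<S^2>_0/M -> q/(3 M_L)``, so
    ``C_inf = 2 M_0 q / (b_u^2 M_L)``.
    """
    _require_positive(M_L=M_L, q=q, b_u=b_u, M_0=M_0)
    return 2.0 * M_0 * q / (b_u * b_u * M_L)
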