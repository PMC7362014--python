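"""From single-chain form factor to measurable reduced scattering intensity.

At finite mass concentration ``c`` the excess Rayleigh ratio of a polymer
solution, reduced by the optical constant and concentration, is

    R_theta / (K_e c) = M_w P(k) / [1 + 2 A2_app M_w P(k) c]

with ``A2_app`` the apparent second virial coefficient.  Including the
third virial term ``A3 = g A2^2 M_w`` (reduced third virial coefficient
``g``) in the inverse-intensity expansion relates ``A2_app`` to the
true ``A2``:

    A2_app = A2 + (3g/2) A2^2 M_w c
    A2     = [sqrt(1 + 6 g A2_app M_w c) - 1] / (3 g M_w c)

``g`` is approximately 1/3 for flexible chains in good solvents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .chain import SampleSpec

__all__ = [
    "ScatteringProfile",
    "VirialState",
    "AVOGADRO",
    "ELECTRON_RADIUS_CM",
    "reduced_intensity",
    "true_A2",
    "apparent_A2",
    "kratky",
    "reduce_raw",
    "optical_constant",
]

AVOGADRO = 6.02214076e23
ELECTRON_RADIUS_CM = 2.82e-13  # classical electron radius, cm

DEFAULT_G = 1.0 / 3.0


@dataclass(frozen=True)
class ScatteringProfile:
    """One circularly averaged 1-D profile: k (nm^-1) vs reduced intensity
    R/(K_e c) (g^-1 mol), with optional standard errors."""

    k: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    meta: Optional[SampleSpec] = None

    def __post_init__(self) -> None:
        k = np.asarray(self.k, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "intensity", i)
        if k.ndim != 1 or i.shape != k.shape:
            raise ValueError("k and intensity must be 1-D arrays of equal length")
        if k.size and (np.any(k <= 0) or np.any(np.diff(k) <= 0)):
            raise ValueError("k must be positive and strictly increasing")
        if np.any(i <= 0):
            raise ValueError("intensity must be positive")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != k.shape:
                raise ValueError("sigma must match k in length")

    def __len__(self) -> int:
        return self.k.size


@dataclass(frozen=True)
class VirialState:
    """Apparent and true second virial coefficients (cm^3 g^-2 mol) and
    the reduced third virial coefficient g."""

    A2_app: float
    A2: float
    g: float = DEFAULT_G

    def __post_init__(self) -> None:
        if not 0 < self.g <= 1:
            raise ValueError(f"g must be in (0, 1], got {self.g!r}")


def reduced_intensity(
    k,
    sample: SampleSpec,
    A2_app: float,
    pk: Callable[[np.ndarray], np.ndarray],
) -> np.ndarray | float:
    """Reduced intensity M_w P(k) / [1 + 2 A2_app M_w P(k) c]."""
    p = np.asarray(pk(np.asarray(k, dtype=float)), dtype=float)
    denom = 1.0 + 2.0 * A2_app * sample.M_w * p * sample.c
    if np.any(denom <= 0):
        raise ValueError("non-positive interference denominator (A2_app * c too negative)")
    out = sample.M_w * p / denom
    return out if np.ndim(out) else float(out)


def true_A2(A2_app: float, M_w: float, c: float, g: float = DEFAULT_G) -> float:
    """True second virial coefficient from the apparent one.

    Solves ``A2_app = A2 + (3g/2) A2^2 M_w c`` for A2 (positive root),
    i.e. ``A2 = [sqrt(1 + 6 g A2_app M_w c) - 1] / (3 g M_w c)``;
    the c -> 0 limit returns A2_app.
    """
    if M_w <= 0:
        raise ValueError("M_w must be positive")
    if c < 0:
        raise ValueError("c must be >= 0")
    mwc = M_w * c
    if mwc == 0:
        return A2_app
    radicand = 1.0 + 6.0 * g * A2_app * mwc
    if radicand <= 0:
        raise ValueError("radicand 1 + 6 g A2_app M_w c must be positive")
    # sqrt(1+a)-1 written as a/(sqrt(1+a)+1) to keep the c -> 0 limit exact
    a = 6.0 * g * A2_app * mwc
    return (a / (math.sqrt(radicand) + 1.0)) / (3.0 * g * mwc)


def apparent_A2(A2: float, M_w: float, c: float, g: float = DEFAULT_G) -> float:
    """Inverse of :func:`true_A2`: ``A2_app = A2 + (3g/2) A2^2 M_w c``."""
    if M_w <= 0:
        raise ValueError("M_w must be positive")
    if c < 0:
        raise ValueError("c must be >= 0")
    return A2 + 1.5 * g * A2 * A2 * M_w * c


def kratky(profile: ScatteringProfile, shift: float = 0.0):
    """Kratky transform: (k, k^2 * intensity + shift).

    A Gaussian coil gives a horizontal plateau ``2 M_w / <S^2>_0``; a rod
    gives a linear rise of slope ``pi M_w / L``.  ``shift`` is a purely
    graphical additive offset used to separate stacked curves.
    """
    return profile.k, profile.k ** 2 * profile.intensity + shift


def reduce_raw(
    I_soln, Imon_soln: float, I_solv, Imon_solv: float, F: float
) -> np.ndarray | float:
    """Excess Rayleigh ratio ``F (I_soln/Imon_soln - I_solv/Imon_solv)``."""
    if Imon_soln <= 0 or Imon_solv <= 0:
        raise ValueError("monitor values must be positive")
    if F <= 0:
        raise ValueError("instrument constant F must be positive")
    out = F * (
        np.asarray(I_soln, dtype=float) / Imon_soln
        - np.asarray(I_solv, dtype=float) / Imon_solv
    )
    return out if np.ndim(out) else float(out)


def optical_constant(gamma: float) -> float:
    """X-ray optical constant ``K_e = N_A a_e^2 gamma^2`` (cgs), with ``a_e``
    the classical electron radius and ``gamma`` the contrast factor."""
    return AVOGADRO * ELECTRON_RADIUS_CM ** 2 * gamma * gamma
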