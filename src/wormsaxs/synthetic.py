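"""Synthetic scattering profiles and radius-of-gyration datasets with
known ground truth.

The generator evaluates the perturbed touched-bead wormlike-chain
forward model on a log-spaced k-grid and applies multiplicative Gaussian
noise, ``I_i = model(k_i) (1 + eps_i)`` with ``eps_i ~ N(0, sigma_rel)``.
Multiplicative noise is used because photon-counting error scales with
intensity over the dynamic range of a 1-D SAXS profile; the default
relative level is 2%.  Instrumental smearing, buffer-subtraction
artifacts and Poisson statistics are deliberately not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chain import SampleSpec, WormlikeParams, chain_dimensions
from .excluded_volume import thickness_corrected_s2
from .model import model_intensity
from .solution import ScatteringProfile

__all__ = ["SyntheticSpec", "generate_profile", "generate_s2_dataset"]

OLIGOMER_RESIDUES = (3, 6, 9, 12)  # glucose counts of the reference oligomers


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration of one synthetic profile: ground-truth parameters,
    sample metadata, k-grid, relative noise level and mandatory seed."""

    true_params: WormlikeParams
    sample: SampleSpec
    A2_app: float = 3.0e-4
    k_min: float = 0.05
    k_max: float = 3.0
    n_points: int = 100
    sigma_rel: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be >= 0")
        if not 0 < self.k_min < self.k_max:
            raise ValueError("need 0 < k_min < k_max")
        if self.n_points < 2:
            raise ValueError("need at least 2 k points")

    def k_grid(self) -> np.ndarray:
        return np.geomspace(self.k_min, self.k_max, self.n_points)


def generate_profile(spec: SyntheticSpec) -> ScatteringProfile:
    """Noisy reduced-intensity profile, bit-reproducible per seed.

    The reported ``sigma`` column is the true per-point standard
    deviation ``sigma_rel * model``.
    """
    k = spec.k_grid()
    model = np.asarray(
        model_intensity(k, spec.sample, spec.true_params, spec.A2_app), dtype=float
    )
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(0.0, spec.sigma_rel, size=k.size) if spec.sigma_rel > 0 else 0.0
    return ScatteringProfile(
        k=k,
        intensity=model * (1.0 + eps),
        sigma=spec.sigma_rel * model,
        meta=spec.sample,
    )


def generate_s2_dataset(
    params: WormlikeParams,
    M_list=None,
    M0: float = 162.0,
) -> pd.DataFrame:
    """Thickness-corrected radius-of-gyration table over a mass range.

    One row per molecular weight M: contour length L, <S^2> from the
    perturbed wormlike chain plus the (3/20) d_b^2 bead term, and its
    square root.  By default M spans the reference oligomers
    (n = 3, 6, 9, 12 glucoses, M = 162 n) up to 7.4e5 on a log grid,
    the range over which a single smooth curve connects oligomer and
    polymer dimensions.
    """
    if M_list is None:
        oligomers = [M0 * n for n in OLIGOMER_RESIDUES]
        polymers = np.geomspace(5e3, 7.4e5, 25)
        M_list = np.concatenate([oligomers, polymers])
    M = np.asarray(M_list, dtype=float)
    if np.any(M <= 0):
        raise ValueError("molecular weights must be positive")
    rows = []
    for m in M:
        dims = chain_dimensions(m, params)
        s2 = thickness_corrected_s2(dims, params)
        rows.append(dict(M=m, L=dims.L, S2=s2, rg=np.sqrt(s2)))
    return pd.DataFrame(rows)
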