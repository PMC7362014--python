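"""Forward model: reduced scattering intensity of one touched-bead
wormlike-chain sample, composing chain geometry, excluded volume, form
factor and concentration correction."""

from __future__ import annotations

import numpy as np

from .chain import SampleSpec, WormlikeParams, chain_dimensions
from .excluded_volume import perturbed_s2
from .formfactor import (
    CrossoverCoefficients,
    UNITY_COEFFICIENTS,
    pk_perturbed,
    pk_unperturbed,
)
from .solution import reduced_intensity

__all__ = ["model_intensity"]


def model_intensity(
    k,
    sample: SampleSpec,
    params: WormlikeParams,
    A2_app: float,
    perturbed: bool = True,
    coefficients: CrossoverCoefficients = UNITY_COEFFICIENTS,
) -> np.ndarray | float:
    """Reduced intensity R/(K_e c) at wavenumbers ``k`` for one sample.

    ``perturbed=False`` forces the unperturbed (B = 0) form factor while
    keeping the chain geometry — the comparison drawn when assessing the
    importance of excluded volume.
    """
    dims = chain_dimensions(sample.M_w, params)
    if perturbed:
        # B = 0 gives S2 = S2_0 and the family stays continuous in B
        s2 = perturbed_s2(dims, params)

        def pk(kk):
            return pk_perturbed(kk, dims, params, s2, coefficients)

    else:

        def pk(kk):
            return pk_unperturbed(kk, dims, params, coefficients)

    return reduced_intensity(k, sample, A2_app, pk)
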