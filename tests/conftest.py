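import numpy as np
import pytest
from hypothesis import settings

from wormsaxs import SampleSpec, SyntheticSpec, WormlikeParams, generate_profile
from wormsaxs import pullulan

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# printed reference values for the six pullulan standards:
# (rg_perturbed, tol) and (rg_unperturbed, tol) in nm, A2 in 1e-4 cm^3 g^-2 mol.
# Half-subscript notation in the source tables (e.g. 7.6_5) is a half final
# digit; tolerances are +/-1 of the last printed digit.
TABLE_RG = {
    "P20": ((4.9, 0.1), (4.7, 0.1)),
    "P50": ((7.65, 0.05), (7.1, 0.1)),
    "P100": ((12.5, 0.5), (11.0, 1.0)),
    "P200": ((18.0, 1.0), (15.0, 1.0)),
    "P400": ((24.0, 1.0), (20.0, 1.0)),
    "P800": ((37.0, 1.0), (28.0, 1.0)),
}
TABLE_A2 = {
    "P20": (3.9, 0.1),
    "P50": (6.0, 0.1),
    "P100": (1.85, 0.05),
    "P200": (3.1, 0.1),
    "P400": (3.2, 0.1),
    "P800": (2.3, 0.1),
}


@pytest.fixture(scope="session")
def p800_params() -> WormlikeParams:
    return pullulan.wormlike_params("P800")


@pytest.fixture(scope="session")
def p800_sample() -> SampleSpec:
    return pullulan.sample_spec("P800")


@pytest.fixture(scope="session")
def p800_noiseless_profile(p800_params, p800_sample):
    spec = SyntheticSpec(
        true_params=p800_params, sample=p800_sample,
        A2_app=pullulan.SAMPLES["P800"]["A2_app"], sigma_rel=0.0, seed=0,
    )
    return generate_profile(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
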