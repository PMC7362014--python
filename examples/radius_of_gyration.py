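"""Derived chain dimensions of the six pullulan standards.

For each sample the contour length follows from L = M_w/M_L, the
unperturbed radius of gyration from the wormlike-chain closed form, and
the perturbed radius from the quasi-two-parameter expansion factor.
The two radii bracket the effect of intramolecular excluded volume:
their ratio grows from ~1.05 at M_w = 2.3e4 to ~1.34 at 7.4e5.
"""

import math

from wormsaxs import chain_dimensions, perturbed_s2
from wormsaxs import pullulan

print(f"{'sample':<8}{'M_w':>10}{'L/nm':>10}{'rg0/nm':>9}{'rg/nm':>8}{'rg/rg0':>8}")
for name, s in pullulan.SAMPLES.items():
    params = pullulan.wormlike_params(name)
    dims = chain_dimensions(s["M_w"], params)
    rg0 = math.sqrt(dims.S2_0)
    rg = math.sqrt(perturbed_s2(dims, params))
    print(f"{name:<8}{s['M_w']:>10.3g}{dims.L:>10.1f}{rg0:>9.2f}{rg:>8.2f}{rg / rg0:>8.3f}")
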