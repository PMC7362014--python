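"""Reference inputs for pullulan, an alpha-glucan of maltotriose repeats.

``SAMPLES`` collects literature metadata and SAXS-derived wormlike-chain
parameters for six commercial pullulan standards (P20–P800) in 0.05 M
aqueous NaCl at 25 C: weight-average molecular weight ``M_w``,
polydispersity ``M_w/M_n``, measured mass concentration ``c`` (g/cm^3),
persistence length ``q`` (nm), excluded-volume strength ``B`` (nm), bead
diameter ``d_b`` (nm) with molar mass per contour length fixed at
470 nm^-1, and the apparent second virial coefficient ``A2_app``
(cm^3 g^-2 mol).

Chemistry constants: glucose-residue mass ``M0 = 162`` g/mol and virtual
bond length (O–O distance across a glucosidic linkage) ``b_u = 0.479``
nm for pullulan (root-mean-square over the maltotriose unit), 0.425 nm
for amylose.
"""

from __future__ import annotations

from .chain import SampleSpec, WormlikeParams

__all__ = [
    "M_L_DEFAULT",
    "M0_GLUCOSE",
    "BU_PULLULAN",
    "BU_AMYLOSE",
    "SAMPLES",
    "sample_spec",
    "wormlike_params",
    "average_params",
]

M_L_DEFAULT = 470.0     # g mol^-1 nm^-1, fixed when fitting SAXS profiles
M0_GLUCOSE = 162.0      # g/mol per glucose residue
BU_PULLULAN = 0.479     # nm
BU_AMYLOSE = 0.425      # nm

# sample: M_w, M_w/M_n, c [g/cm^3], q [nm], B [nm], d_b [nm], A2_app [cm^3 g^-2 mol]
SAMPLES: dict[str, dict[str, float]] = {
    "P20":  dict(M_w=2.30e4, pdi=1.08, c=6.84e-3, q=1.50, B=0.35, d_b=0.77, A2_app=4.0e-4),
    "P50":  dict(M_w=5.06e4, pdi=1.09, c=5.11e-3, q=1.50, B=0.30, d_b=0.77, A2_app=6.5e-4),
    "P100": dict(M_w=1.16e5, pdi=1.11, c=7.61e-3, q=1.60, B=0.30, d_b=0.89, A2_app=2.0e-4),
    "P200": dict(M_w=2.02e5, pdi=1.31, c=6.16e-3, q=1.65, B=0.38, d_b=0.77, A2_app=3.7e-4),
    "P400": dict(M_w=3.43e5, pdi=1.30, c=5.48e-3, q=1.65, B=0.35, d_b=0.89, A2_app=4.2e-4),
    "P800": dict(M_w=7.36e5, pdi=1.23, c=5.79e-3, q=1.50, B=0.52, d_b=0.84, A2_app=3.5e-4),
}


def sample_spec(name: str) -> SampleSpec:
    """Sample metadata (M_w, c, polydispersity) for one named standard."""
    s = SAMPLES[name]
    return SampleSpec(M_w=s["M_w"], c=s["c"], polydispersity=s["pdi"])


def wormlike_params(name: str, M_L: float = M_L_DEFAULT) -> WormlikeParams:
    """SAXS-derived wormlike-chain parameters for one named standard."""
    s = SAMPLES[name]
    return WormlikeParams(M_L=M_L, q=s["q"], B=s["B"], d_b=s["d_b"])


def average_params(M_L: float = M_L_DEFAULT, d_b: float = 1.0) -> WormlikeParams:
    """Parameters averaged over the six standards, with the bead diameter
    that also describes oligomer radii of gyration (d_b = 1.0 nm)."""
    n = len(SAMPLES)
    q = sum(s["q"] for s in SAMPLES.values()) / n
    B = sum(s["B"] for s in SAMPLES.values()) / n
    return WormlikeParams(M_L=M_L, q=q, B=B, d_b=d_b)
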