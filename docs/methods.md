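# Methods

## Model

A dissolved semiflexible polymer is represented as a Kratky–Porod
(wormlike) chain of contour length `L` and persistence length `q`,
decorated with contiguous ("touched") beads of diameter `d_b` to carry
finite chain thickness, and perturbed by intramolecular excluded volume
of strength `B`. The map from molecular weight to geometry is
`L = M_w/M_L` with `M_L` the molar mass per unit contour length. The
model is monodisperse; the polydispersity of a sample is carried as
metadata only, which matches how narrow standards (M_w/M_n ≤ 1.3) are
analysed in practice.

Unperturbed dimensions use the Benoit–Doty closed form for `<S²>₀`,
which interpolates between the rod limit `L²/12` and the coil limit
`qL/3`. Excluded volume uses the quasi-two-parameter (QTP) scheme:
scaled variable `z̃ = (3/4)K(N)(3/2π)^{3/2}(B/2q)√N` with
`N = L/2q`, the Yamakawa–Shimada–Stockmayer piecewise stiffness factor
`K(N)` (algebraic branch for `N > 6`, exponential branch below), and
the Domb–Barrett closed form for the radius expansion factor
`α_S(z̃)`. All QTP coefficients sit in one constants block in
`excluded_volume.py`. These standard forms were validated end-to-end:
with the literature chain parameters of the six pullulan standards they
reproduce every published (perturbed, unperturbed) radius pair to ±1 in
the last printed digit, which is also enforced as a test.

The form factor is the coil–rod crossover parametrization
`P(k) = [(1−w)P_coil + w P_rod]·Γ·F₀b²` with switch `w = exp(−ξ⁻⁵)`.
The crossover variables are
`ξ = (π/2N)(<S²>₀/(2q)²)(2qk)` (unperturbed) and
`ξ' = (π/1.103N)^{3/2}(<S²>^{1/2}/2q)^{2.564}(2qk)` (perturbed); both
are linear in `k`, so the coil branch is exact at low `k` and the rod
branch takes over at high `k`. The rod branch is unaffected by
excluded volume; the coil branch of the perturbed chain is evaluated at
the swollen radius.

### Crossover correction Γ

The residual correction factors Γ(k; N, ξ) and Γ′(k; N, ξ′) of the
published crossover parametrizations are tabulated coefficient sets
that are not bundled here. `CrossoverCoefficients` is a named,
versioned registry accepting user-supplied callables; the shipped
default is the unity correction Γ = Γ′ = 1, which is exact in the
`k → 0` limit where every radius-level quantity in this package lives,
and leaves the qualitative coil–rod crossover to the blend switch and
the bead factor. Consequences worth knowing:

- all `<S²>`-level results (radii, virial conversion, characteristic
  ratio) are independent of Γ;
- at `B = 0` the unperturbed (ξ) and perturbed (ξ′) parametrizations
  agree to ≤3% only in the coil-dominated region; across the crossover
  they differ by up to ~40%, precisely the region the published Γ
  tables correct. Fits of synthetic data are self-consistent (the
  generator and estimator share the forward model), but absolute
  high-k shapes should not be over-interpreted under the unity set.
- the Pedersen–Schurtenberger excluded-volume coil function
  (tanh switch at `x = k·rg ≈ 1.5` to the swollen-coil power law,
  ν = 0.585, C₁ = 1.2220, C₂ = 0.4288, C₃ = −1.651) is available as an
  optional coil branch (`coil="ps_exv"`); the default is the Debye
  function at the perturbed radius, which keeps the `B → 0` limit
  consistent.

The forward model used by the generator and the fit is the *perturbed*
parametrization for every `B ≥ 0` (at `B = 0`, `α_S = 1`), so the model
family is continuous in `B`; the unperturbed parametrization is kept as
the explicit comparison model for assessing the excluded-volume effect.

## Concentration and virial handling

Finite concentration enters as
`R/K_e c = M_w P(k)/[1 + 2 A2_app M_w P(k) c]`. Including the third
virial term `A₃ = g A₂² M_w` in the inverse-intensity expansion gives
`A2_app = A₂ + (3g/2) A₂² M_w c`, whose positive root is
`A₂ = [√(1 + 6 g A2_app M_w c) − 1]/(3 g M_w c)`; `g = 1/3` by default
(good-solvent approximation), overridable everywhere. The pair of
closed forms is verified as an exact round trip (1e−12 relative) and
against all six published (A₂,app → A₂) pairs. Raw-reduction helpers
(`reduce_raw`, `optical_constant`) implement the excess Rayleigh ratio
and `K_e = N_A a_e² γ²` with caller-supplied contrast factor γ.

## Fitting

`fit_profile` formalizes the manual staged procedure: `d_b` and
`A2_app` only shape the high-`k` and low-`k` ends, `q` and `B` act
everywhere. Stages: (1) bounded least squares over (q, B) on the full
window, (2) `d_b` on the highest third of points, then `A2_app` on the
lowest third, (3) joint polish. `M_L` is always held fixed (default
470 g mol⁻¹ nm⁻¹) — it is practically degenerate with `q` in a
single-sample fit. Objective: least squares on Kratky values `k²I`,
uniform by default, inverse-variance (`1/(k²σ)²`) when a σ column is
present. Bounds: q ∈ [0.5, 10] nm, B ∈ [0, 2] nm, d_b ∈ [0.2, 3] nm,
A2_app ∈ [0, 2×10⁻³] cm³ g⁻² mol; initial guesses (2, 0.3, 0.8,
3×10⁻⁴); five seeded, jittered starts guard against local minima.
Non-convergence is flagged in the result, not raised. Profiles must
have ≥20 points spanning a decade in `k`.

Estimator behaviour under the default study conditions (P800-like
truth, 100 log-spaced points over 0.05–3 nm⁻¹, 2% multiplicative
noise, inverse-variance weighting): recovery is unbiased, `d_b` and
`A2_app` come back to ~1%, but `q` and `B` are anticorrelated at
r ≈ −0.999 (they trade off along a ridge of nearly constant perturbed
radius), giving 20-seed median errors of ≈7% for `q` and ≈12% for `B`.
This spread is the information limit of the objective at that noise —
the optimizer demonstrably reaches the global minimum — and shrinks
roughly linearly with the noise level (≈3% for `B` at 0.5% noise).
Noiseless profiles are recovered to optimizer tolerance (≪1%).

## Synthetic data

`generate_profile` evaluates the forward model on a log-spaced grid
(default 100 points, 0.05–3 nm⁻¹, the experimentally typical window)
and applies multiplicative Gaussian noise `I = model·(1 + ε)`,
`ε ~ N(0, σ_rel)`, defaulting to σ_rel = 2% — multiplicative because
photon-counting error scales with intensity over this dynamic range.
The σ column stores the true per-point level `σ_rel·model`. Seeds are
mandatory in serialized specs; identical seeds give bit-identical
profiles. Not emulated: Poisson statistics, instrumental smearing,
buffer-subtraction artifacts, interparticle structure factors beyond
the virial denominator — so passing recovery tests demonstrate
estimator correctness under the stated noise model, not robustness to
every instrumental effect in measured data.

`generate_s2_dataset` tabulates the thickness-corrected
`<S²> = α_S²<S²>₀ + (3/20)d_b²` from oligomer masses (n = 3–12 glucose
residues, M = 162n) to 7.4×10⁵, the range over which a single smooth
curve connects oligomer and polymer dimensions for a non-helical chain.

## Numerical choices

- `<S²>₀`: Taylor series in `x = L/q` (summed to machine precision) for
  `x < 0.2`; the direct closed form cancels as ~24·eps/x⁴ there. Branch
  agreement at the seam is better than 1e−10 (checked against a
  40-digit oracle).
- Debye, rod and bead-sphere functions switch to series below
  u = 10⁻⁴, v = 10⁻³, x = 10⁻³ respectively; `Si` comes from
  `scipy.special.sici` (verified to 1e−10 against quadrature).
- Blend weight `exp(−ξ⁻⁵)` is clamped to 0 for ξ < 10⁻² and 1 for
  ξ > 10³ (under/overflow guards); the weight at `k = 0` is defined
  as 0 (pure coil).
- `√(1+a) − 1` in the virial conversion is computed as `a/(√(1+a)+1)`
  so the `c → 0` limit is exact.
- `K(N)` keeps the published piecewise forms, whose branches meet near
  `N = 6` with a ~0.2% step; this is inherent to the cited
  parametrization and far below the precision of any derived quantity.

## Known limitations

- Γ = Γ′ = 1 by default (see above); supply a coefficient table for
  quantitative high-k work.
- Single-sample fits only; no global multi-sample fitting with shared
  parameters, no fitting of `M_L`.
- No polydisperse averaging of `P(k)` or `<S²>`; no smearing.
- Hydrodynamic properties ([η], R_H) and A₂ theory curves are out of
  scope; A₂ appears only through the apparent→true conversion.
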