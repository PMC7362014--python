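"""Staged nonlinear estimation of wormlike-chain parameters from a
reduced-intensity profile.

Free parameters are the persistence length ``q``, excluded-volume
strength ``B``, bead diameter ``d_b`` and apparent second virial
coefficient ``A2_app``; the mass per contour length ``M_L`` is held
fixed (it is practically degenerate with ``q`` in a single-sample fit).
The objective is least squares on Kratky-transformed values ``k^2 I``,
optionally inverse-variance weighted.

The fit is staged the way an experienced analyst proceeds by hand:
``d_b`` and ``A2_app`` shape only the high-k and low-k ends of the
profile respectively, while ``q`` and ``B`` act over the whole range.

    Stage 1  (q, B) over the full k-window, d_b and A2_app at guesses;
    Stage 2  d_b on the highest third of k-points, then A2_app on the
             lowest third;
    Stage 3  joint polish of all free parameters.

Five jittered, seeded starting points guard against local minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .chain import SampleSpec, WormlikeParams, chain_dimensions
from .excluded_volume import perturbed_s2
from .model import model_intensity
from .solution import ScatteringProfile, true_A2

__all__ = ["FitConfig", "FitResult", "fit_profile", "profile_residual"]

_PARAM_ORDER = ("q", "B", "d_b", "A2_app")


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the staged fit.

    ``bounds`` / ``initial`` map parameter names to (lo, hi) intervals
    and starting values; ``window_fraction`` sets the size of the low-k
    (A2_app) and high-k (d_b) refinement windows as a fraction of the
    number of points.
    """

    M_L: float = 470.0
    perturbed: bool = True
    weighting: str = "uniform"  # or "inverse_variance"
    bounds: dict = field(
        default_factory=lambda: {
            "q": (0.5, 10.0),
            "B": (0.0, 2.0),
            "d_b": (0.2, 3.0),
            "A2_app": (0.0, 2.0e-3),
        }
    )
    initial: dict = field(
        default_factory=lambda: {"q": 2.0, "B": 0.3, "d_b": 0.8, "A2_app": 3.0e-4}
    )
    window_fraction: float = 1.0 / 3.0
    n_starts: int = 5
    jitter: float = 0.3
    seed: int = 0
    max_iterations: int = 200
    tolerance: float = 1e-10

    def __post_init__(self) -> None:
        if self.weighting not in ("uniform", "inverse_variance"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        for name in _PARAM_ORDER:
            lo, hi = self.bounds[name]
            if not 0 <= lo < hi:
                raise ValueError(f"bounds for {name} must satisfy 0 <= lo < hi")


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters plus derived chain dimensions and diagnostics.

    Derived values (rg0 = <S^2>_0^{1/2}, rg = <S^2>^{1/2}, true A2) are
    always recomputed from ``params``/``A2_app``, never stored
    independently.
    """

    params: WormlikeParams
    A2_app: float
    sample: SampleSpec
    residual_norm: float
    converged: bool
    stages: tuple = ()

    @property
    def derived(self) -> dict:
        dims = chain_dimensions(self.sample.M_w, self.params)
        s2 = perturbed_s2(dims, self.params)
        return {
            "rg0": float(np.sqrt(dims.S2_0)),
            "rg": float(np.sqrt(s2)),
            "A2": true_A2(self.A2_app, self.sample.M_w, self.sample.c),
        }


def _weights(profile: ScatteringProfile, weighting: str) -> np.ndarray:
    if weighting == "inverse_variance":
        if profile.sigma is None:
            raise ValueError("inverse-variance weighting requires a sigma column")
        if np.any(profile.sigma <= 0):
            raise ValueError("inverse-variance weighting requires strictly positive sigma")
        return 1.0 / (profile.k ** 2 * profile.sigma)
    return np.ones_like(profile.k)


def profile_residual(
    profile: ScatteringProfile,
    params: WormlikeParams,
    A2_app: float,
    weighting: str = "uniform",
    perturbed: bool = True,
) -> float:
    """Weighted sum of squared Kratky-space residuals; 0 iff exact match."""
    r = _residual_vector(profile, params, A2_app, _weights(profile, weighting),
                         perturbed, np.ones(profile.k.size, dtype=bool))
    return float(np.dot(r, r))


def _residual_vector(profile, params, A2_app, w, perturbed, mask):
    if profile.meta is None:
        raise ValueError("profile has no sample metadata (M_w, c)")
    k = profile.k[mask]
    model = model_intensity(k, profile.meta, params, A2_app, perturbed=perturbed)
    return w[mask] * (k ** 2 * np.asarray(model) - k ** 2 * profile.intensity[mask])


def _make_params(x: np.ndarray, config: FitConfig) -> tuple[WormlikeParams, float]:
    q, B, d_b, A2_app = x
    return WormlikeParams(M_L=config.M_L, q=q, B=max(B, 0.0), d_b=d_b), A2_app


def _solve(profile, config, x0, free, mask, w):
    """Bounded least squares over the sub-vector of free parameters."""
    idx = [i for i, name in enumerate(_PARAM_ORDER) if name in free]
    lo = np.array([config.bounds[_PARAM_ORDER[i]][0] for i in idx])
    hi = np.array([config.bounds[_PARAM_ORDER[i]][1] for i in idx])
    x0_sub = np.clip(np.asarray(x0, dtype=float)[idx], lo, hi)

    def fun(sub):
        x = np.array(x0, dtype=float)
        x[idx] = sub
        params, a2 = _make_params(x, config)
        return _residual_vector(profile, params, a2, w, config.perturbed, mask)

    sol = least_squares(
        fun,
        x0_sub,
        bounds=(lo, hi),
        x_scale=np.maximum(np.abs(x0_sub), 0.1 * (hi - lo)),
        xtol=config.tolerance,
        ftol=config.tolerance,
        gtol=config.tolerance,
        max_nfev=config.max_iterations * (len(idx) + 1),
    )
    x = np.array(x0, dtype=float)
    x[idx] = sol.x
    return x, float(np.dot(sol.fun, sol.fun)), bool(sol.status > 0)


def _staged_fit(profile, config, x0):
    n = profile.k.size
    w = _weights(profile, config.weighting)
    full = np.ones(n, dtype=bool)
    n_win = max(int(round(config.window_fraction * n)), 4)
    low = np.zeros(n, dtype=bool)
    low[:n_win] = True
    high = np.zeros(n, dtype=bool)
    high[-n_win:] = True

    # B has no effect on the unperturbed model; keep it out of the fit then
    shape_free = {"q", "B"} if config.perturbed else {"q"}
    joint_free = set(_PARAM_ORDER) if config.perturbed else {"q", "d_b", "A2_app"}

    stages = []
    x, cost, ok1 = _solve(profile, config, x0, shape_free, full, w)
    stages.append(("q,B full-window", cost, ok1))
    x, cost, ok2 = _solve(profile, config, x, {"d_b"}, high, w)
    stages.append(("d_b high-k", cost, ok2))
    x, cost, ok3 = _solve(profile, config, x, {"A2_app"}, low, w)
    stages.append(("A2_app low-k", cost, ok3))
    x, cost, ok4 = _solve(profile, config, x, joint_free, full, w)
    stages.append(("joint polish", cost, ok4))
    return x, cost, all((ok1, ok2, ok3, ok4)), tuple(stages)


def fit_profile(profile: ScatteringProfile, config: FitConfig | None = None) -> FitResult:
    """Staged bounded least-squares fit of one profile.

    Requires at least 20 points spanning a decade in k.  Non-convergence
    is reported through ``FitResult.converged``, not raised.
    """
    config = config or FitConfig()
    if profile.k.size < 20:
        raise ValueError("profile too short: need >= 20 points")
    if profile.k[-1] / profile.k[0] < 10:
        raise ValueError("profile must span at least a decade in k")

    x0_center = np.array([config.initial[name] for name in _PARAM_ORDER])
    rng = np.random.default_rng(config.seed)
    starts = [x0_center]
    for _ in range(max(config.n_starts - 1, 0)):
        jit = x0_center * (1.0 + config.jitter * rng.uniform(-1, 1, size=4))
        starts.append(jit)

    best = None
    for x0 in starts:
        x, cost, ok, stages = _staged_fit(profile, config, x0)
        if best is None or cost < best[1]:
            best = (x, cost, ok, stages)

    x, cost, ok, stages = best
    params, a2 = _make_params(x, config)
    return FitResult(
        params=params,
        A2_app=a2,
        sample=profile.meta,
        residual_norm=cost,
        converged=ok,
        stages=stages,
    )
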