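"""Plain-text profile I/O, analysis configuration and fit reports.

Profiles are whitespace-delimited text columns with a commented header::

    # k[nm^-1] RKc[g^-1 mol] sigma
    5.000000e-02 7.123e+04 1.42e+03
    ...

A sidecar YAML config carries sample metadata and model defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .chain import SampleSpec
from .fitting import FitConfig, FitResult
from .solution import ScatteringProfile

__all__ = [
    "AnalysisConfig",
    "read_profile",
    "write_profile",
    "write_report",
    "report_dict",
]

_HEADER = "# k[nm^-1] RKc[g^-1 mol] sigma"


@dataclass(frozen=True)
class AnalysisConfig:
    """Resolved analysis configuration: sample block, model block, fit block.

    Unknown keys in a config file are rejected with an error naming the
    offending key.
    """

    sample: SampleSpec | None = None
    M_L: float = 470.0
    g: float = 1.0 / 3.0
    b_u: float = 0.479
    M0: float = 162.0
    fit: FitConfig = field(default_factory=FitConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        known_top = {"sample", "model", "fit"}
        for key in raw:
            if key not in known_top:
                raise ValueError(f"unknown config key: {key!r}")
        kwargs: dict = {}
        sample = raw.get("sample")
        if sample is not None:
            allowed = {"M_w", "c", "polydispersity"}
            for key in sample:
                if key not in allowed:
                    raise ValueError(f"unknown config key: sample.{key!r}")
            kwargs["sample"] = SampleSpec(**sample)
        model = raw.get("model", {})
        allowed = {"M_L", "g", "b_u", "M0"}
        for key in model:
            if key not in allowed:
                raise ValueError(f"unknown config key: model.{key!r}")
        kwargs.update(model)
        fit = raw.get("fit", {})
        allowed = {f.name for f in FitConfig.__dataclass_fields__.values()}
        for key in fit:
            if key not in allowed:
                raise ValueError(f"unknown config key: fit.{key!r}")
        fit = dict(fit)
        fit.setdefault("M_L", kwargs.get("M_L", 470.0))
        kwargs["fit"] = FitConfig(**fit)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)


def read_profile(path: str | Path, meta: SampleSpec | None = None) -> ScatteringProfile:
    """Read a whitespace/comma-delimited text profile.

    Malformed rows and non-increasing k are rejected with the offending
    line number.
    """
    rows: list[tuple[float, ...]] = []
    lines: list[int] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        text = line.strip()
        if not text or text.startswith("#"):
            continue
        fields = text.replace(",", " ").split()
        if len(fields) < 2:
            raise ValueError(f"{path}: line {lineno}: expected >= 2 columns")
        try:
            rows.append(tuple(float(f) for f in fields[:3]))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: malformed number") from exc
        lines.append(lineno)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    k = np.array([r[0] for r in rows])
    bad = np.nonzero(np.diff(k) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"{path}: line {lines[bad[0] + 1]}: k must be strictly increasing"
        )
    intensity = np.array([r[1] for r in rows])
    has_sigma = all(len(r) >= 3 for r in rows)
    sigma = np.array([r[2] for r in rows]) if has_sigma else None
    return ScatteringProfile(k=k, intensity=intensity, sigma=sigma, meta=meta)


def write_profile(profile: ScatteringProfile, path: str | Path) -> None:
    """Write a profile in the header format read by :func:`read_profile`;
    round trip is lossless to the printed precision (12 significant digits)."""
    lines = [_HEADER]
    sigma = profile.sigma
    for i in range(len(profile)):
        cols = [f"{profile.k[i]:.12e}", f"{profile.intensity[i]:.12e}"]
        if sigma is not None:
            cols.append(f"{sigma[i]:.12e}")
        lines.append(" ".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


def report_dict(result: FitResult, config: AnalysisConfig | None = None, seed=None) -> dict:
    """Machine-readable fit report mirroring the standard parameter-table
    schema (M_L, q, B, d_b, A2_app, A2, rg, rg0) plus provenance."""
    derived = result.derived
    rep = {
        "M_L": float(result.params.M_L),
        "q": float(result.params.q),
        "B": float(result.params.B),
        "d_b": float(result.params.d_b),
        "A2_app": float(result.A2_app),
        "A2": float(derived["A2"]),
        "rg": float(derived["rg"]),
        "rg0": float(derived["rg0"]),
        "M_w": float(result.sample.M_w),
        "c": float(result.sample.c),
        "residual_norm": float(result.residual_norm),
        "converged": bool(result.converged),
        "stages": [[str(name), float(cost), bool(ok)] for name, cost, ok in result.stages],
    }
    if seed is not None:
        rep["seed"] = int(seed)
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(
                {
                    "M_L": config.M_L,
                    "g": config.g,
                    "b_u": config.b_u,
                    "M0": config.M0,
                },
                sort_keys=True,
            ).encode()
        ).hexdigest()[:12]
        rep["config_hash"] = digest
    return rep


def write_report(result: FitResult, path: str | Path, config=None, seed=None) -> None:
    """Write the fit report: a human-readable table followed by a
    machine-readable YAML block."""
    rep = report_dict(result, config=config, seed=seed)
    rows = [
        ("M_L / nm^-1", f"{rep['M_L']:.0f}"),
        ("q / nm", f"{rep['q']:.3g}"),
        ("B / nm", f"{rep['B']:.3g}"),
        ("d_b / nm", f"{rep['d_b']:.3g}"),
        ("A2_app / cm^3 g^-2 mol", f"{rep['A2_app']:.3g}"),
        ("A2 / cm^3 g^-2 mol", f"{rep['A2']:.3g}"),
        ("<S^2>^1/2 / nm", f"{rep['rg']:.3g}"),
        ("<S^2>_0^1/2 / nm", f"{rep['rg0']:.3g}"),
    ]
    width = max(len(r[0]) for r in rows)
    table = "\n".join(f"# {name:<{width}}  {val}" for name, val in rows)
    body = yaml.safe_dump(rep, sort_keys=True)
    Path(path).write_text(table + "\n---\n" + body)
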