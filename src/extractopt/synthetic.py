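"""Synthetic design tables with the statistical structure the analysis
assumes: a 4-factor Box-Behnken design whose response follows a known full
quadratic polynomial plus homoscedastic Gaussian noise.  Every pipeline
stage is testable against tables generated here, with ground truth known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data_io import DesignTable, paper_fixture
from .doe import PAPER_DOMAINS, FactorDomain, build_bbd
from .rsm import QuadraticModel, fit_quadratic, predict

__all__ = ["SurfaceSpec", "simulate_table", "paperlike_spec", "simulate_screening"]


@dataclass
class SurfaceSpec:
    """Ground-truth quadratic surface plus the noise and replication plan."""

    model: QuadraticModel
    noise_sd: float  # response noise σ, in yield %
    n_center: int = 5
    seed: Optional[int] = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def to_dict(self) -> dict:
        return {"model": self.model.to_dict(), "noise_sd": self.noise_sd,
                "n_center": self.n_center, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "SurfaceSpec":
        return cls(QuadraticModel.from_dict(d["model"]), d["noise_sd"],
                   d["n_center"], d["seed"])


def simulate_table(spec: SurfaceSpec, domains: Sequence[FactorDomain] = PAPER_DOMAINS,
                   seed: Optional[int] = None) -> DesignTable:
    """A BBD table whose yields are the true surface plus N(0, σ²) noise.

    ``seed`` overrides ``spec.seed`` when given.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    design = build_bbd(domains, n_center=spec.n_center)
    mean = predict(spec.model, design.factors)
    noise = rng.normal(0.0, spec.noise_sd, len(design)) if spec.noise_sd > 0 \
        else np.zeros(len(design))
    return design.with_yields(mean + noise)


def paperlike_spec(noise_sd: Optional[float] = None, n_center: int = 5,
                   seed: Optional[int] = None) -> SurfaceSpec:
    """Surface spec matching the packaged 29-run study.

    The true coefficients are the quadratic re-fit of the fixture (the
    printed regression equation is typographically unreliable and is never
    used), and the default noise σ is the square root of the fixture
    ANOVA's residual mean square (≈ 1.27 % yield).
    """
    table = paper_fixture()
    model = fit_quadratic(table, coding="coded")
    if noise_sd is None:
        resid = table.yields - model.fitted
        noise_sd = float(np.sqrt((resid @ resid) / (len(table) - 15)))
    return SurfaceSpec(model=model, noise_sd=noise_sd, n_center=n_center, seed=seed)


_SHAPES = ("peaked", "monotone", "plateau")


def simulate_screening(curve_shape: str, levels: Sequence[float], noise_sd: float = 0.0,
                       seed: Optional[int] = None, peak_index: Optional[int] = None):
    """Single-factor screening curves for exercising BBD level selection.

    Shapes: ``peaked`` (unimodal with an interior maximum), ``monotone``
    (strictly increasing), ``plateau`` (rises then stays flat from
    ``peak_index`` onward, so the tie-rule picks the earliest plateau
    level).

    Returns a list of ``(level, mean_yield)`` pairs.
    """
    if curve_shape not in _SHAPES:
        raise ValueError(f"unknown curve_shape {curve_shape!r}; choose from {_SHAPES}")
    levels = [float(v) for v in levels]
    if len(levels) < 3:
        raise ValueError(f"need at least 3 levels, got {len(levels)}")
    k = len(levels)
    if peak_index is None:
        peak_index = k // 2 if curve_shape == "peaked" else (
            k - 1 if curve_shape == "monotone" else 1)
    pos = np.arange(k, dtype=float)
    if curve_shape == "peaked":
        means = 15.0 - (pos - peak_index) ** 2
    elif curve_shape == "monotone":
        means = 10.0 + pos
    else:  # plateau
        means = 10.0 + np.minimum(pos, peak_index)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, k) if noise_sd > 0 else np.zeros(k)
    return list(zip(levels, (means + noise).tolist()))
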