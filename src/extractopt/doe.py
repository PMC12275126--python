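"""Box-Behnken design construction and factor coding.

A Box-Behnken design (BBD) for four factors crosses every pair of factors
at their (±1, ±1) corners while the other two sit at the center, then adds
replicated all-center runs: 6 pairs × 4 corners + n_center = 24 + n_center
runs.  Coding maps the three actual levels (low, mid, high) linearly onto
−1, 0, +1 so that quadratic response-surface terms are comparable across
factors with very different units.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FactorDomain",
    "CodedPoint",
    "select_bbd_levels",
    "build_bbd",
    "encode",
    "decode",
]


@dataclass(frozen=True)
class FactorDomain:
    """One process factor with its three BBD levels.

    Parameters
    ----------
    name : str
        Factor identifier (e.g. ``"ratio"``).
    unit : str
        Physical unit, e.g. ``"mL/g"``.
    low, mid, high : float
        The three design levels; ``mid`` must be the midpoint of
        ``low``/``high`` up to rounding.
    screen_levels : tuple of float, optional
        The single-factor screening levels the BBD levels were chosen from.
    """

    name: str
    unit: str
    low: float
    mid: float
    high: float
    screen_levels: tuple = field(default=())

    def __post_init__(self):
        if not (self.low < self.mid < self.high):
            raise ValueError(
                f"factor {self.name!r}: levels must satisfy low < mid < high, "
                f"got ({self.low}, {self.mid}, {self.high})"
            )
        span = self.high - self.low
        if abs(self.mid - (self.low + self.high) / 2.0) > 0.05 * span:
            raise ValueError(
                f"factor {self.name!r}: mid level {self.mid} is not the "
                f"midpoint of ({self.low}, {self.high})"
            )
        if self.screen_levels and any(
            b <= a for a, b in zip(self.screen_levels, self.screen_levels[1:])
        ):
            raise ValueError(
                f"factor {self.name!r}: screen_levels must be strictly increasing"
            )

    @property
    def half_range(self) -> float:
        return (self.high - self.low) / 2.0

    @property
    def levels(self) -> tuple:
        return (self.low, self.mid, self.high)


@dataclass(frozen=True)
class CodedPoint:
    """Coded coordinates of one design point; −1/0/+1 for design runs,
    real-valued for prediction queries."""

    values: tuple

    def __post_init__(self):
        if len(self.values) != 4:
            raise ValueError(f"expected 4 coded coordinates, got {len(self.values)}")

    def __iter__(self):
        return iter(self.values)


def select_bbd_levels(screen_curve: Sequence) -> tuple:
    """Pick the three BBD levels from a single-factor screening curve.

    The peak-response level becomes the mid level and its two neighbours the
    extremes.  If the peak sits at an endpoint of the screened range, the
    endpoint is kept as an extreme level and the returned triple is the
    endpoint plus its two nearest interior neighbours (the middle of the
    triple is then the mid level).  Ties are broken toward the lower level.

    Parameters
    ----------
    screen_curve : sequence of (level, mean_yield)
        Ordered by increasing level.

    Returns
    -------
    (low, mid, high) : tuple of float
    """
    curve = list(screen_curve)
    if len(curve) < 3:
        raise ValueError(f"need at least 3 screening levels, got {len(curve)}")
    levels = [float(lv) for lv, _ in curve]
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("screening levels must be strictly increasing")
    yields = np.asarray([y for _, y in curve], dtype=float)
    peak = int(np.argmax(yields))  # argmax takes the first maximum: low tie-break
    if peak == 0:
        triple = levels[0:3]
    elif peak == len(levels) - 1:
        triple = levels[-3:]
    else:
        triple = levels[peak - 1 : peak + 2]
    return tuple(triple)


def _bbd_coded_rows(n_center: int) -> np.ndarray:
    """Coded rows of the 4-factor BBD in canonical pair-lexicographic order."""
    rows = []
    for a, b in itertools.combinations(range(4), 2):
        for sa, sb in itertools.product((-1.0, 1.0), repeat=2):
            row = [0.0, 0.0, 0.0, 0.0]
            row[a], row[b] = sa, sb
            rows.append(row)
    rows.extend([[0.0, 0.0, 0.0, 0.0]] * n_center)
    return np.asarray(rows)


def build_bbd(domains: Sequence[FactorDomain], n_center: int = 5):
    """Construct the 4-factor Box-Behnken design on actual factor levels.

    Run order is deterministic: the six factor pairs in lexicographic order,
    the four (±1, ±1) corners of each in (−,−), (−,+), (+,−), (+,+) order,
    then the center replicates.

    Returns
    -------
    DesignTable
        With ``yield_pct`` column absent (NaN) until responses are filled in.
    """
    from .data_io import DesignTable  # deferred to avoid import cycle

    domains = tuple(domains)
    if len(domains) != 4:
        raise ValueError(f"a 4-factor BBD needs exactly 4 domains, got {len(domains)}")
    if n_center < 1:
        raise ValueError(f"n_center must be >= 1, got {n_center}")
    coded = _bbd_coded_rows(n_center)
    actual = decode(coded, domains)
    return DesignTable.from_arrays(actual, yields=None, domains=domains)


def encode(points, domains: Sequence[FactorDomain]):
    """Map actual factor values onto coded units: (x − mid) / half_range.

    Accepts a single point (length-4) or an (n, 4) array; returns the same
    shape.  Extrapolation beyond ±1 is permitted.
    """
    x = np.asarray(points, dtype=float)
    mids = np.array([d.mid for d in domains])
    halfs = np.array([d.half_range for d in domains])
    return (x - mids) / halfs


def decode(coded, domains: Sequence[FactorDomain]):
    """Inverse of :func:`encode`: mid + z · half_range."""
    z = np.asarray(coded, dtype=float)
    mids = np.array([d.mid for d in domains])
    halfs = np.array([d.half_range for d in domains])
    return mids + z * halfs


#: The fixture's factor domains, levels as chosen by single-factor screening.
PAPER_DOMAINS = (
    FactorDomain("ratio", "mL/g", 20.0, 25.0, 30.0, (15.0, 20.0, 25.0, 30.0)),
    FactorDomain("temperature", "degC", 80.0, 90.0, 100.0, (40.0, 60.0, 80.0, 100.0)),
    FactorDomain("time", "min", 60.0, 75.0, 90.0, (30.0, 60.0, 90.0, 120.0)),
    FactorDomain("power", "W", 250.0, 300.0, 350.0, (250.0, 350.0, 450.0, 550.0)),
)
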