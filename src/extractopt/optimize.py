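"""Constrained maximization of a fitted surrogate over the design box.

Dense grid search (default 101 points per axis) followed by a
coordinate-ascent polish at 10× finer steps.  The quadratic surface is
cheap enough for an exhaustive grid; the MLP surrogate is non-convex, so
the polish restarts from the best few grid cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["OptimumResult", "maximize", "surface_grid"]

_FACTOR_ORDER = ("ratio", "temperature", "time", "power")


@dataclass
class OptimumResult:
    """The located maximum of one surrogate over the experimental region."""

    settings: dict  # factor name -> actual value
    predicted_yield: float  # %
    surrogate: str
    resolution: int
    at_boundary: dict  # factor name -> bool

    def to_dict(self) -> dict:
        return {"settings": self.settings, "predicted_yield": self.predicted_yield,
                "surrogate": self.surrogate, "resolution": self.resolution,
                "at_boundary": self.at_boundary}

    @classmethod
    def from_dict(cls, d: dict) -> "OptimumResult":
        return cls(d["settings"], d["predicted_yield"], d["surrogate"],
                   d["resolution"], d["at_boundary"])

    def to_text(self) -> str:
        parts = [f"predicted maximum yield = {self.predicted_yield:.4f} %  "
                 f"({self.surrogate})"]
        for k, v in self.settings.items():
            edge = "  [box edge]" if self.at_boundary.get(k) else ""
            parts.append(f"  {k} = {v:.4f}{edge}")
        return "\n".join(parts)


def _grid_axes(box, resolution):
    return [np.linspace(lo, hi, resolution) for lo, hi in box]


def _best_grid_points(predict, box, resolution, k):
    """Top-k grid points, evaluated in chunks over the first axis."""
    axes = _grid_axes(box, resolution)
    best_vals = np.full(k, -np.inf)
    best_pts = np.zeros((k, 4))
    rest = np.stack([g.ravel() for g in np.meshgrid(*axes[1:], indexing="ij")], axis=1)
    for a in axes[0]:
        pts = np.column_stack([np.full(len(rest), a), rest])
        vals = np.asarray(predict(pts))
        order = np.argsort(vals)[-k:]
        cand_vals = np.concatenate([best_vals, vals[order]])
        cand_pts = np.vstack([best_pts, pts[order]])
        keep = np.argsort(cand_vals)[-k:]
        best_vals, best_pts = cand_vals[keep], cand_pts[keep]
    return best_pts[::-1], best_vals[::-1]


def _coordinate_ascent(predict, x0, box, step, tol=1e-6, max_rounds=200):
    x = np.asarray(x0, dtype=float).copy()
    val = float(predict(x[None, :])[0])
    for _ in range(max_rounds):
        improved = False
        for j in range(4):
            lo, hi = box[j]
            for cand in (x[j] - step[j], x[j] + step[j]):
                cand = min(max(cand, lo), hi)
                if cand == x[j]:
                    continue
                trial = x.copy()
                trial[j] = cand
                v = float(predict(trial[None, :])[0])
                if v > val + tol:
                    x, val, improved = trial, v, True
        if not improved:
            step = step / 2.0
            if np.all(step < tol):
                break
    return x, val


def maximize(surrogate, box: Sequence, resolution: int = 101,
             n_starts: int = 5, factor_names=_FACTOR_ORDER) -> OptimumResult:
    """Locate the yield-maximizing factor settings within the box.

    Parameters
    ----------
    surrogate : object with ``predict((n, 4) array) -> (n,) array``
        A fitted quadratic model or MLP surrogate (actual factor units).
    box : sequence of 4 (low, high) pairs
        The experimental region, one pair per factor in table-column order.
    resolution : int
        Grid points per axis for the global stage.
    n_starts : int
        Grid cells from which the coordinate-ascent polish restarts
        (non-convex surrogates benefit from several).
    """
    box = [(float(lo), float(hi)) for lo, hi in box]
    if any(hi <= lo for lo, hi in box):
        raise ValueError(f"empty box {box}")
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    predict = surrogate.predict
    starts, start_vals = _best_grid_points(predict, box, resolution, max(1, n_starts))
    step = np.array([(hi - lo) / max(resolution - 1, 1) / 10.0 for lo, hi in box])
    best_x, best_v = starts[0], start_vals[0]
    for x0 in starts:
        x, v = _coordinate_ascent(predict, x0, box, step.copy())
        if v > best_v:
            best_x, best_v = x, v
    tol = np.array([(hi - lo) / max(resolution - 1, 1) for lo, hi in box])
    flat = np.ptp(start_vals) == 0 and np.allclose(start_vals, best_v)
    at_edge = {
        name: (not flat) and bool(min(best_x[j] - box[j][0], box[j][1] - best_x[j]) <= tol[j])
        for j, name in enumerate(factor_names)
    }
    return OptimumResult(
        settings={name: float(best_x[j]) for j, name in enumerate(factor_names)},
        predicted_yield=float(best_v),
        surrogate=type(surrogate).__name__,
        resolution=resolution,
        at_boundary=at_edge,
    )


def surface_grid(surrogate, pair, others_at: dict, box: Sequence,
                 resolution: int = 51, factor_names=_FACTOR_ORDER):
    """Predictions over a 2-D slice of the factor space, for surface plots.

    Parameters
    ----------
    pair : (str, str)
        The two factor names spanning the grid (rows, then columns).
    others_at : dict
        Actual settings for the remaining two factors.

    Returns
    -------
    (row_axis, col_axis, grid) : two 1-D arrays and the (res, res) matrix.
    """
    for f in pair:
        if f not in factor_names:
            raise ValueError(f"unknown factor {f!r}; expected one of {factor_names}")
    ir, ic = factor_names.index(pair[0]), factor_names.index(pair[1])
    row_axis = np.linspace(*box[ir], resolution)
    col_axis = np.linspace(*box[ic], resolution)
    pts = np.zeros((resolution * resolution, 4))
    for j, name in enumerate(factor_names):
        if name == pair[0]:
            pts[:, j] = np.repeat(row_axis, resolution)
        elif name == pair[1]:
            pts[:, j] = np.tile(col_axis, resolution)
        else:
            pts[:, j] = others_at[name]
    grid = np.asarray(surrogate.predict(pts)).reshape(resolution, resolution)
    return row_axis, col_axis, grid
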