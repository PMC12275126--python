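"""Goodness-of-fit metrics, the stratified train/validation split, and the
model-comparison report.

Metrics follow the standard definitions:

    R²   = 1 − Σ(y − ŷ)² / Σ(y − ȳ)²
    MAE  = (1/n) Σ |y − ŷ|
    RMSE = sqrt((1/n) Σ (y − ŷ)²)

The split sorts runs by observed yield, bands them into ``n_valid``
quantile strata, and draws one validation run per stratum, so validation
covers the whole response range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .data_io import DesignTable
from .errors import DimensionError

__all__ = ["FitMetrics", "SplitSpec", "metrics", "split", "compare_models",
           "ComparisonReport"]


@dataclass
class FitMetrics:
    """R², MAE and RMSE for one (observations, predictions) pair."""

    r2: Optional[float]
    mae: float
    rmse: float
    n: int

    def to_dict(self) -> dict:
        return {"r2": self.r2, "mae": self.mae, "rmse": self.rmse, "n": self.n}

    @classmethod
    def from_dict(cls, d: dict) -> "FitMetrics":
        return cls(d["r2"], d["mae"], d["rmse"], d["n"])

    def to_text(self) -> str:
        r2 = "undefined" if self.r2 is None else f"{self.r2:.4f}"
        return (f"R2 = {r2}   MAE = {self.mae:.4f}   RMSE = {self.rmse:.4f}   "
                f"(n = {self.n})")


def metrics(actual, predicted) -> FitMetrics:
    """Compute R², MAE, RMSE.  With a constant ``actual`` series the total
    sum of squares vanishes and R² is flagged undefined (None)."""
    y = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise DimensionError(f"series shapes differ: {y.shape} vs {p.shape}")
    if len(y) < 1:
        raise ValueError("need at least one observation")
    e = y - p
    sse = float(e @ e)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = None if sst == 0.0 else 1.0 - sse / sst
    return FitMetrics(r2=r2, mae=float(np.abs(e).mean()),
                      rmse=float(np.sqrt(sse / len(y))), n=len(y))


@dataclass
class SplitSpec:
    """Stratified train/validation partition sizes and seed."""

    n_train: int = 21
    n_valid: int = 8
    seed: int = 0


def split(table: DesignTable, spec: SplitSpec):
    """Stratified split: one validation run per yield-quantile stratum.

    Returns ``(train_table, valid_table)``; the two are disjoint and cover
    the input table.
    """
    n = len(table)
    if spec.n_train + spec.n_valid != n:
        raise ValueError(
            f"split sizes {spec.n_train}+{spec.n_valid} do not match table size {n}"
        )
    rng = np.random.default_rng(spec.seed)
    order = np.argsort(table.yields, kind="stable")
    strata = np.array_split(order, spec.n_valid)
    valid_idx = np.sort([s[rng.integers(len(s))] for s in strata])
    train_idx = np.setdiff1d(np.arange(n), valid_idx)
    return table.subset(train_idx), table.subset(valid_idx)


@dataclass
class ComparisonReport:
    """Per-model fit metrics over the full table, ranked by R² descending."""

    entries: list  # (name, FitMetrics), ranked

    @property
    def winner(self) -> str:
        return self.entries[0][0]

    def to_dict(self) -> dict:
        return {"ranking": [{"model": nm, **m.to_dict()} for nm, m in self.entries],
                "winner": self.winner}

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonReport":
        entries = [(e["model"], FitMetrics(e["r2"], e["mae"], e["rmse"], e["n"]))
                   for e in d["ranking"]]
        return cls(entries)

    def to_text(self) -> str:
        lines = [f"{'Model':<16}{'R2':>8}{'MAE':>8}{'RMSE':>8}"]
        for nm, m in self.entries:
            r2 = "" if m.r2 is None else f"{m.r2:.4f}"
            lines.append(f"{nm:<16}{r2:>8}{m.mae:>8.4f}{m.rmse:>8.4f}")
        lines.append(f"best: {self.winner}")
        return "\n".join(lines)


def compare_models(table: DesignTable, models: dict) -> ComparisonReport:
    """Rank surrogates by full-table R².

    Parameters
    ----------
    table : DesignTable
    models : dict
        Maps model name to either an object with a ``predict(points)``
        method or a precomputed length-n prediction vector.
    """
    y = table.yields
    entries = []
    for name, model in models.items():
        pred = model if isinstance(model, (np.ndarray, list, tuple)) \
            else model.predict(table.factors)
        entries.append((name, metrics(y, pred)))
    entries.sort(key=lambda e: -np.inf if e[1].r2 is None else e[1].r2, reverse=True)
    return ComparisonReport(entries)


def paired_error_test(actual, pred_a, pred_b):
    """Optional paired t-test on absolute errors of two prediction vectors.

    Returns ``(t, p)``; a significantly negative ``t`` means model A's
    absolute errors are smaller.
    """
    ea = np.abs(np.asarray(actual) - np.asarray(pred_a))
    eb = np.abs(np.asarray(actual) - np.asarray(pred_b))
    t, p = stats.ttest_rel(ea, eb)
    return float(t), float(p)
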