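"""Full quadratic response-surface fit and its analysis of variance.

The model is the 15-term second-order polynomial conventional in response
surface methodology,

    y = b0 + Σ bi·xi + Σ bij·xi·xj + Σ bii·xi²   (i < j over 4 factors),

fitted by ordinary least squares either on coded (−1/0/+1) or actual factor
units; the fitted surface is identical under both codings.  The ANOVA
partitions the total sum of squares into the model, per-term partial
(Type-III) contributions, lack of fit, and pure error from replicated
runs, and reports the R² family, PRESS, and the coefficient of variation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .data_io import DesignTable
from .doe import FactorDomain, encode
from .errors import DegenerateLeverageError, SingularDesignError

__all__ = [
    "TERM_NAMES",
    "QuadraticModel",
    "AnovaRow",
    "AnovaReport",
    "fit_quadratic",
    "predict",
    "anova",
    "press",
]

#: Conventional RSM letters for the four factors, in table-column order:
#: A = liquid-to-solid ratio, B = temperature, C = time, D = power.
FACTOR_LETTERS = ("A", "B", "C", "D")
_PAIRS = list(itertools.combinations(range(4), 2))
TERM_NAMES = (
    list(FACTOR_LETTERS)
    + [FACTOR_LETTERS[a] + FACTOR_LETTERS[b] for a, b in _PAIRS]
    + [letter + "2" for letter in FACTOR_LETTERS]
)


def quadratic_design_matrix(x: np.ndarray) -> np.ndarray:
    """(n, 15) model matrix: intercept, 4 linear, 6 interaction, 4 quadratic."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    cols = [np.ones(len(x))]
    cols += [x[:, j] for j in range(4)]
    cols += [x[:, a] * x[:, b] for a, b in _PAIRS]
    cols += [x[:, j] ** 2 for j in range(4)]
    return np.column_stack(cols)


@dataclass
class QuadraticModel:
    """Fitted 15-coefficient response-surface polynomial."""

    intercept: float
    coefficients: np.ndarray  # 14 values ordered as TERM_NAMES
    coding: str  # "coded" | "actual"
    domains: tuple
    fitted: Optional[np.ndarray] = None
    residuals: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (14,):
            raise ValueError(
                f"expected 14 non-intercept coefficients, got {self.coefficients.shape}"
            )
        if self.coding not in ("coded", "actual"):
            raise ValueError(f"coding must be 'coded' or 'actual', got {self.coding!r}")

    @property
    def beta(self) -> np.ndarray:
        return np.concatenate([[self.intercept], self.coefficients])

    def predict(self, points) -> np.ndarray:
        return predict(self, points)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": dict(zip(TERM_NAMES, self.coefficients.tolist())),
            "coding": self.coding,
            "domains": [
                {"name": d.name, "unit": d.unit, "low": d.low, "mid": d.mid, "high": d.high}
                for d in self.domains
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "QuadraticModel":
        domains = tuple(
            FactorDomain(d["name"], d["unit"], d["low"], d["mid"], d["high"])
            for d in payload["domains"]
        )
        coefs = np.array([payload["coefficients"][t] for t in TERM_NAMES])
        return cls(payload["intercept"], coefs, payload["coding"], domains)


def fit_quadratic(design: DesignTable, coding: str = "coded") -> QuadraticModel:
    """Ordinary-least-squares fit of the full quadratic model.

    Parameters
    ----------
    design : DesignTable
        Runs with observed yields; needs at least 16 distinct-point runs so
        the 15 parameters leave a residual degree of freedom.
    coding : {"coded", "actual"}
        Factor units the stored coefficients refer to.  Predictions are
        identical either way.
    """
    y = design.yields
    if np.isnan(y).any():
        raise ValueError("design table has missing yields")
    x = design.coded if coding == "coded" else design.factors
    M = quadratic_design_matrix(x)
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise SingularDesignError(
            f"model matrix is rank deficient (rank {np.linalg.matrix_rank(M)} < 15)"
        )
    res = sm.OLS(y, M).fit()
    model = QuadraticModel(
        intercept=float(res.params[0]),
        coefficients=res.params[1:],
        coding=coding,
        domains=design.domains,
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
    )
    model._sm_result = res
    return model


def predict(model: QuadraticModel, points) -> np.ndarray:
    """Evaluate the polynomial at points given in ACTUAL factor units.

    A single length-4 point returns a scalar; an (n, 4) array returns a
    length-n vector.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    x = encode(pts, model.domains) if model.coding == "coded" else pts
    out = quadratic_design_matrix(x) @ model.beta
    return float(out[0]) if single else out


@dataclass
class AnovaRow:
    source: str
    ss: float
    df: int
    ms: Optional[float] = None
    f: Optional[float] = None
    p: Optional[float] = None


@dataclass
class AnovaReport:
    """Table of per-source SS/df/MS/F/p plus summary statistics."""

    rows: list
    r2: float
    adj_r2: float
    pred_r2: float
    cv_pct: float
    press: float

    def row(self, source: str) -> AnovaRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(f"no ANOVA row {source!r}")

    def to_dict(self) -> dict:
        return {
            "rows": [
                {"source": r.source, "ss": r.ss, "df": r.df, "ms": r.ms, "f": r.f, "p": r.p}
                for r in self.rows
            ],
            "r2": self.r2, "adj_r2": self.adj_r2, "pred_r2": self.pred_r2,
            "cv_pct": self.cv_pct, "press": self.press,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "AnovaReport":
        rows = [AnovaRow(**r) for r in payload["rows"]]
        return cls(rows, payload["r2"], payload["adj_r2"], payload["pred_r2"],
                   payload["cv_pct"], payload["press"])

    def to_text(self) -> str:
        def fmt_p(p):
            if p is None:
                return ""
            return "< 0.0001" if p < 1e-4 else f"{p:.4f}"

        lines = [f"{'Source':<14}{'SS':>10}{'df':>4}{'MS':>10}{'F':>10}  p-value"]
        for r in self.rows:
            ms = f"{r.ms:.4g}" if r.ms is not None else ""
            f = f"{r.f:.4g}" if r.f is not None else ""
            lines.append(f"{r.source:<14}{r.ss:>10.4g}{r.df:>4}{ms:>10}{f:>10}  {fmt_p(r.p)}")
        lines.append("")
        lines.append(f"R2 = {self.r2:.4f}   adjusted R2 = {self.adj_r2:.4f}   "
                     f"predicted R2 = {self.pred_r2:.4f}")
        lines.append(f"C.V.% = {self.cv_pct:.2f}   PRESS = {self.press:.4f}")
        return "\n".join(lines)


def _term_ss(M: np.ndarray, y: np.ndarray, ss_res_full: float, method: str) -> np.ndarray:
    """Per-term 1-df sums of squares for the 14 non-intercept terms."""
    k = M.shape[1]
    out = np.empty(k - 1)
    if method == "type3":
        # extra SS from dropping each term out of the full model
        for i in range(1, k):
            keep = [j for j in range(k) if j != i]
            r = sm.OLS(y, M[:, keep]).fit()
            out[i - 1] = r.ssr - ss_res_full
    elif method == "type1":
        # sequential SS in TERM_NAMES order
        prev_ssr = sm.OLS(y, M[:, :1]).fit().ssr
        for i in range(1, k):
            r = sm.OLS(y, M[:, : i + 1]).fit()
            out[i - 1] = prev_ssr - r.ssr
            prev_ssr = r.ssr
    else:
        raise ValueError(f"unknown SS method {method!r}")
    return out


def anova(model: QuadraticModel, design: DesignTable, ss_method: str = "type3") -> AnovaReport:
    """Full response-surface ANOVA on orthogonally coded factors.

    Per-term sums of squares are partial (Type-III, drop-one-term) by
    default, matching the convention of standard RSM software; sequential
    Type-I is available via ``ss_method="type1"`` (the two coincide for the
    mutually orthogonal linear and interaction columns of a BBD and differ
    slightly for the quadratic terms).

    Lack of fit is separated from pure error using replicated design
    points.  With no replicates the pure-error row is absent and lack of
    fit equals the residual.
    """
    y = design.yields
    z = design.coded
    M = quadratic_design_matrix(z)
    full = sm.OLS(y, M).fit()
    n = len(y)
    df_model, df_res = 14, n - 15
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(full.ssr)
    ss_model = ss_tot - ss_res
    ms_model, ms_res = ss_model / df_model, ss_res / df_res
    f_model = ms_model / ms_res
    rows = [AnovaRow("Model", ss_model, df_model, ms_model, f_model,
                     float(stats.f.sf(f_model, df_model, df_res)))]
    for name, ss in zip(TERM_NAMES, _term_ss(M, y, ss_res, ss_method)):
        f = (ss / 1.0) / ms_res
        rows.append(AnovaRow(name, float(ss), 1, float(ss), float(f),
                             float(stats.f.sf(f, 1, df_res))))
    rows.append(AnovaRow("Residual", ss_res, df_res, ms_res))

    # pure error from exact replicates of the factor settings
    _, inverse = np.unique(design.factors, axis=0, return_inverse=True)
    ss_pure, df_pure = 0.0, 0
    for g in np.unique(inverse):
        yg = y[inverse == g]
        if len(yg) > 1:
            ss_pure += float(((yg - yg.mean()) ** 2).sum())
            df_pure += len(yg) - 1
    if df_pure > 0:
        ss_lof = ss_res - ss_pure
        df_lof = df_res - df_pure
        ms_lof, ms_pure = ss_lof / df_lof, ss_pure / df_pure
        f_lof = ms_lof / ms_pure
        rows.append(AnovaRow("Lack of Fit", ss_lof, df_lof, ms_lof, f_lof,
                             float(stats.f.sf(f_lof, df_lof, df_pure))))
        rows.append(AnovaRow("Pure Error", ss_pure, df_pure, ms_pure))
    else:
        rows.append(AnovaRow("Lack of Fit", ss_res, df_res, ms_res))
    rows.append(AnovaRow("Cor Total", ss_tot, n - 1))

    try:
        press_val = press(model, design)
        pred_r2 = 1.0 - press_val / ss_tot
    except DegenerateLeverageError:
        press_val, pred_r2 = np.nan, np.nan  # a leverage of 1: LOO undefined
    r2 = 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (ss_res / df_res) / (ss_tot / (n - 1))
    cv_pct = 100.0 * np.sqrt(ms_res) / y.mean()
    return AnovaReport(rows, float(r2), float(adj_r2), float(pred_r2),
                       float(cv_pct), float(press_val))


def press(model: QuadraticModel, design: DesignTable) -> float:
    """Leave-one-out prediction error sum of squares.

    Uses the OLS hat-matrix identity e_{(i)} = e_i / (1 − h_ii), which
    equals the explicit n-refit leave-one-out computation exactly.
    """
    y = design.yields
    x = design.coded if model.coding == "coded" else design.factors
    M = quadratic_design_matrix(x)
    res = sm.OLS(y, M).fit()
    h = res.get_influence().hat_matrix_diag
    if np.any(h >= 1.0 - 1e-12):
        raise DegenerateLeverageError("a leverage of 1 makes PRESS undefined")
    e = np.asarray(res.resid)
    return float(((e / (1.0 - h)) ** 2).sum())
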