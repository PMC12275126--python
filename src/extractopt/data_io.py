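"""Design-table I/O, yield arithmetic, and the packaged 29-run dataset.

The central container is :class:`DesignTable`: an ordered collection of
extraction runs, each with four factor settings (liquid-to-solid ratio in
mL/g, temperature in °C, time in min, ultrasonic power in W) and the
observed polysaccharide yield in percent.  Yield itself is mass of
polysaccharide recovered per mass of dry plant material:

    yield(%) = 100 · concentration (g/mL) · volume (mL) / material mass (g)
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .doe import PAPER_DOMAINS, FactorDomain, encode
from .errors import ParseError

__all__ = [
    "AssayReading",
    "RunRecord",
    "DesignTable",
    "yield_from_assay",
    "load_design_csv",
    "paper_fixture",
    "write_report",
    "FACTOR_COLUMNS",
]

FACTOR_COLUMNS = ("ratio_ml_per_g", "temperature_c", "time_min", "power_w")
YIELD_COLUMN = "yield_pct"


@dataclass(frozen=True)
class AssayReading:
    """One phenol-sulfuric assay readout used to compute extraction yield."""

    concentration: float  # polysaccharide concentration, g/mL
    volume: float  # extract volume, mL
    material_mass: float  # dry plant mass, g

    def __post_init__(self):
        for name in ("concentration", "volume", "material_mass"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v}")


@dataclass(frozen=True)
class RunRecord:
    """One extraction run of the design table."""

    run_id: int
    ratio: float  # mL/g
    temperature: float  # degC
    time: float  # min
    power: float  # W
    yield_pct: Optional[float] = None

    def __post_init__(self):
        if self.run_id <= 0:
            raise ValueError(f"run_id must be positive, got {self.run_id}")
        for name in ("ratio", "temperature", "time", "power"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.yield_pct is not None and not (0.0 < self.yield_pct < 100.0):
            raise ValueError(f"yield_pct must lie in (0, 100), got {self.yield_pct}")

    @property
    def factors(self) -> tuple:
        return (self.ratio, self.temperature, self.time, self.power)


def yield_from_assay(reading: AssayReading) -> float:
    """Polysaccharide yield in percent from one assay reading."""
    return 100.0 * reading.concentration * reading.volume / reading.material_mass


class DesignTable:
    """Ordered collection of extraction runs plus the factor domains.

    Internally a :class:`pandas.DataFrame` with columns
    ``run, ratio_ml_per_g, temperature_c, time_min, power_w, yield_pct``
    and, optionally, auxiliary prediction columns carried along untouched.
    """

    def __init__(self, frame: pd.DataFrame, domains: Sequence[FactorDomain] = PAPER_DOMAINS,
                 is_bbd: bool = False):
        frame = frame.reset_index(drop=True)
        if frame["run"].duplicated().any():
            dup = int(frame["run"][frame["run"].duplicated()].iloc[0])
            raise ParseError(f"duplicate run_id {dup}")
        self._frame = frame
        self.domains = tuple(domains)
        if is_bbd:
            self._check_bbd_levels()

    def _check_bbd_levels(self):
        for col, dom in zip(FACTOR_COLUMNS, self.domains):
            bad = ~self._frame[col].isin(dom.levels)
            if bad.any():
                row = int(self._frame.index[bad][0]) + 1
                raise ParseError(
                    f"row {row}, column {col!r}: value "
                    f"{self._frame[col][bad].iloc[0]} is not a design level of "
                    f"{dom.name} {dom.levels}"
                )

    # -- construction -----------------------------------------------------

    @classmethod
    def from_arrays(cls, factors, yields=None, domains=PAPER_DOMAINS, run_ids=None):
        factors = np.asarray(factors, dtype=float)
        n = len(factors)
        data = {"run": np.asarray(run_ids) if run_ids is not None else np.arange(1, n + 1)}
        for j, col in enumerate(FACTOR_COLUMNS):
            data[col] = factors[:, j]
        data[YIELD_COLUMN] = np.full(n, np.nan) if yields is None else np.asarray(yields, float)
        return cls(pd.DataFrame(data), domains=domains)

    @classmethod
    def from_records(cls, records: Sequence[RunRecord], domains=PAPER_DOMAINS):
        rows = [
            {"run": r.run_id, "ratio_ml_per_g": r.ratio, "temperature_c": r.temperature,
             "time_min": r.time, "power_w": r.power,
             YIELD_COLUMN: np.nan if r.yield_pct is None else r.yield_pct}
            for r in records
        ]
        return cls(pd.DataFrame(rows), domains=domains)

    # -- access -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self._frame)

    def __getitem__(self, i: int) -> RunRecord:
        row = self._frame.iloc[i]
        y = row[YIELD_COLUMN]
        return RunRecord(
            run_id=int(row["run"]), ratio=row["ratio_ml_per_g"],
            temperature=row["temperature_c"], time=row["time_min"],
            power=row["power_w"], yield_pct=None if pd.isna(y) else float(y),
        )

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def factors(self) -> np.ndarray:
        """(n, 4) array of actual factor settings."""
        return self._frame[list(FACTOR_COLUMNS)].to_numpy(dtype=float)

    @property
    def coded(self) -> np.ndarray:
        """(n, 4) array of coded factor settings."""
        return encode(self.factors, self.domains)

    @property
    def yields(self) -> np.ndarray:
        return self._frame[YIELD_COLUMN].to_numpy(dtype=float)

    def aux_column(self, name: str) -> np.ndarray:
        """An auxiliary (e.g. printed-prediction) column carried by the table."""
        if name not in self._frame.columns:
            raise KeyError(f"no column {name!r} in table")
        return self._frame[name].to_numpy(dtype=float)

    def subset(self, indices) -> "DesignTable":
        return DesignTable(self._frame.iloc[np.asarray(indices)], domains=self.domains)

    def with_yields(self, yields) -> "DesignTable":
        frame = self._frame.copy()
        frame[YIELD_COLUMN] = np.asarray(yields, dtype=float)
        return DesignTable(frame, domains=self.domains)

    def center_mask(self) -> np.ndarray:
        """Boolean mask of runs sitting at the all-mid (center) point."""
        return np.all(self.coded == 0.0, axis=1)

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, path) -> None:
        self._frame.to_csv(path, index=False)


_REQUIRED = ("run",) + FACTOR_COLUMNS + (YIELD_COLUMN,)


def load_design_csv(path, column_map: Optional[Mapping[str, str]] = None,
                    domains: Sequence[FactorDomain] = PAPER_DOMAINS) -> DesignTable:
    """Read a design table from CSV.

    Parameters
    ----------
    path : path-like
    column_map : mapping, optional
        Maps canonical column names (``run``, ``ratio_ml_per_g``,
        ``temperature_c``, ``time_min``, ``power_w``, ``yield_pct``) to the
        file's actual header names.
    """
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    column_map = dict(column_map or {})
    rename = {column_map.get(c, c): c for c in _REQUIRED}
    raw = raw.rename(columns=rename)
    missing = [c for c in _REQUIRED if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for col in _REQUIRED:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            row = int(raw.index[bad][0]) + 1
            raise ParseError(
                f"{path}: row {row}, column {col!r}: non-numeric value "
                f"{raw[col][bad].iloc[0]!r}"
            )
        raw[col] = coerced
    return DesignTable(raw, domains=domains)


def paper_fixture() -> DesignTable:
    """The packaged 29-run ultrasonic-extraction BBD dataset.

    Factors were assigned to the printed columns by matching each column's
    value set to the stated design levels — ratio {20,25,30} mL/g,
    temperature {80,90,100} °C, time {60,75,90} min, power {250,300,350} W —
    because the printed column headers contradict the values they hold and
    the level sets are disjoint, making the assignment unambiguous.  Yields
    are stored exactly as printed (2 decimals).  The three printed
    prediction columns are carried as opaque auxiliary vectors
    (``pred_rsm``, ``pred_bp``, ``pred_gaaco_bp``).
    """
    ref = importlib.resources.files("extractopt.data") / "thd_ultrasonic_bbd.csv"
    with importlib.resources.as_file(ref) as p:
        frame = pd.read_csv(p)
    return DesignTable(frame, domains=PAPER_DOMAINS, is_bbd=True)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_report(report, path, format: str = "json") -> None:
    """Serialize a report object (AnovaReport, FitMetrics, OptimumResult, ...).

    ``format="json"`` writes a lossless machine-readable rendering (objects
    exposing ``to_dict`` round-trip through their ``from_dict``);
    ``format="text"`` writes the object's aligned-text rendering
    (``to_text`` if present, else ``str``).
    """
    if format == "json":
        payload = report.to_dict() if hasattr(report, "to_dict") else _to_jsonable(report)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    elif format == "text":
        text = report.to_text() if hasattr(report, "to_text") else str(report)
        with open(path, "w") as fh:
            fh.write(text if text.endswith("\n") else text + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
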