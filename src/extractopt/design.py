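"""Central composite designs with coded factors.

An extraction variable is described by its value at the design centre
(``center``, actual units) and the change in actual units that corresponds
to one coded unit (``step``).  Coding maps an actual value ``z`` to the
dimensionless ``x = (z - center) / step``, so the design is centred at 0
with unit spacing between factorial levels.

A four-factor rotatable central composite design (CCD) consists of a
2^4 full factorial block (coded levels ±1), 2·4 axial points at distance
``alpha`` on each axis, and replicated centre points.  With 16 factorial
points the rotatable axial distance is 16^(1/4) = 2, which is the design
used throughout this package.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FactorDefinition",
    "DesignPoint",
    "DesignMatrix",
    "code_value",
    "decode_value",
    "build_ccd",
    "load_experiment_table",
    "load_factor_config",
    "center_point_stats",
    "InsufficientReplicationError",
    "TableParseError",
    "UnsupportedDesignError",
]

N_FACTORS = 4


class UnsupportedDesignError(ValueError):
    """Raised for factor counts the CCD builder does not support."""


class TableParseError(ValueError):
    """Raised when an experiment table cannot be validated."""


class InsufficientReplicationError(ValueError):
    """Raised when too few centre replicates exist for a pure-error estimate."""


@dataclass(frozen=True)
class FactorDefinition:
    """One extraction variable and its coding.

    Parameters
    ----------
    name, unit:
        Human-readable identification (e.g. ``"ammonia concentration"``, ``"%"``).
    center:
        Actual value at the design centre (coded 0).
    step:
        Actual-unit change per coded unit; must be positive.
    coded_min, coded_max:
        Admissible coded range; the standard rotatable four-factor CCD
        spans exactly [-2, 2].
    """

    name: str
    unit: str
    center: float
    step: float
    coded_min: float = -2.0
    coded_max: float = 2.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.center) or not np.isfinite(self.step):
            raise ValueError(f"factor {self.name!r}: center and step must be finite")
        if self.step <= 0:
            raise ValueError(f"factor {self.name!r}: step must be > 0, got {self.step}")
        if not self.coded_min < self.coded_max:
            raise ValueError(f"factor {self.name!r}: coded_min must be < coded_max")

    @property
    def actual_min(self) -> float:
        return self.center + self.coded_min * self.step

    @property
    def actual_max(self) -> float:
        return self.center + self.coded_max * self.step


def code_value(z: float, factor: FactorDefinition) -> float:
    """Map an actual value to coded units: ``(z - center) / step``."""
    if not np.isfinite(z):
        raise ValueError(f"cannot code non-finite value {z!r}")
    return (z - factor.center) / factor.step


def decode_value(x: float, factor: FactorDefinition) -> float:
    """Map a coded value back to actual units: ``center + x * step``."""
    return factor.center + x * factor.step


@dataclass(frozen=True)
class DesignPoint:
    """A single experimental run: coded settings, actual settings, response."""

    run_id: int
    coded: tuple[float, ...]
    actual: tuple[float, ...]
    response: float | None = None
    kind: str = "other"  # factorial | axial | center | other

    def __post_init__(self) -> None:
        if self.response is not None:
            if not np.isfinite(self.response) or self.response <= 0:
                raise ValueError(
                    f"run {self.run_id}: response must be finite and > 0, "
                    f"got {self.response}"
                )


def _classify(coded: Sequence[float]) -> str:
    arr = np.asarray(coded, dtype=float)
    if np.all(arr == 0):
        return "center"
    if np.all(np.abs(arr) == 1):
        return "factorial"
    nonzero = arr[arr != 0]
    if len(nonzero) == 1:
        return "axial"
    return "other"


@dataclass
class DesignMatrix:
    """An ordered collection of design points over a fixed set of factors."""

    factors: tuple[FactorDefinition, ...]
    points: list[DesignPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        k = len(self.factors)
        for p in self.points:
            if len(p.coded) != k or len(p.actual) != k:
                raise ValueError(f"run {p.run_id}: expected {k} factor settings")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def coded(self) -> np.ndarray:
        """Coded settings as an (n_runs, n_factors) array."""
        return np.array([p.coded for p in self.points], dtype=float)

    @property
    def responses(self) -> np.ndarray:
        """Responses as a float array; missing responses become NaN."""
        return np.array(
            [np.nan if p.response is None else p.response for p in self.points]
        )

    @property
    def has_responses(self) -> bool:
        return all(p.response is not None for p in self.points)

    def center_points(self) -> list[DesignPoint]:
        return [p for p in self.points if p.kind == "center"]

    def with_responses(self, values: Iterable[float]) -> "DesignMatrix":
        values = list(values)
        if len(values) != len(self.points):
            raise ValueError("response vector length does not match run count")
        pts = [replace(p, response=float(v)) for p, v in zip(self.points, values)]
        return DesignMatrix(self.factors, pts)

    def to_frame(self, include_actual: bool = False) -> pd.DataFrame:
        cols: dict[str, list] = {"run": [p.run_id for p in self.points]}
        for j in range(len(self.factors)):
            cols[f"x{j + 1}"] = [p.coded[j] for p in self.points]
        if include_actual:
            for j in range(len(self.factors)):
                cols[f"z{j + 1}"] = [p.actual[j] for p in self.points]
        cols["response"] = [p.response for p in self.points]
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path, include_actual: bool = False) -> None:
        self.to_frame(include_actual=include_actual).to_csv(path, index=False)


def build_ccd(
    factors: Sequence[FactorDefinition],
    axial_distance: float = 2.0,
    n_center: int = 6,
) -> DesignMatrix:
    """Build a four-factor central composite design.

    Runs are emitted in a fixed canonical order so the output is
    bit-reproducible: the 16 factorial points in binary-counter order
    (first factor most significant, -1 before +1), then axial pairs by
    factor index (-alpha before +alpha), then the centre replicates.
    """
    factors = tuple(factors)
    if len(factors) != N_FACTORS:
        raise UnsupportedDesignError(
            f"only {N_FACTORS}-factor designs are supported, got {len(factors)} "
            "(generalisation to k factors is a documented extension point)"
        )
    if axial_distance <= 0:
        raise ValueError("axial_distance must be > 0")
    if n_center < 1:
        raise ValueError("n_center must be >= 1")

    rows: list[tuple[float, ...]] = []
    for combo in itertools.product((-1.0, 1.0), repeat=N_FACTORS):
        rows.append(combo)
    for j in range(N_FACTORS):
        for sign in (-1.0, 1.0):
            point = [0.0] * N_FACTORS
            point[j] = sign * axial_distance
            rows.append(tuple(point))
    rows.extend([(0.0,) * N_FACTORS] * n_center)

    points = []
    for i, coded in enumerate(rows, start=1):
        actual = tuple(decode_value(x, f) for x, f in zip(coded, factors))
        points.append(
            DesignPoint(run_id=i, coded=coded, actual=actual, kind=_classify(coded))
        )
    return DesignMatrix(factors, points)


def load_factor_config(path: str | Path) -> tuple[FactorDefinition, ...]:
    """Load factor definitions from a YAML or JSON file.

    The file holds a list of mappings with keys ``name``, ``unit``,
    ``center``, ``step`` and optionally ``coded_min`` / ``coded_max``.
    """
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, list):
        raise TableParseError("factor config must be a list of factor mappings")
    return tuple(FactorDefinition(**entry) for entry in data)


def load_experiment_table(
    source: str | Path | pd.DataFrame,
    factors: Sequence[FactorDefinition] | None = None,
) -> DesignMatrix:
    """Load and validate an experiment table.

    Accepts a CSV path (header ``run,x1..x4,response``; optional actual-unit
    columns ``z1..z4`` may replace the coded ones when ``factors`` is given)
    or an equivalent DataFrame.  Rows with coded values outside each
    factor's coded range, duplicate run ids, or non-numeric cells are
    rejected with an error naming the offending row.
    """
    if isinstance(source, pd.DataFrame):
        frame = source.copy()
    else:
        path = Path(source)
        try:
            frame = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise TableParseError(f"{path}: empty table") from exc
    if frame.empty:
        raise TableParseError("empty table")

    coded_cols = [f"x{j + 1}" for j in range(N_FACTORS)]
    actual_cols = [f"z{j + 1}" for j in range(N_FACTORS)]
    has_coded = all(c in frame.columns for c in coded_cols)
    has_actual = all(c in frame.columns for c in actual_cols)
    if "run" not in frame.columns:
        raise TableParseError("missing required column 'run'")
    if not has_coded and not has_actual:
        raise TableParseError(f"missing factor columns {coded_cols} (or {actual_cols})")
    if has_actual and not has_coded and factors is None:
        raise TableParseError("actual-unit columns require factor definitions")

    if factors is None:
        # Generic placeholder factors: coding is the identity on each axis.
        factors = tuple(
            FactorDefinition(name=f"x{j + 1}", unit="", center=0.0, step=1.0)
            for j in range(N_FACTORS)
        )
    factors = tuple(factors)

    run_ids = frame["run"]
    if run_ids.duplicated().any():
        dup = run_ids[run_ids.duplicated()].iloc[0]
        raise TableParseError(f"duplicate run id {dup!r}")

    numeric_cols = coded_cols if has_coded else actual_cols
    check_cols = list(numeric_cols) + (["response"] if "response" in frame else [])
    for col in check_cols:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = frame.index[bad][0]
            raise TableParseError(f"non-numeric value in column {col!r}, row {row}")
        frame[col] = converted

    points = []
    for idx, row in frame.iterrows():
        if has_coded:
            coded = tuple(float(row[c]) for c in coded_cols)
        else:
            coded = tuple(
                code_value(float(row[c]), f) for c, f in zip(actual_cols, factors)
            )
        for x, f in zip(coded, factors):
            if not (f.coded_min - 1e-9 <= x <= f.coded_max + 1e-9):
                raise TableParseError(
                    f"row {idx}: coded value {x} for {f.name!r} outside "
                    f"[{f.coded_min}, {f.coded_max}]"
                )
        actual = tuple(decode_value(x, f) for x, f in zip(coded, factors))
        resp = row.get("response")
        response = None if resp is None or pd.isna(resp) else float(resp)
        points.append(
            DesignPoint(
                run_id=int(row["run"]),
                coded=coded,
                actual=actual,
                response=response,
                kind=_classify(coded),
            )
        )
    return DesignMatrix(factors, points)


def center_point_stats(design: DesignMatrix) -> tuple[float, float]:
    """Mean and relative standard deviation of the centre-point responses.

    The RSD is ``100 * sd / mean`` with the sample (n-1) standard
    deviation; at least two replicated centre runs with responses are
    required.
    """
    values = np.array(
        [p.response for p in design.center_points() if p.response is not None]
    )
    if len(values) < 2:
        raise InsufficientReplicationError(
            f"need >= 2 centre replicates with responses, found {len(values)}"
        )
    mean = float(values.mean())
    rsd = float(100.0 * values.std(ddof=1) / mean)
    return mean, rsd
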