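"""Search the coded design space over a fitted surrogate and decode the optimum.

Any callable mapping a coded 4-vector to a predicted response (quadratic
surface or network forward pass) can be maximized with the genetic
algorithm over the coded box, which defaults to [-2, 2]^4 — the full
physical factor ranges in coded units.  For quadratic surrogates an exact
box-constrained maximizer is available by KKT enumeration and doubles as
the GA's correctness oracle.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .design import FactorDefinition, decode_value
from .ga import EvolutionHistory, GAConfig, evolve
from .rsm import TERM_NAMES, QuadraticModel

__all__ = [
    "OptimizationResult",
    "optimize_conditions",
    "quadratic_optimum_closed_form",
    "comparison_report",
]


def _projected_gradient_polish(
    f: Callable[[np.ndarray], float],
    x: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    steps: int = 15,
    h: float = 1e-5,
) -> np.ndarray:
    """Deterministic local ascent: central-difference gradient direction with
    backtracking line search, iterates projected onto the box.

    Used as the GA's lamarckian refinement during condition search, so each
    individual settles into its own basin's exact box-constrained optimum
    and the evolutionary competition compares basins at full precision.
    """
    x = x.copy()
    fx = f(x)
    t = 0.25 * float(np.max(upper - lower))
    eye = np.eye(len(x))
    for _ in range(steps):
        grad = np.array(
            [
                (f(np.clip(x + h * e, lower, upper)) - f(np.clip(x - h * e, lower, upper)))
                / (2 * h)
                for e in eye
            ]
        )
        norm = float(np.linalg.norm(grad))
        if norm < 1e-10 or t < 1e-8:
            break
        direction = grad / norm
        improved = False
        trial = t
        for _ in range(12):
            candidate = np.clip(x + trial * direction, lower, upper)
            fc = f(candidate)
            if fc > fx + 1e-12:
                x, fx, t = candidate, fc, trial * 2.0
                improved = True
                break
            trial /= 2.0
        if not improved:
            t = trial
    return x


@dataclass
class OptimizationResult:
    """Best coded point found, its decoded actual conditions, and GA history."""

    surrogate_kind: str  # rsm | bpnn | ga_bpnn | other
    best_coded: np.ndarray
    best_actual: dict[str, float]
    predicted_response: float
    history: EvolutionHistory | None = None

    def summary(self) -> str:
        parts = [f"[{self.surrogate_kind}] predicted {self.predicted_response:.4f} mg at"]
        coded = ", ".join(f"{v:.2f}" for v in self.best_coded)
        parts.append(f"  coded ({coded})")
        for name, value in self.best_actual.items():
            parts.append(f"  {name}: {value:g}")
        return "\n".join(parts)


def optimize_conditions(
    predict_fn: Callable[[np.ndarray], float],
    factors: Sequence[FactorDefinition],
    ga_config: GAConfig | None = None,
    bounds: Sequence[tuple[float, float]] | None = None,
    surrogate_kind: str = "other",
    clamped_warning: bool = False,
    polish_steps: int = 15,
) -> OptimizationResult:
    """Maximize ``predict_fn`` over the coded box and decode the optimum.

    The search is a memetic GA: every individual is locally refined by a
    short projected-gradient ascent (``polish_steps`` iterations; 0
    disables it for a pure-GA search) before fitness evaluation.  The
    response surfaces here have competing near-equal optima at opposite
    corners of interaction terms, and the lamarckian polish lets the fixed
    GA budget discriminate between such basins at full precision.

    ``bounds`` defaults to each factor's (coded_min, coded_max).  Set
    ``clamped_warning`` when the surrogate is a tanh-output network, whose
    predictions saturate at the training-range endpoints.
    """
    factors = tuple(factors)
    if bounds is None:
        bounds = [(f.coded_min, f.coded_max) for f in factors]
    if clamped_warning:
        warnings.warn(
            "tanh-output surrogate: predictions are clamped to the training "
            "response range",
            stacklevel=2,
        )
    config = ga_config or GAConfig()
    if not config.maximize:
        raise ValueError("condition search maximizes the response")
    lower = np.array([b[0] for b in bounds], dtype=float)
    upper = np.array([b[1] for b in bounds], dtype=float)
    refine = None
    if polish_steps > 0:
        refine = lambda g: _projected_gradient_polish(  # noqa: E731
            lambda x: float(predict_fn(x)), g, lower, upper, polish_steps
        )
    best, history = evolve(
        lambda g: float(predict_fn(g)), bounds, config, refine=refine
    )
    actual = {
        f.name: decode_value(x, f) for x, f in zip(best.genome, factors)
    }
    return OptimizationResult(
        surrogate_kind=surrogate_kind,
        best_coded=best.genome.copy(),
        best_actual=actual,
        predicted_response=best.fitness,
        history=history,
    )


def _quadratic_parts(model: QuadraticModel) -> tuple[float, np.ndarray, np.ndarray]:
    """Split active coefficients into constant, linear vector, symmetric matrix Q
    so that y(x) = a0 + c·x + x'Qx."""
    coefs = np.where(model.term_active, model.coefficients, 0.0)
    a0 = coefs[0]
    c = coefs[1:5].copy()
    Q = np.zeros((4, 4))
    pairs = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
    for k, (i, j) in enumerate(pairs):
        Q[i, j] = Q[j, i] = coefs[5 + k] / 2.0
    for j in range(4):
        Q[j, j] = coefs[11 + j]
    return float(a0), c, Q


def quadratic_optimum_closed_form(
    model: QuadraticModel,
    bounds: Sequence[tuple[float, float]] | None = None,
) -> tuple[np.ndarray, float]:
    """Exact box-constrained maximum of a quadratic by KKT enumeration.

    At a box-constrained maximum of a quadratic every coordinate is either
    at a bound or has zero partial derivative, so enumerating all 3^4
    assignments of {lower, upper, free} per coordinate and solving the
    stationary system on each free set visits every candidate.  The box is
    compact, so a maximum always exists.
    """
    if bounds is None:
        bounds = [(-2.0, 2.0)] * 4
    lower = np.array([b[0] for b in bounds], dtype=float)
    upper = np.array([b[1] for b in bounds], dtype=float)
    a0, c, Q = _quadratic_parts(model)

    def value(x: np.ndarray) -> float:
        return a0 + c @ x + x @ Q @ x

    best_x: np.ndarray | None = None
    best_v = -np.inf
    for pattern in itertools.product((0, 1, 2), repeat=4):
        free = [j for j, p in enumerate(pattern) if p == 2]
        x = np.where(np.array(pattern) == 0, lower, upper).astype(float)
        if free:
            fixed = [j for j in range(4) if j not in free]
            # gradient: 2 Q x + c; solve for the free block
            A = 2.0 * Q[np.ix_(free, free)]
            rhs = -(c[free] + 2.0 * Q[np.ix_(free, fixed)] @ x[fixed])
            try:
                x_free = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                continue
            x[free] = x_free
            if np.any(x < lower - 1e-9) or np.any(x > upper + 1e-9):
                continue
            x = np.clip(x, lower, upper)
        v = value(x)
        if v > best_v:
            best_v, best_x = v, x.copy()
    assert best_x is not None
    return best_x, float(best_v)


def comparison_report(
    results: Sequence[OptimizationResult],
    experimental: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Tabulate optima per surrogate with optional validation discrepancies.

    ``experimental`` gives one observed (confirmatory-run) value per
    result; when present, a ``discrepancy = |experimental - predicted|``
    column is added.
    """
    if not results:
        raise ValueError("need at least one optimization result")
    rows = []
    for res in results:
        row: dict[str, float | str] = {"method": res.surrogate_kind}
        for j, v in enumerate(res.best_coded):
            row[f"x{j + 1}"] = float(v)
        for name, v in res.best_actual.items():
            row[name] = float(v)
        row["predicted"] = res.predicted_response
        rows.append(row)
    frame = pd.DataFrame(rows)
    if experimental is not None:
        if len(experimental) != len(results):
            raise ValueError("one experimental value per result required")
        frame["experimental"] = list(experimental)
        frame["discrepancy"] = (frame["experimental"] - frame["predicted"]).abs()
    return frame


def model_predict_fn(model: QuadraticModel) -> Callable[[np.ndarray], float]:
    """Adapter: a quadratic model as a coded-point -> mg callable."""
    return lambda x: float(model.predict(x))
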