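"""Second-order response-surface fitting and ANOVA diagnostics.

The response y is modelled as a full quadratic in the four coded factors,

    y = a0 + sum_i a_i x_i + sum_{i<j} a_ij x_i x_j + sum_i a_ii x_i^2 + eps,

fitted by ordinary least squares (15 terms including the intercept).
Model adequacy is judged with the conventional designed-experiment
diagnostics: an ANOVA with partial (Type-III) per-term sums of squares, a
lack-of-fit test whose pure-error component comes from replicated design
points, the PRESS-based predicted R², and the adequate-precision
signal-to-noise ratio.  Terms whose partial F-test is nonsignificant can
be pruned to obtain a reduced predictive equation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix

__all__ = [
    "TERM_NAMES",
    "QuadraticModel",
    "AnovaTable",
    "expand_quadratic",
    "fit_quadratic",
    "anova",
    "predicted_r_squared",
    "adequate_precision",
    "prune_nonsignificant",
    "render_anova_text",
    "SingularDesignError",
    "UndefinedPressError",
]

# Canonical term ordering of the quadratic basis.
TERM_NAMES: tuple[str, ...] = (
    "intercept",
    "x1", "x2", "x3", "x4",
    "x1:x2", "x1:x3", "x1:x4", "x2:x3", "x2:x4", "x3:x4",
    "x1^2", "x2^2", "x3^2", "x4^2",
)
N_TERMS = len(TERM_NAMES)
_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


class SingularDesignError(ValueError):
    """Raised when the model matrix is rank-deficient on the active terms."""


class UndefinedPressError(ValueError):
    """Raised when a leverage of 1 makes the PRESS statistic undefined."""


def expand_quadratic(coded_point: np.ndarray) -> np.ndarray:
    """Expand coded points into the 15-term quadratic basis.

    Accepts a single 4-vector or an (n, 4) array; returns the matching
    15-vector or (n, 15) matrix ordered as :data:`TERM_NAMES`.
    """
    x = np.asarray(coded_point, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("coded point must be finite")
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != 4:
        raise ValueError(f"expected 4 coded factors, got {x.shape[1]}")
    cols = [np.ones(len(x))]
    cols += [x[:, j] for j in range(4)]
    cols += [x[:, i] * x[:, j] for i, j in _PAIRS]
    cols += [x[:, j] ** 2 for j in range(4)]
    out = np.column_stack(cols)
    return out[0] if single else out


@dataclass
class QuadraticModel:
    """A fitted (or user-supplied) second-order polynomial in coded units.

    ``coefficients`` always holds all 15 entries in :data:`TERM_NAMES`
    order; ``term_active`` masks out pruned terms, whose coefficients are
    simply ignored by :meth:`predict`.
    """

    coefficients: np.ndarray
    term_active: np.ndarray = field(
        default_factory=lambda: np.ones(N_TERMS, dtype=bool)
    )
    residual_sd: float = float("nan")

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.term_active = np.asarray(self.term_active, dtype=bool)
        if self.coefficients.shape != (N_TERMS,):
            raise ValueError(f"expected {N_TERMS} coefficients")
        if self.term_active.shape != (N_TERMS,):
            raise ValueError(f"expected {N_TERMS} term-active flags")

    @property
    def n_active(self) -> int:
        return int(self.term_active.sum())

    @property
    def active_terms(self) -> tuple[str, ...]:
        return tuple(t for t, a in zip(TERM_NAMES, self.term_active) if a)

    def predict(self, coded_point: np.ndarray) -> float | np.ndarray:
        """Evaluate the polynomial (active terms only) at coded points."""
        basis = expand_quadratic(coded_point)
        coefs = np.where(self.term_active, self.coefficients, 0.0)
        out = basis @ coefs
        return float(out) if np.ndim(out) == 0 else out

    @classmethod
    def from_named_coefficients(cls, mapping: dict[str, float]) -> "QuadraticModel":
        """Build a model from a sparse {term name: coefficient} mapping.

        Terms absent from the mapping are marked inactive, so a reduced
        published equation can be entered directly.
        """
        unknown = set(mapping) - set(TERM_NAMES)
        if unknown:
            raise ValueError(f"unknown term names: {sorted(unknown)}")
        coefs = np.zeros(N_TERMS)
        active = np.zeros(N_TERMS, dtype=bool)
        for i, name in enumerate(TERM_NAMES):
            if name in mapping:
                coefs[i] = mapping[name]
                active[i] = True
        return cls(coefficients=coefs, term_active=active)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "terms": list(TERM_NAMES),
            "coefficients": self.coefficients.tolist(),
            "term_active": self.term_active.tolist(),
            "residual_sd": None if np.isnan(self.residual_sd) else self.residual_sd,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "QuadraticModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            coefficients=np.array(payload["coefficients"]),
            term_active=np.array(payload["term_active"], dtype=bool),
            residual_sd=payload.get("residual_sd") or float("nan"),
        )


def _model_matrix(design: DesignMatrix, active: np.ndarray) -> np.ndarray:
    return expand_quadratic(design.coded)[:, active]


def _check_responses(design: DesignMatrix) -> np.ndarray:
    if not design.has_responses:
        raise ValueError("design has runs without responses")
    return design.responses


def fit_quadratic(
    design: DesignMatrix, term_active: np.ndarray | None = None
) -> QuadraticModel:
    """Fit the quadratic surface by ordinary least squares.

    With the default all-active mask this estimates all 15 coefficients;
    a mask restricts the fit to the active terms (used by the
    refit-after-prune mode).
    """
    y = _check_responses(design)
    active = (
        np.ones(N_TERMS, dtype=bool) if term_active is None
        else np.asarray(term_active, dtype=bool)
    )
    X = _model_matrix(design, active)
    if len(y) < X.shape[1]:
        raise SingularDesignError(
            f"{len(y)} runs cannot identify {X.shape[1]} terms"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = [t for t, a in zip(TERM_NAMES, active) if a]
        raise SingularDesignError(
            f"model matrix is rank deficient (rank {rank} < {X.shape[1]}) "
            f"on terms {names}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    coefs = np.zeros(N_TERMS)
    coefs[active] = beta
    resid = y - X @ beta
    df_res = len(y) - X.shape[1]
    residual_sd = float(np.sqrt(resid @ resid / df_res)) if df_res > 0 else 0.0
    return QuadraticModel(coefficients=coefs, term_active=active, residual_sd=residual_sd)


def _rss(design: DesignMatrix, active: np.ndarray, y: np.ndarray) -> float:
    X = _model_matrix(design, active)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


@dataclass
class AnovaTable:
    """Full ANOVA of a fitted quadratic surface.

    ``table`` has one row per active non-intercept term plus the Model,
    Residual, Lack of Fit and Pure Error rows, with columns
    ``ss, df, ms, F, p``.  Summary statistics follow the usual
    designed-experiment definitions.
    """

    table: pd.DataFrame
    r_squared: float
    adj_r_squared: float
    pred_r_squared: float
    adeq_precision: float
    has_lack_of_fit: bool = True

    def row(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def p_values(self) -> pd.Series:
        """p-values of the individual model terms (Model row excluded)."""
        skip = {"Model", "Residual", "Lack of Fit", "Pure Error"}
        return self.table.loc[[i for i in self.table.index if i not in skip], "p"]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "rows": self.table.reset_index()
            .rename(columns={"index": "term"})
            .to_dict(orient="records"),
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "pred_r_squared": self.pred_r_squared,
            "adeq_precision": self.adeq_precision,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def anova(model: QuadraticModel, design: DesignMatrix) -> AnovaTable:
    """ANOVA with partial (Type-III) per-term sums of squares.

    Each term's SS is the increase in residual SS when that term alone is
    dropped from the active set; for the orthogonal columns of a CCD this
    coincides with the sequential decomposition.  Pure error pools the
    within-group variation of replicated coded points; lack of fit is the
    remainder of the residual, with df = (distinct design points) -
    (active model terms).
    """
    y = _check_responses(design)
    n = len(y)
    active = model.term_active
    p = int(active.sum())

    X = _model_matrix(design, active)
    beta = model.coefficients[active]
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    ss_total = float(((y - y.mean()) ** 2).sum())
    ss_model = ss_total - rss
    df_model = p - 1
    df_res = n - p
    ms_model = ss_model / df_model
    ms_res = rss / df_res if df_res > 0 else float("nan")

    rows: dict[str, dict] = {}
    f_model = ms_model / ms_res if ms_res > 0 else float("inf")
    rows["Model"] = {
        "ss": ss_model, "df": df_model, "ms": ms_model,
        "F": f_model,
        "p": float(stats.f.sf(f_model, df_model, df_res)) if np.isfinite(f_model) else 0.0,
    }
    # Full-model RSS refitted on the active set (equals rss when the model
    # was fitted on this same design, but recompute for user-supplied fits).
    rss_full = _rss(design, active, y)
    for i, name in enumerate(TERM_NAMES):
        if name == "intercept" or not active[i]:
            continue
        reduced = active.copy()
        reduced[i] = False
        ss_term = _rss(design, reduced, y) - rss_full
        f_term = (ss_term / 1.0) / ms_res if ms_res > 0 else float("inf")
        rows[name] = {
            "ss": ss_term, "df": 1, "ms": ss_term,
            "F": f_term,
            "p": float(stats.f.sf(f_term, 1, df_res)) if np.isfinite(f_term) else 0.0,
        }
    rows["Residual"] = {
        "ss": rss, "df": df_res, "ms": ms_res, "F": np.nan, "p": np.nan,
    }

    # Pure error from replicated coded points.
    groups: dict[tuple, list[float]] = {}
    for point, resp in zip(design.points, y):
        groups.setdefault(tuple(point.coded), []).append(float(resp))
    ss_pe = 0.0
    df_pe = 0
    for vals in groups.values():
        if len(vals) > 1:
            arr = np.array(vals)
            ss_pe += float(((arr - arr.mean()) ** 2).sum())
            df_pe += len(vals) - 1
    has_lof = df_pe > 0
    if has_lof:
        n_distinct = len(groups)
        ss_lof = rss - ss_pe
        df_lof = n_distinct - p
        ms_pe = ss_pe / df_pe
        ms_lof = ss_lof / df_lof if df_lof > 0 else float("nan")
        if ms_pe > 0 and np.isfinite(ms_lof):
            f_lof = ms_lof / ms_pe
            p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
        else:
            f_lof, p_lof = float("nan"), float("nan")
        rows["Lack of Fit"] = {
            "ss": ss_lof, "df": df_lof, "ms": ms_lof,
            "F": f_lof, "p": p_lof,
        }
        rows["Pure Error"] = {
            "ss": ss_pe, "df": df_pe, "ms": ms_pe, "F": np.nan, "p": np.nan,
        }

    r2 = 1.0 - rss / ss_total
    adj_r2 = 1.0 - (rss / df_res) / (ss_total / (n - 1))
    try:
        pred_r2 = predicted_r_squared(model, design)
    except UndefinedPressError:
        pred_r2 = float("nan")
    table = pd.DataFrame.from_dict(rows, orient="index")
    return AnovaTable(
        table=table,
        r_squared=r2,
        adj_r_squared=adj_r2,
        pred_r_squared=pred_r2,
        adeq_precision=adequate_precision(model, design),
        has_lack_of_fit=has_lof,
    )


def predicted_r_squared(model: QuadraticModel, design: DesignMatrix) -> float:
    """PRESS-based predicted R².

    PRESS = sum of squared leave-one-out prediction errors, obtained from
    the hat-matrix identity e_i / (1 - h_ii); predicted R² = 1 - PRESS/SS_total.
    """
    y = _check_responses(design)
    X = _model_matrix(design, model.term_active)
    hat = X @ np.linalg.solve(X.T @ X, X.T)
    h = np.diag(hat)
    if np.any(h >= 1.0 - 1e-12):
        raise UndefinedPressError("a leverage of 1 makes PRESS undefined")
    resid = y - X @ model.coefficients[model.term_active]
    press = float(((resid / (1.0 - h)) ** 2).sum())
    ss_total = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss_total


def adequate_precision(model: QuadraticModel, design: DesignMatrix) -> float:
    """Signal-to-noise ratio (fitted-value range over average prediction SE).

    Computed as (max ŷ - min ŷ) / sqrt(p · MS_residual / n) with p the
    number of active model terms (intercept included).  Values above 4
    indicate an adequate signal.  Returns +inf for a perfect fit.
    """
    y = _check_responses(design)
    X = _model_matrix(design, model.term_active)
    fitted = X @ model.coefficients[model.term_active]
    resid = y - fitted
    n, p = X.shape
    df_res = n - p
    ms_res = float(resid @ resid) / df_res if df_res > 0 else 0.0
    signal = float(fitted.max() - fitted.min())
    if ms_res == 0.0:
        return 0.0 if signal == 0.0 else float("inf")
    return signal / float(np.sqrt(p * ms_res / n))


def prune_nonsignificant(
    model: QuadraticModel,
    anova_table: AnovaTable,
    alpha: float = 0.05,
    refit: bool = False,
    design: DesignMatrix | None = None,
) -> QuadraticModel:
    """Deactivate terms whose partial F-test has p >= alpha.

    Model hierarchy is deliberately not enforced: a linear term may be
    dropped while its quadratic survives.  By default the retained
    coefficients keep their full-model estimates (truncation); with
    ``refit=True`` (requires ``design``) the reduced model is re-estimated
    on the active terms only.
    """
    p_values = anova_table.p_values()
    active = model.term_active.copy()
    for i, name in enumerate(TERM_NAMES):
        if name == "intercept":
            continue
        if name in p_values.index and not (p_values[name] < alpha):
            active[i] = False
    if active.sum() <= 1:
        import warnings

        warnings.warn(
            "all model terms pruned; retaining intercept-only model",
            stacklevel=2,
        )
        active[:] = False
        active[0] = True
    if refit:
        if design is None:
            raise ValueError("refit=True requires the design")
        return fit_quadratic(design, term_active=active)
    return QuadraticModel(
        coefficients=model.coefficients.copy(),
        term_active=active,
        residual_sd=model.residual_sd,
    )


def render_anova_text(anova_table: AnovaTable, digits: int = 2) -> str:
    """Plain-text ANOVA report with per-term rows and summary statistics.

    p-values below 1e-4 are rendered as ``<0.0001`` in the conventional
    report style.
    """
    lines = [f"{'Source':<14}{'SS':>12}{'df':>5}{'MS':>12}{'F':>10}  p"]
    for name, row in anova_table.table.iterrows():
        f_txt = "" if np.isnan(row["F"]) else f"{row['F']:.{digits}f}"
        if np.isnan(row["p"]):
            p_txt = ""
        elif row["p"] < 1e-4:
            p_txt = "<0.0001"
        else:
            p_txt = f"{row['p']:.4f}"
        lines.append(
            f"{name:<14}{row['ss']:>12.{digits}f}{int(row['df']):>5}"
            f"{row['ms']:>12.{digits}f}{f_txt:>10}  {p_txt}"
        )
    lines.append("")
    lines.append(
        f"R-squared {anova_table.r_squared:.4f}   "
        f"adj {anova_table.adj_r_squared:.4f}   "
        f"pred {anova_table.pred_r_squared:.4f}   "
        f"adeq precision {anova_table.adeq_precision:.3f}"
    )
    return "\n".join(lines)
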