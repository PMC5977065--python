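"""A 4-H-1 feedforward network trained by full-batch backpropagation.

Each hidden neuron computes tanh(w·x + b) on the coded factor settings;
the output layer is either linear (the common tansig-hidden / linear-output
architecture, the default) or tanh.  The mg-scale response is mapped to
[-1, 1] by an affine min-max transform during training and the transform is
stored with the weights, so `forward` always answers in mg when scaling is
present.

Model quality is summarised by the maximum absolute error (MAE — note:
the maximum, not the mean), the Pearson correlation r, and the
coefficient of determination R² = 1 - RSS/SS_total about the observed
mean.  Hidden-layer size is chosen by scanning H over a range under
k-fold cross-validation and picking the H with the smallest test MAE
(ties broken by the larger test correlation).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import DesignMatrix

__all__ = [
    "NetworkWeights",
    "TrainingConfig",
    "EvaluationMetrics",
    "forward",
    "train_backprop",
    "evaluate",
    "kfold_split",
    "scan_hidden_neurons",
    "select_hidden_count",
    "TrainingDivergedError",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class NetworkWeights:
    """Parameters of a 4-H-1 network plus output-scaling metadata.

    ``response_scaling`` is the (y_min, y_max) pair of the affine map that
    took the mg-scale response onto [-1, 1] during training; when present,
    :func:`forward` inverts it so predictions come back in mg.
    """

    input_weights: np.ndarray  # (H, 4)
    hidden_bias: np.ndarray  # (H,)
    output_weights: np.ndarray  # (H,)
    output_bias: float
    hidden_activation: str = "tanh"
    output_activation: str = "linear"  # linear | tanh
    response_scaling: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.input_weights = np.asarray(self.input_weights, dtype=float)
        self.hidden_bias = np.asarray(self.hidden_bias, dtype=float)
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        h = self.input_weights.shape[0]
        if self.input_weights.shape != (h, 4):
            raise ValueError("input_weights must be (H, 4)")
        if self.hidden_bias.shape != (h,) or self.output_weights.shape != (h,):
            raise ValueError("hidden_bias and output_weights must have length H")
        for arr in (self.input_weights, self.hidden_bias, self.output_weights):
            if not np.all(np.isfinite(arr)):
                raise ValueError("weights must be finite")
        if not np.isfinite(self.output_bias):
            raise ValueError("output bias must be finite")
        if self.hidden_activation != "tanh":
            raise ValueError("only tanh hidden activation is supported")
        if self.output_activation not in ("linear", "tanh"):
            raise ValueError("output_activation must be 'linear' or 'tanh'")

    @property
    def hidden_count(self) -> int:
        return self.input_weights.shape[0]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "hidden_count": self.hidden_count,
            "input_weights": self.input_weights.tolist(),
            "hidden_bias": self.hidden_bias.tolist(),
            "output_weights": self.output_weights.tolist(),
            "output_bias": self.output_bias,
            "hidden_activation": self.hidden_activation,
            "output_activation": self.output_activation,
            "response_scaling": (
                list(self.response_scaling) if self.response_scaling else None
            ),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "NetworkWeights":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        scaling = d.get("response_scaling")
        return cls(
            input_weights=np.array(d["input_weights"]),
            hidden_bias=np.array(d["hidden_bias"]),
            output_weights=np.array(d["output_weights"]),
            output_bias=float(d["output_bias"]),
            hidden_activation=d.get("hidden_activation", "tanh"),
            output_activation=d.get("output_activation", "linear"),
            response_scaling=tuple(scaling) if scaling else None,
        )


@dataclass
class TrainingConfig:
    max_epochs: int = 2000
    learning_rate: float = 0.01
    k_folds: int = 10
    seed: int = 0
    loss: str = "mse"

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.loss != "mse":
            raise ValueError("only mean-squared-error loss is supported")


@dataclass(frozen=True)
class EvaluationMetrics:
    mae: float  # maximum absolute error
    r: float  # Pearson correlation
    r_squared: float


def _scale_response(y: np.ndarray, scaling: tuple[float, float]) -> np.ndarray:
    lo, hi = scaling
    return 2.0 * (y - lo) / (hi - lo) - 1.0


def _unscale_response(t: np.ndarray, scaling: tuple[float, float]) -> np.ndarray:
    lo, hi = scaling
    return lo + (t + 1.0) * (hi - lo) / 2.0


def _forward_raw(
    W1: np.ndarray,
    b1: np.ndarray,
    W2: np.ndarray,
    b2: float,
    X: np.ndarray,
    output_activation: str,
) -> tuple[np.ndarray, np.ndarray]:
    hidden = np.tanh(X @ W1.T + b1)
    u = hidden @ W2 + b2
    out = np.tanh(u) if output_activation == "tanh" else u
    return hidden, out


def forward(weights: NetworkWeights, coded_point: np.ndarray) -> float | np.ndarray:
    """Deterministic forward pass; returns mg when response scaling is set."""
    x = np.asarray(coded_point, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    _, out = _forward_raw(
        weights.input_weights,
        weights.hidden_bias,
        weights.output_weights,
        weights.output_bias,
        X,
        weights.output_activation,
    )
    if weights.response_scaling is not None:
        out = _unscale_response(out, weights.response_scaling)
    return float(out[0]) if single else out


def _gradients(
    W1: np.ndarray,
    b1: np.ndarray,
    W2: np.ndarray,
    b2: float,
    X: np.ndarray,
    t: np.ndarray,
    output_activation: str,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, float]:
    """MSE loss and its exact gradients for one full batch."""
    # overflow here just signals divergence, which the caller detects
    with np.errstate(over="ignore", invalid="ignore"):
        hidden = np.tanh(X @ W1.T + b1)
        u = hidden @ W2 + b2
        out = np.tanh(u) if output_activation == "tanh" else u
        err = out - t
        n = len(t)
        loss = float(err @ err / n)
        d_out = 2.0 * err / n
        d_u = d_out * (1.0 - out**2) if output_activation == "tanh" else d_out
        g_W2 = hidden.T @ d_u
        g_b2 = float(d_u.sum())
        d_hidden = np.outer(d_u, W2)
        d_z = d_hidden * (1.0 - hidden**2)
        g_W1 = d_z.T @ X
        g_b1 = d_z.sum(axis=0)
    return loss, g_W1, g_b1, g_W2, g_b2


def _init_weights(hidden_count: int, rng: np.random.Generator):
    W1 = rng.uniform(-0.5, 0.5, size=(hidden_count, 4))
    b1 = rng.uniform(-0.5, 0.5, size=hidden_count)
    W2 = rng.uniform(-0.5, 0.5, size=hidden_count)
    b2 = float(rng.uniform(-0.5, 0.5))
    return W1, b1, W2, b2


def _descend(
    W1, b1, W2, b2, X, t, epochs: int, lr: float, output_activation: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, list[float]]:
    history: list[float] = []
    for _ in range(epochs):
        loss, g_W1, g_b1, g_W2, g_b2 = _gradients(
            W1, b1, W2, b2, X, t, output_activation
        )
        if not np.isfinite(loss):
            raise TrainingDivergedError(
                "training loss diverged; try a smaller learning rate"
            )
        W1 = W1 - lr * g_W1
        b1 = b1 - lr * g_b1
        W2 = W2 - lr * g_W2
        b2 = b2 - lr * g_b2
        history.append(loss)
    return W1, b1, W2, b2, history


def train_backprop(
    data: DesignMatrix,
    hidden_count: int,
    config: TrainingConfig | None = None,
    output_activation: str = "linear",
    initial: NetworkWeights | None = None,
    scaling: tuple[float, float] | None = None,
) -> tuple[NetworkWeights, list[float]]:
    """Full-batch gradient descent on the MSE of the scaled response.

    The response is min-max scaled to [-1, 1] over the training data (or
    with a caller-supplied ``scaling`` so held-out evaluation shares the
    training transform); the transform is stored in the returned weights.
    Fully reproducible given ``config.seed``.  Returns the weights and the
    per-epoch loss history.
    """
    config = config or TrainingConfig()
    if hidden_count < 1:
        raise ValueError("hidden_count must be >= 1")
    y = data.responses
    if np.isnan(y).any():
        raise ValueError("all runs need responses for training")
    X = data.coded
    if scaling is None:
        lo, hi = float(y.min()), float(y.max())
        scaling = (lo, hi) if hi > lo else (lo - 1.0, hi + 1.0)
    t = _scale_response(y, scaling)

    if initial is not None:
        W1 = initial.input_weights.copy()
        b1 = initial.hidden_bias.copy()
        W2 = initial.output_weights.copy()
        b2 = initial.output_bias
    else:
        rng = np.random.default_rng(config.seed)
        W1, b1, W2, b2 = _init_weights(hidden_count, rng)

    W1, b1, W2, b2, history = _descend(
        W1, b1, W2, b2, X, t, config.max_epochs, config.learning_rate,
        output_activation,
    )
    weights = NetworkWeights(
        input_weights=W1,
        hidden_bias=b1,
        output_weights=W2,
        output_bias=b2,
        output_activation=output_activation,
        response_scaling=scaling,
    )
    return weights, history


def evaluate(predicted: Sequence[float], actual: Sequence[float]) -> EvaluationMetrics:
    """Maximum absolute error, Pearson r, and R² about the observed mean."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValueError("predicted and actual must have equal length")
    if len(p) < 2:
        raise ValueError("need at least 2 values")
    mae = float(np.max(np.abs(p - a)))
    if p.std() == 0.0 or a.std() == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(p, a)[0, 1])
    ss_res = float(((p - a) ** 2).sum())
    ss_tot = float(((a - a.mean()) ** 2).sum())
    return EvaluationMetrics(mae=mae, r=r, r_squared=1.0 - ss_res / ss_tot)


def kfold_split(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded random partition of range(n) into k folds of near-equal size."""
    if k > n:
        raise ValueError(f"cannot split {n} items into {k} folds")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def _subset(data: DesignMatrix, idx: np.ndarray) -> DesignMatrix:
    return DesignMatrix(data.factors, [data.points[i] for i in idx])


def scan_hidden_neurons(
    data: DesignMatrix,
    h_min: int = 1,
    h_max: int = 9,
    config: TrainingConfig | None = None,
    aggregate: str = "first",
) -> pd.DataFrame:
    """Train networks with H = h_min..h_max and tabulate CV metrics.

    ``aggregate='first'`` evaluates one train/test split (the first fold
    held out); ``'mean'`` averages the metrics over all k folds.  A row
    whose training diverges is flagged (NaN metrics, ``error`` column)
    rather than aborting the scan.
    """
    config = config or TrainingConfig()
    if aggregate not in ("first", "mean"):
        raise ValueError("aggregate must be 'first' or 'mean'")
    n = len(data)
    folds = kfold_split(n, config.k_folds, config.seed)
    if aggregate == "first":
        folds = folds[:1]
    y = data.responses
    scaling = (float(y.min()), float(y.max()))

    rows = []
    for h in range(h_min, h_max + 1):
        metrics = []
        error = ""
        try:
            for test_idx in folds:
                train_idx = np.setdiff1d(np.arange(n), test_idx)
                train = _subset(data, train_idx)
                test = _subset(data, test_idx)
                weights, _ = train_backprop(
                    train, h, config, scaling=scaling
                )
                m_train = evaluate(forward(weights, train.coded), train.responses)
                pred_test = forward(weights, test.coded)
                mae_test = float(np.max(np.abs(pred_test - test.responses)))
                if len(test_idx) >= 2 and np.std(pred_test) > 0:
                    r_test = float(np.corrcoef(pred_test, test.responses)[0, 1])
                else:
                    r_test = float("nan")
                metrics.append(
                    (m_train.mae, mae_test, m_train.r_squared, m_train.r, r_test)
                )
        except TrainingDivergedError as exc:
            error = str(exc)
        if error:
            rows.append(
                {"hidden": h, "mae_train": np.nan, "mae_test": np.nan,
                 "r2_train": np.nan, "r_train": np.nan, "r_test": np.nan,
                 "error": error}
            )
        else:
            arr = np.array(metrics)
            mean = arr.mean(axis=0)
            rows.append(
                {"hidden": h, "mae_train": mean[0], "mae_test": mean[1],
                 "r2_train": mean[2], "r_train": mean[3], "r_test": mean[4],
                 "error": ""}
            )
    return pd.DataFrame(rows)


def select_hidden_count(scan: pd.DataFrame) -> int:
    """Selection rule: minimum test MAE, ties broken by larger test r."""
    ok = scan.dropna(subset=["mae_test"])
    if ok.empty:
        raise ValueError("no successful scan rows to select from")
    best = ok.sort_values(
        ["mae_test", "r_test"], ascending=[True, False], kind="stable"
    ).iloc[0]
    return int(best["hidden"])


def write_scan_report(scan: pd.DataFrame, path: str | Path) -> None:
    """CSV scan report: one row per hidden-layer size with CV metrics."""
    scan.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)
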