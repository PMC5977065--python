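"""Hybrid GA-trained network: genome-encoded weights under a minimax fitness.

Backpropagation alone tends to stall in local minima on small designed
datasets, so the weight vector of the 4-H-1 network is encoded as a
real-valued chromosome of length S = R·S1 + S1·S2 + S1 + S2 (inputs R,
hidden S1, outputs S2) and searched by the genetic algorithm.  Each
individual's fitness is

    fitness = max(MAE_train, MAE_test)

— the worse of the maximum absolute errors on the training and testing
splits — so minimizing it demands that the network generalize, not just
interpolate.  Each candidate is optionally polished by a few epochs of
backpropagation before evaluation (the lamarckian variant), and the best
individual found is refined by a longer backpropagation run at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignMatrix
from .ga import EvolutionHistory, GAConfig, evolve
from .network import (
    NetworkWeights,
    TrainingDivergedError,
    _descend,
    _scale_response,
    evaluate,
    forward,
    kfold_split,
)

__all__ = [
    "HybridConfig",
    "FitnessValue",
    "chromosome_length",
    "encode_weights",
    "decode_genome",
    "hybrid_fitness",
    "train_ga_bpnn",
    "scan_hidden_neurons_hybrid",
    "import_weights_table",
    "export_weights_table",
    "WeightTableError",
]


class WeightTableError(ValueError):
    """Raised when a tabular weight file does not match the expected layout."""


def chromosome_length(inputs: int, hidden: int, outputs: int) -> int:
    """Genome length S = R·S1 + S1·S2 + S1 + S2 for an R-S1-S2 network."""
    if min(inputs, hidden, outputs) < 1:
        raise ValueError("layer sizes must be >= 1")
    return inputs * hidden + hidden * outputs + hidden + outputs


@dataclass
class HybridConfig:
    """Settings for the GA + backpropagation weight search.

    ``weight_bounds`` is the per-gene box the GA searches; it is kept wide
    so published solutions with large weights stay representable, while
    ``init_range`` keeps the initial population small — genes sampled
    uniformly over the whole box would saturate every tanh and leave the
    polish without usable gradients.  ``polish_epochs`` is the short
    lamarckian backprop polish applied to every individual before its
    fitness is assessed (0 disables it, giving a pure-GA search);
    ``bp_epochs`` is the final refinement budget M.  The GA default uses a
    small absolute mutation step (mutation_scale 0.005 of the 60-unit gene
    range, i.e. sd 0.3) because weight perturbations act before a tanh.
    """

    ga: GAConfig = field(
        default_factory=lambda: GAConfig(maximize=False, mutation_scale=0.005)
    )
    bp_epochs: int = 500
    polish_epochs: int = 20
    weight_bounds: tuple[float, float] = (-30.0, 30.0)
    init_range: float = 1.0
    learning_rate: float = 0.1
    k_folds: int = 10
    output_activation: str = "linear"

    def __post_init__(self) -> None:
        if self.ga.maximize:
            raise ValueError("hybrid fitness is minimized; set ga.maximize=False")
        lo, hi = self.weight_bounds
        if not lo < hi:
            raise ValueError("weight_bounds must satisfy lower < upper")


@dataclass(frozen=True)
class FitnessValue:
    """Minimax fitness: the worse of the two maximum absolute errors (mg)."""

    mae_train: float
    mae_test: float

    @property
    def fitness(self) -> float:
        return max(self.mae_train, self.mae_test)


def encode_weights(weights: NetworkWeights) -> np.ndarray:
    """Flatten weights into the canonical genome: W1 row-major, W2, B1, B2."""
    return np.concatenate(
        [
            weights.input_weights.ravel(),
            weights.output_weights,
            weights.hidden_bias,
            [weights.output_bias],
        ]
    )


def decode_genome(
    genome: np.ndarray,
    inputs: int,
    hidden: int,
    outputs: int = 1,
    output_activation: str = "linear",
    response_scaling: tuple[float, float] | None = None,
) -> NetworkWeights:
    """Inverse of :func:`encode_weights`; exact round-trip."""
    genome = np.asarray(genome, dtype=float)
    expected = chromosome_length(inputs, hidden, outputs)
    if genome.shape != (expected,):
        raise ValueError(
            f"genome length {genome.shape} does not match expected ({expected},) "
            f"for a {inputs}-{hidden}-{outputs} network"
        )
    pos = 0
    W1 = genome[pos : pos + inputs * hidden].reshape(hidden, inputs)
    pos += inputs * hidden
    W2 = genome[pos : pos + hidden * outputs]
    pos += hidden * outputs
    b1 = genome[pos : pos + hidden]
    pos += hidden
    b2 = float(genome[pos])
    return NetworkWeights(
        input_weights=W1,
        hidden_bias=b1,
        output_weights=W2,
        output_bias=b2,
        output_activation=output_activation,
        response_scaling=response_scaling,
    )


def hybrid_fitness(
    genome: np.ndarray,
    train_data: DesignMatrix,
    test_data: DesignMatrix,
    scaling: tuple[float, float],
    hidden: int,
    output_activation: str = "linear",
) -> FitnessValue:
    """Decode a genome and score it on both splits (mg scale)."""
    if len(train_data) == 0 or len(test_data) == 0:
        raise ValueError("both data splits must be non-empty")
    weights = decode_genome(
        genome, 4, hidden,
        output_activation=output_activation, response_scaling=scaling,
    )
    mae_train = float(
        np.max(np.abs(forward(weights, train_data.coded) - train_data.responses))
    )
    mae_test = float(
        np.max(np.abs(forward(weights, test_data.coded) - test_data.responses))
    )
    return FitnessValue(mae_train=mae_train, mae_test=mae_test)


def _subset(data: DesignMatrix, idx: np.ndarray) -> DesignMatrix:
    return DesignMatrix(data.factors, [data.points[i] for i in idx])


def train_ga_bpnn(
    data: DesignMatrix,
    hidden_count: int,
    config: HybridConfig | None = None,
    test_fold: int = 0,
) -> tuple[NetworkWeights, FitnessValue, EvolutionHistory]:
    """GA search of weight space under the minimax fitness, then BP refinement.

    The data are split with :func:`kfold_split` under the GA seed and fold
    ``test_fold`` is held out.  The GA minimizes max(MAE_train, MAE_test);
    each individual receives a short lamarckian backprop polish on the
    training split before evaluation.  The best genome is then refined by
    ``bp_epochs`` epochs of backpropagation, and the refined network is
    returned only if it does not worsen the fitness.
    """
    config = config or HybridConfig()
    y = data.responses
    if np.isnan(y).any():
        raise ValueError("all runs need responses")
    folds = kfold_split(len(data), config.k_folds, config.ga.seed)
    test_idx = folds[test_fold]
    train_idx = np.setdiff1d(np.arange(len(data)), test_idx)
    train = _subset(data, train_idx)
    test = _subset(data, test_idx)
    scaling = (float(y.min()), float(y.max()))

    X_train = train.coded
    t_train = _scale_response(train.responses, scaling)

    def fitness_fn(genome: np.ndarray) -> float:
        return hybrid_fitness(
            genome, train, test, scaling, hidden_count, config.output_activation
        ).fitness

    def descend_genome(genome: np.ndarray, epochs: int) -> np.ndarray:
        # Backprop polish on the training split; a divergent descent (large
        # weights can blow up at this step size) returns the genome as-is.
        w = decode_genome(genome, 4, hidden_count)
        try:
            W1, b1, W2, b2, _ = _descend(
                w.input_weights, w.hidden_bias, w.output_weights, w.output_bias,
                X_train, t_train, epochs, config.learning_rate,
                config.output_activation,
            )
        except TrainingDivergedError:
            return genome
        out = np.concatenate([W1.ravel(), W2, b1, [b2]])
        return out if np.all(np.isfinite(out)) else genome

    length = chromosome_length(4, hidden_count, 1)
    lo, hi = config.weight_bounds
    bounds = (np.full(length, lo), np.full(length, hi))
    init = (np.full(length, -config.init_range), np.full(length, config.init_range))
    refine = (
        (lambda g: descend_genome(g, config.polish_epochs))
        if config.polish_epochs > 0
        else None
    )
    best, history = evolve(
        fitness_fn, bounds, config.ga, refine=refine, init_bounds=init
    )

    genome = best.genome
    if config.bp_epochs > 0:
        refined = np.clip(descend_genome(genome, config.bp_epochs), lo, hi)
        if fitness_fn(refined) <= best.fitness:
            genome = refined

    value = hybrid_fitness(
        genome, train, test, scaling, hidden_count, config.output_activation
    )
    weights = decode_genome(
        genome, 4, hidden_count,
        output_activation=config.output_activation, response_scaling=scaling,
    )
    return weights, value, history


def scan_hidden_neurons_hybrid(
    data: DesignMatrix,
    h_min: int = 1,
    h_max: int = 9,
    config: HybridConfig | None = None,
) -> pd.DataFrame:
    """Hybrid-trained scan over hidden-layer sizes with per-split metrics.

    One row per H with columns hidden, mae_train, mae_test, r2_train,
    r_train, r_test; rows whose training fails are flagged rather than
    aborting.  Apply :func:`extractopt.network.select_hidden_count` for
    the selection rule.
    """
    config = config or HybridConfig()
    folds = kfold_split(len(data), config.k_folds, config.ga.seed)
    test_idx = folds[0]
    train_idx = np.setdiff1d(np.arange(len(data)), test_idx)
    rows = []
    for h in range(h_min, h_max + 1):
        try:
            weights, value, _ = train_ga_bpnn(data, h, config)
            train = _subset(data, train_idx)
            test = _subset(data, test_idx)
            m_train = evaluate(forward(weights, train.coded), train.responses)
            pred_test = forward(weights, test.coded)
            if len(test_idx) >= 2 and np.std(pred_test) > 0:
                r_test = float(np.corrcoef(pred_test, test.responses)[0, 1])
            else:
                r_test = float("nan")
            rows.append(
                {"hidden": h, "mae_train": value.mae_train,
                 "mae_test": value.mae_test, "r2_train": m_train.r_squared,
                 "r_train": m_train.r, "r_test": r_test, "error": ""}
            )
        except Exception as exc:  # noqa: BLE001 - row-level flagging by contract
            rows.append(
                {"hidden": h, "mae_train": np.nan, "mae_test": np.nan,
                 "r2_train": np.nan, "r_train": np.nan, "r_test": np.nan,
                 "error": str(exc)}
            )
    return pd.DataFrame(rows)


def export_weights_table(weights: NetworkWeights, path: str | Path) -> None:
    """Write weights as a 6-column table: W1 (4 cols), W2, B1, with B2 in
    an extra column of the first row and ``/`` marking empty cells."""
    h = weights.hidden_count
    lines = ["w1_1,w1_2,w1_3,w1_4,w2,b1,b2"]
    for i in range(h):
        cells = [f"{v}" for v in weights.input_weights[i]]
        cells += [f"{weights.output_weights[i]}", f"{weights.hidden_bias[i]}"]
        cells.append(f"{weights.output_bias}" if i == 0 else "/")
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def import_weights_table(path: str | Path) -> NetworkWeights:
    """Parse the tabular weight layout written by :func:`export_weights_table`.

    Each row holds one hidden neuron: four input weights, the
    hidden-to-output weight, the hidden bias; the single output bias sits
    in the first row's final column and ``/`` fills the rest.  Ragged rows
    or non-numeric non-``/`` cells raise with the offending row number.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise WeightTableError("empty weight table")
    start = 1 if lines[0].lower().lstrip().startswith(("w1", "#")) else 0
    W1, W2, B1 = [], [], []
    b2: float | None = None
    for row_no, line in enumerate(lines[start:], start=start + 1):
        cells = [c.strip() for c in line.split(",")]
        if len(cells) != 7:
            raise WeightTableError(
                f"row {row_no}: expected 7 columns (4 input weights, W2, B1, B2), "
                f"got {len(cells)}"
            )
        if cells[6] != "/" and b2 is not None:
            raise WeightTableError(f"row {row_no}: multiple output-bias entries")
        try:
            W1.append([float(c) for c in cells[:4]])
            W2.append(float(cells[4]))
            B1.append(float(cells[5]))
            if cells[6] != "/":
                b2 = float(cells[6])
        except ValueError as exc:
            raise WeightTableError(f"row {row_no}: non-numeric cell ({exc})") from exc
    if b2 is None:
        raise WeightTableError("missing output-bias entry")
    return NetworkWeights(
        input_weights=np.array(W1),
        hidden_bias=np.array(B1),
        output_weights=np.array(W2),
        output_bias=b2,
        output_activation="linear",
        response_scaling=None,
    )
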