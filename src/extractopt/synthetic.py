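"""Synthetic CCD datasets with known ground truth.

Every stage of the pipeline — OLS fitting, ANOVA behaviour, network
training, GA search — can be exercised against data whose generating
process is fully known: a second-order polynomial or a small tanh
network evaluated on the standard four-factor CCD, plus i.i.d. Gaussian
noise on the mg scale.  The defaults mirror the glycyrrhizic-acid study
conditions: the fitted reduced response surface as the true polynomial
and a noise standard deviation equal to the square root of that fit's
residual mean square (sqrt(64.87) ≈ 8.05 mg), so simulated replicates
live on the same error scale as the real experiment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datasets import glycyrrhizic_factors
from .design import DesignMatrix, FactorDefinition, build_ccd
from .network import NetworkWeights, forward
from .rsm import QuadraticModel

__all__ = [
    "SyntheticSpec",
    "STUDY_SURFACE",
    "STUDY_NOISE_SD",
    "generate_quadratic_dataset",
    "generate_network_dataset",
]

# The reduced second-order surface fitted to the study data (coded units,
# response in mg), used as the default simulation truth.
STUDY_SURFACE: dict[str, float] = {
    "intercept": 365.45,
    "x1": 11.92,
    "x3": 11.95,
    "x4": 11.45,
    "x3:x4": -14.1,
    "x1^2": -8.25,
    "x2^2": -9.68,
}

# Residual scale of that fit: sqrt(residual mean square 64.87).
STUDY_NOISE_SD: float = 8.054
STUDY_SURFACE_MODEL = QuadraticModel.from_named_coefficients(STUDY_SURFACE)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    ``generator`` selects the truth family; exactly one of
    ``true_coefficients`` (term-name -> value mapping or QuadraticModel)
    or ``true_weights`` is used.  ``noise_sd`` is the standard deviation
    of the additive Gaussian noise in mg.
    """

    generator: str = "quadratic"  # quadratic | network
    true_coefficients: dict[str, float] | QuadraticModel | None = None
    true_weights: NetworkWeights | None = None
    noise_sd: float = STUDY_NOISE_SD
    n_center: int = 6
    axial_distance: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generator not in ("quadratic", "network"):
            raise ValueError("generator must be 'quadratic' or 'network'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _truth_model(spec: SyntheticSpec) -> QuadraticModel:
    truth = spec.true_coefficients
    if truth is None:
        return STUDY_SURFACE_MODEL
    if isinstance(truth, QuadraticModel):
        return truth
    return QuadraticModel.from_named_coefficients(dict(truth))


def generate_quadratic_dataset(
    spec: SyntheticSpec,
    factors: tuple[FactorDefinition, ...] | None = None,
) -> tuple[DesignMatrix, QuadraticModel]:
    """CCD responses from a known polynomial plus seeded Gaussian noise.

    Returns the populated design together with the true model so
    downstream tests can assert recovery.
    """
    factors = factors or glycyrrhizic_factors()
    truth = _truth_model(spec)
    design = build_ccd(factors, spec.axial_distance, spec.n_center)
    rng = np.random.default_rng(spec.seed)
    clean = truth.predict(design.coded)
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=len(design))
    return design.with_responses(noisy), truth


def generate_network_dataset(
    spec: SyntheticSpec,
    factors: tuple[FactorDefinition, ...] | None = None,
) -> tuple[DesignMatrix, NetworkWeights]:
    """CCD responses from a known network forward pass plus Gaussian noise."""
    if spec.true_weights is None:
        raise ValueError("network generator requires true_weights")
    factors = factors or glycyrrhizic_factors()
    design = build_ccd(factors, spec.axial_distance, spec.n_center)
    rng = np.random.default_rng(spec.seed)
    clean = np.asarray(forward(spec.true_weights, design.coded), dtype=float)
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=len(design))
    return design.with_responses(noisy), spec.true_weights


def write_ground_truth(
    spec: SyntheticSpec,
    truth: QuadraticModel | NetworkWeights,
    path: str | Path,
) -> None:
    """Serialize the generating truth next to a dataset (JSON)."""
    payload: dict = {
        "generator": spec.generator,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "n_center": spec.n_center,
    }
    payload["truth"] = json.loads(truth.to_json())
    Path(path).write_text(json.dumps(payload, indent=2))
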