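"""Embedded study data: the 30-run glycyrrhizic-acid extraction CCD.

The dataset ships the published central composite design for extracting
glycyrrhizic acid from *Glycyrrhiza glabra* (licorice): four factors —
ammonia concentration, ethanol concentration, return (reflux) time and
liquid-solid ratio — at five coded levels each, with the measured
glycyrrhizic-acid content in mg per batch as the response.  Also included
are the published weights of the GA-trained 4-7-1 network fitted to the
same data, and the published hidden-neuron scan metrics for that hybrid
trainer, so model-selection rules can be exercised on real numbers.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .design import DesignMatrix, FactorDefinition, load_experiment_table

__all__ = [
    "glycyrrhizic_factors",
    "glycyrrhizic_ccd",
    "glycyrrhizic_network_weights",
    "reference_hybrid_scan",
    "reference_optima",
    "CCD_TABLE_CSV",
]

# Note on the liquid-solid ratio step: the level grid runs 10.0 -> 12.0
# across coded -2..+2, which fixes the step at 0.5 actual units per coded
# unit (one coded unit = 0.5 volume/mass).
def glycyrrhizic_factors() -> tuple[FactorDefinition, ...]:
    """The four extraction factors with their centres and coded steps."""
    return (
        FactorDefinition("ammonia concentration", "%", center=0.60, step=0.05),
        FactorDefinition("ethanol concentration", "%", center=60.0, step=5.0),
        FactorDefinition("return time", "h", center=2.00, step=0.25),
        FactorDefinition("liquid-solid ratio", "vol/mass", center=11.0, step=0.5),
    )


# 30 runs: 16 factorial (+-1), 8 axial (+-2), 6 centre replicates,
# in the original randomised run order.
CCD_TABLE_CSV = """\
run,x1,x2,x3,x4,response
1,1,-1,-1,1,360.68
2,0,0,2,0,372.52
3,1,1,1,-1,368.57
4,0,0,-2,0,333.06
5,1,1,1,1,353.78
6,0,0,0,0,366.60
7,-1,1,-1,-1,290.93
8,1,-1,-1,-1,312.35
9,-1,1,1,1,347.86
10,-1,-1,-1,1,343.91
11,-2,0,0,0,297.87
12,1,1,-1,1,376.46
13,0,2,0,0,334.03
14,-1,1,-1,1,339.97
15,0,0,0,2,369.56
16,-1,1,1,-1,345.89
17,1,1,-1,-1,306.43
18,0,0,0,0,366.60
19,1,-1,1,-1,364.62
20,1,-1,1,1,358.71
21,0,0,0,0,364.62
22,0,0,0,0,367.58
23,-1,-1,1,-1,340.95
24,-1,-1,-1,-1,293.61
25,2,0,0,0,367.58
26,0,0,0,-2,337.01
27,-1,-1,1,1,351.80
28,0,0,0,0,363.64
29,0,-2,0,0,319.94
30,0,0,0,0,363.64
"""


def glycyrrhizic_ccd() -> DesignMatrix:
    """The 30-run extraction dataset as a validated :class:`DesignMatrix`."""
    frame = pd.read_csv(io.StringIO(CCD_TABLE_CSV))
    return load_experiment_table(frame, glycyrrhizic_factors())


# Published weights of the GA-trained 4-7-1 tanh-hidden network.
# Rows: one hidden neuron each; columns: the four input weights, the
# hidden->output weight, the hidden bias.  The single output bias follows.
_W1 = np.array(
    [
        [-1.7112, 6.3033, 2.1697, -1.9326],
        [0.6937, 0.6410, 0.6825, -6.2043],
        [-0.2540, 3.1229, -0.8732, 22.4836],
        [4.1697, -0.6174, 0.8745, 3.9847],
        [1.5632, 0.4164, 1.0697, 5.9332],
        [-0.8586, 10.9352, 1.5034, -1.7881],
        [-0.9376, 0.3819, 4.8547, -4.6069],
    ]
)
_W2 = np.array([-0.7868, 0.4207, 0.4419, 0.6316, -0.7100, 0.7376, 1.0109])
_B1 = np.array([-1.6870, 28.0577, -0.4640, 0.5918, 5.7520, 1.1129, -6.2961])
_B2 = 0.7532


def glycyrrhizic_network_weights():
    """The published 4-7-1 network weights for the extraction dataset.

    The output-layer activation and response-scaling conventions used when
    these weights were trained are not recorded alongside them, so the
    weights are exposed raw: linear output, no response scaling.  A forward
    pass therefore returns the network's unscaled output signal.
    """
    from .network import NetworkWeights

    return NetworkWeights(
        input_weights=_W1.copy(),
        hidden_bias=_B1.copy(),
        output_weights=_W2.copy(),
        output_bias=_B2,
        output_activation="linear",
        response_scaling=None,
    )


def reference_hybrid_scan() -> pd.DataFrame:
    """Published hidden-neuron scan metrics for the GA-trained network.

    One row per candidate hidden-layer size H in 1..9: maximum absolute
    error on the training and testing splits (mg), training R², and the
    train/test Pearson correlations.  Useful for exercising the selection
    rule (minimum MAE_test, tie-break on r_test) on real numbers.
    """
    return pd.DataFrame(
        {
            "hidden": range(1, 10),
            "mae_train": [24.8167, 12.4153, 6.9400, 7.1209, 4.1890,
                          2.0200, 3.8732, 3.0094, 6.8777],
            "mae_test": [13.6733, 11.4872, 9.4277, 6.8005, 4.2232,
                         4.8036, 2.3678, 3.2231, 4.1785],
            "r2_train": [0.6818, 0.8422, 0.9895, 0.9857, 0.9967,
                         0.9984, 0.9987, 0.9967, 0.9955],
            "r_train": [0.8260, 0.9186, 0.9952, 0.9929, 0.9984,
                        0.9992, 0.9979, 0.9984, 0.9979],
            "r_test": [0.5455, 0.5325, 0.5841, 0.5667, 0.7681,
                       0.7052, 0.9964, 0.9957, 0.9155],
        }
    )


def reference_optima() -> pd.DataFrame:
    """Published optimized coded conditions and validation values per surrogate.

    ``predicted`` is each surrogate's value at its optimum; ``experimental``
    is the mean of three confirmatory extraction batches run at the decoded
    conditions (mg of glycyrrhizic acid).
    """
    return pd.DataFrame(
        {
            "method": ["rsm", "bpnn", "ga_bpnn"],
            "x1": [0.72, 1.54, -0.10],
            "x2": [0.0, 1.09, -0.31],
            "x3": [2.0, -1.23, 2.0],
            "x4": [-2.0, 1.38, 0.13],
            "predicted": [427.1562, 376.4012, 381.24],
            "experimental": [369.23, 365.58, 376.46],
        }
    )
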