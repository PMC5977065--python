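"""Hybrid weight search: GA over the weight genome with backprop polish.

Network weights are flattened into a real chromosome of length
S = R*S1 + S1*S2 + S1 + S2 (43 genes for a 4-7-1 net).  The GA minimizes
fitness = max(MAE_train, MAE_test) — the worse of the maximum absolute
errors on the two cross-validation splits — so a solution must generalize
rather than memorize.  Each candidate gets a short lamarckian backprop
polish; the best genome gets a longer final refinement.
"""

import numpy as np

import extractopt as xo

data = xo.glycyrrhizic_ccd()

print("chromosome length for 4-7-1:", xo.chromosome_length(4, 7, 1))

cfg = xo.HybridConfig(
    ga=xo.GAConfig(population_size=30, generations=12, seed=0,
                   maximize=False, mutation_scale=0.005),
)
weights, value, history = xo.train_ga_bpnn(data, hidden_count=7, config=cfg)
print(f"minimax fitness {value.fitness:.2f} mg "
      f"(train MAE {value.mae_train:.2f}, test MAE {value.mae_test:.2f})")
print(f"best fitness per generation: "
      f"{[round(v, 1) for v in history.best_fitness]}")
print("With elitism the best fitness never worsens between generations.")
print()

# The published 4-7-1 weight set round-trips through the tabular layout.
import tempfile
from pathlib import Path

ref = xo.glycyrrhizic_network_weights()
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "weights_table.csv"
    xo.export_weights_table(ref, path)
    again = xo.import_weights_table(path)
print("published weight table round-trip exact:",
      np.array_equal(again.input_weights, ref.input_weights)
      and again.output_bias == ref.output_bias)
print("raw output signal of the published net at the design centre:",
      round(xo.forward(ref, np.zeros(4)), 4))
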