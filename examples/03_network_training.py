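"""Train a 4-H-1 tanh network on the extraction data and scan hidden sizes.

The response is min-max scaled to [-1, 1]; training is full-batch
gradient descent on the mean squared error.  Hidden-layer size is chosen
by 10-fold cross-validation under the rule: smallest maximum absolute
test error, ties broken by the larger test correlation.
"""

import numpy as np

import extractopt as xo

data = xo.glycyrrhizic_ccd()

config = xo.TrainingConfig(max_epochs=2000, learning_rate=0.2, seed=1)
weights, history = xo.train_backprop(data, hidden_count=4, config=config)
metrics = xo.evaluate(xo.forward(weights, data.coded), data.responses)
print(f"H=4 trained on all 30 runs: final loss {history[-1]:.5f} (scaled units), "
      f"r = {metrics.r:.4f}, max abs error = {metrics.mae:.2f} mg")
print("Training on everything overfits by design — it shows capacity, not")
print("generalization; the scan below holds data out.")
print()

scan = xo.scan_hidden_neurons(data, 1, 5, xo.TrainingConfig(seed=1, learning_rate=0.2))
print(scan[["hidden", "mae_train", "mae_test", "r_train", "r_test"]].round(3).to_string(index=False))
print(f"selected hidden-layer size: {xo.select_hidden_count(scan)} "
      "(min test MAE, tie-break on test r)")
print()

# The published hidden-neuron scan for the GA-trained hybrid: the same
# selection rule applied to those printed metrics picks seven neurons.
ref = xo.reference_hybrid_scan()
print("published hybrid scan -> H =", xo.select_hidden_count(ref))
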