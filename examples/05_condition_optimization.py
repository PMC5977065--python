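"""Search the coded box for the best extraction conditions.

Any fitted surrogate (quadratic surface or network) can be maximized
over the coded box [-2, 2]^4 with the memetic GA; for quadratics an
exact closed-form oracle is available by KKT enumeration and confirms
the GA answer.
"""

import extractopt as xo
from extractopt.optimizer import model_predict_fn

data = xo.glycyrrhizic_ccd()
model = xo.fit_quadratic(data)
pruned = xo.prune_nonsignificant(model, xo.anova(model, data))

point, value = xo.quadratic_optimum_closed_form(pruned)
print(f"closed-form optimum: {value:.4f} mg at coded "
      f"({', '.join(f'{v:.3f}' for v in point)})")

result = xo.optimize_conditions(
    model_predict_fn(pruned), data.factors,
    xo.GAConfig(population_size=30, generations=12, seed=0),
    surrogate_kind="rsm",
)
print(result.summary())
print()
print("The ammonia level sits at an interior stationary point (~0.72 coded)")
print("while return time and liquid-solid ratio are driven to opposite box")
print("edges by their negative interaction; ethanol is optimal at its centre.")
print()

# Compare published optima across the three surrogates with their
# confirmatory wet-lab values.
optima = xo.reference_optima()
results = []
for _, row in optima.iterrows():
    coded = [row["x1"], row["x2"], row["x3"], row["x4"]]
    results.append(xo.OptimizationResult(
        surrogate_kind=row["method"],
        best_coded=__import__("numpy").asarray(coded),
        best_actual={f.name: xo.decode_value(x, f)
                     for x, f in zip(coded, data.factors)},
        predicted_response=row["predicted"],
    ))
report = xo.comparison_report(results, optima["experimental"].tolist())
print(report.round(3).to_string(index=False))
print()
print("The hybrid's 4.78 mg validation gap, against 57.9 mg for the")
print("quadratic surface, is the study's case for the GA-network surrogate.")
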