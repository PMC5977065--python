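# Methods

## The design and its coding

Four extraction variables are modelled in coded units
`x_i = (z_i − z_i⁰)/Δz_i` with centres and steps

| factor | centre z⁰ | step Δz | coded range |
|---|---|---|---|
| ammonia concentration (%) | 0.60 | 0.05 | [−2, 2] |
| ethanol concentration (%) | 60 | 5 | [−2, 2] |
| return time (h) | 2.00 | 0.25 | [−2, 2] |
| liquid-solid ratio | 11.0 | 0.5 | [−2, 2] |

The liquid-solid step is 0.5, fixed by the level grid (10.0 → 12.0 across
coded −2..+2); loaders accept any user-supplied step. The design is the
standard rotatable four-factor CCD: 16 factorial points (±1), 8 axial
points at α = 16^(1/4) = 2, and 6 centre replicates — 30 runs, 25
distinct coded points. `build_ccd` emits runs in a fixed canonical order
(factorial in binary-counter order, axial pairs by factor index, then
centres) so outputs are bit-reproducible; the embedded experiment table
keeps its original randomised run order and is checksummed in the test
suite. The design's moment conditions (Σxᵢ = 0, Σxᵢxⱼ = 0, Σxᵢxⱼ² = 0,
Σxᵢ³ = 0) are asserted as tests; they are what make the linear and
interaction OLS estimates equal their one-column projections.

## Response-surface model

The full quadratic (15 terms, basis order 1, x₁..x₄, the six xᵢxⱼ with
i<j, then xᵢ²) is fitted by OLS. ANOVA uses partial (Type-III) sums of
squares — SS(term) = RSS(model without the term) − RSS(full model) —
which coincides with the sequential decomposition here because the
columns are orthogonal; both routes are exercised in tests. Pure error
pools the within-group variation of replicated coded points (only the
six centre runs replicate, giving 5 df); lack of fit takes the rest of
the residual with df = (distinct points) − (model terms) = 25 − 15 = 10.
Predicted R² uses the PRESS identity e_i/(1 − h_ii), verified against
literal leave-one-out refits. Adequate precision is
(max ŷ − min ŷ)/√(p·MS_res/n). p-values are upper-tail F; the report
renderer prints values below 10⁻⁴ as `<0.0001`.

Pruning keeps terms with p < α (default 0.05) in a single pass, without
enforcing hierarchy — on the study data the linear ethanol term is
dropped while its quadratic stays. Retained coefficients keep their
full-model estimates by default (truncation). The two conventions differ
only in the intercept and quadratic terms (the other columns are
orthogonal); `refit=True` provides the re-estimated alternative. The
truncation default matches the published reduced equation, whose
intercept equals the full-model intercept ≈ centre mean (365.45 mg).
Which convention the original analysis used cannot be determined from the
report; both are available and tested.

Two printed quirks of the source table are interpreted rather than
copied: the rows labelled "x₂³"/"x₂⁴" are x₃²/x₄² (the only terms
otherwise missing from a 14-df model, and their SS values match), and the
response of each run is treated as a single (possibly duplicate-averaged)
measurement, the only reading consistent with 5 pure-error df.

## Feedforward network

A 4–H–1 network with tanh hidden units. The output layer is linear by
default (the common tanh-hidden/linear-output regression architecture); a
tanh output is available, in which case predictions saturate at the
training response range — with min-max scaling of the response to
[−1, 1] that clamp makes out-of-range predictions impossible, which is
why linear output is the default. The response scaling is stored with the
weights so `forward` answers in mg.

Training is full-batch gradient descent on the MSE of the scaled
response, which makes loss histories deterministic given the seed
(weights initialised uniform on [−0.5, 0.5]). The learning rate defaults
to a conservative 0.01; full-batch descent needs a larger step
(0.1–0.2) to approach interpolation of the 30-run dataset within 2000
epochs, and the tests that exercise near-interpolation set it
explicitly. Divergence (non-finite loss) aborts with an error rather
than returning garbage. Gradients are exact and are checked against
central finite differences at 10⁻⁶ relative tolerance.

Evaluation metrics: MAE here is the **maximum** absolute error, not the
mean — a deliberately strict criterion; r is the Pearson correlation; R²
is 1 − RSS/SS_tot about the observed mean, the same formula as the
response-surface R². Hidden-size selection scans H over a range under
seeded k-fold cross-validation (k = 10 on 30 runs gives 27/3 splits) and
picks the H with minimum test MAE, ties broken by larger test r. The
scan can evaluate one held-out fold (default) or average all k; the
published per-H tables are single stochastic realizations of an unseeded
run, so they are treated as structural templates, not golden values —
the selection rule applied to the published hybrid scan does pick H = 7,
and that is asserted.

## Genetic algorithm

Real-coded, box-bounded: size-2 tournament selection, arithmetic (blend)
crossover with a single mixing weight per pair (children are convex
combinations, hence always feasible), per-gene Gaussian mutation with sd
= mutation_scale·(range) clipped to the box, and elitism (default 2).
Defaults: population 30, crossover 0.8, mutation 0.1, scale 0.1.
Termination is a fixed generation budget only, keeping runs exactly
reproducible; with elitism the best-ever fitness is non-worsening, which
is asserted on every run. The original analysis names its operators but
not their variants or rates (they were toolbox defaults); the defaults
here are declared, not inferred, and all are configurable.

`evolve` accepts an optional per-individual `refine` hook applied before
fitness evaluation, with the refined genome written back into the
population (lamarckian local search). It also accepts `init_bounds` to
sample the initial population from a sub-box of the feasible region.

## Hybrid GA + backprop weight search

Weights of the 4–H–1 network are flattened into a chromosome of length
S = R·S₁ + S₁·S₂ + S₁ + S₂ (43 genes at H = 7), ordered W1 row-major,
W2, B1, B2; encode/decode round-trips exactly, as does the tabular
weight-file layout (one hidden neuron per row: four input weights, the
output weight, the hidden bias; the output bias in the first row's last
column, `/` elsewhere).

The GA minimises `fitness = max(MAE_train, MAE_test)` over a seeded
27/3 cross-validation split — a minimax criterion that penalises
memorisation. Design choices that matter:

- **Gene box [−30, 30]** so published solutions with large weights
  (entries up to ±28) stay representable, but **initial sampling on
  [−1, 1]**: genes drawn uniformly over the whole box saturate every
  tanh, zeroing the gradients the polish needs.
- **Lamarckian polish**: each individual gets 20 epochs of backprop
  (step 0.1) on the training split before evaluation; a divergent
  descent returns the genome unchanged. `polish_epochs=0` gives a
  pure-GA search.
- **Mutation sd 0.3 absolute** (scale 0.005 of the 60-unit range):
  weight perturbations act before a tanh, so steps proportional to the
  full box would be destructive.
- **Final refinement**: the best genome gets `bp_epochs` (default 500)
  further epochs and is kept only if the minimax fitness does not
  worsen.

Paired over seeds on the study data, this hybrid achieves a lower median
minimax fitness than plain backprop with a comparable epoch budget — the
study's central claim, asserted as a seeded test. The published per-cell
scan values and the 381.24 mg optimum prediction are single unseeded
realizations with an unrecorded response-scaling convention and are not
reproduced as golden numbers; the published weight table's forward pass
is instead pinned to an independently hand-computed oracle value.

## Condition optimization

Any coded-point → mg callable can be maximised over the coded box
(default [−2, 2]⁴, the full physical ranges — the fitted surface's
optimum sits on that boundary, so the search is not restricted to the
factorial core). The search is a memetic GA: each individual is refined
by a deterministic projected-gradient ascent (central-difference
gradient, backtracking line search, default 15 iterations) before
evaluation. This matters because the pruned surface has two competing
optima at opposite corners of the x₃x₄ interaction separated by only
2 mg (0.5 %): a plain GA at the fixed budget of population 30 × 12
generations commits to whichever basin leads early and picks the wrong
corner in a substantial fraction of seeds, while with the polish every
first-generation individual settles into its own basin's exact optimum
and the comparison between basins is made at full precision. With it,
seeded runs match the closed-form optimum to well under 0.5 mg.

For quadratic surrogates `quadratic_optimum_closed_form` enumerates all
3⁴ assignments of each coordinate to {lower bound, upper bound, free},
solving the stationary system on each free set — every KKT point of a
quadratic on a compact box is visited, so the result is exact and serves
as the GA's independent oracle.

## Synthetic data

`generate_quadratic_dataset` evaluates a known polynomial (default: the
study's fitted reduced surface) on the standard CCD and adds i.i.d.
Gaussian noise on the mg scale; `generate_network_dataset` does the same
through a known network. Defaults mirror the study conditions: noise sd
√64.87 ≈ 8.05 mg, the residual scale of the real fit; 6 centre
replicates; ground truth always returned (and serialisable) next to the
data. The generator emulates homoscedastic replicate noise only — no
heteroscedasticity, drift, run-order effects, or measurement-chain
(calibration-curve) error — so passing recovery tests demonstrate
correctness of the estimators under the model's own assumptions, not
robustness to real-world violations of them.

Calibration and recovery are tested: fitted residual mean square scatters
around the injected variance; all 15 coefficients fall within 4 proper
standard errors of truth in ≥95 % of 200 seeded replicates; data from a
known 3-neuron network selects H ≥ 3 in ≥80 % of seeded scan repeats.
For the hybrid-recovery property the noise sd is set to 5 mg: the
minimax fitness is a max statistic over 30 runs, whose irreducible floor
is about twice the noise sd, and at much smaller sd the (absolute)
optimizer error rather than the statistic dominates; 5 mg is small
relative to the ~80 mg response spread and below the real data's 8 mg
residual scale.

## Numerical conventions and limitations

- Golden-value tests compare after rounding to the precision the value
  is printed with; property tests use explicit tolerances stated inline.
- Rank deficiency of the model matrix raises naming the collinear terms;
  a leverage of 1 makes PRESS undefined and is reported as such (the
  ANOVA then carries pred-R² = NaN).
- The RSD of centre replicates uses the sample (n−1) standard deviation.
- Only 4-factor CCDs are built natively (k-factor generalisation is an
  extension point); no fractional-factorial or Box–Behnken designs, no
  blocking, no response transformations, no momentum/second-order
  network optimizers, no multi-objective GA.
- Problem sizes in the test suite (e.g. 20-seed GA sweeps, 50-seed
  recovery runs, 200-replicate coefficient recovery) were chosen so the
  whole suite exercises every stochastic claim while remaining a
  few-minute desk run.
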