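# Methods

## Model

The package predicts an individual survival time in two stages under a
proportional-hazards assumption, h(t | x) = h₀(t) · exp(h(x)).

**Hazard ratio network.** h(x) is a fully connected network (reference
configuration: hidden widths 64–32–32, ReLU, scalar linear output, Xavier
uniform initialization, dropout 0.5 on the third layer only). It is trained by
full-batch Adam on the Cox negative log partial likelihood; the partial
likelihood eliminates h₀(t), so the baseline hazard is never estimated. The
risk set of subject i is {j : T_j ≥ T_i} (a subject is at risk at its own
event time), and tied event times share one risk set (Breslow). The loss is
implemented as a sum over events with a log-sum-exp shift; an option divides
by the number of events for learning-rate stability (off by default). Since
risk sets couple every row, minibatching would bias the objective; training is
full-batch, which the cohort sizes used here (10²–10⁴ rows) make cheap.

**Distribution function network.** A second network of the same architecture
outputs a per-subject positive scalar y_pred(x). With the hazard network
frozen (its weights are read once and never written — callers can verify via
`weights_hash()`), y_pred is trained on

    mean over included subjects of ( y_i − y_pred(x_i) / exp(h(x_i)) )²,

and the predicted survival time is ŷ(x) = y_pred(x) / exp(h(x)).

*Censored subjects are excluded from this loss by default.* A censored time is
a lower bound on the death time, so squared error against it would bias
y_pred downward; `include_censored=True` exists for ablation and logs a
warning. Excluding them still leaves a selection bias (uncensored subjects die
earlier on average), which shows up as predicted curves lying somewhat below
the ground-truth KM curve; the fixed-distribution comparators are fitted on
the same subjects and inherit the same bias, keeping the comparison fair.

Two numerical guards: log-risks are clipped at ±50 before exponentiation, and
the distribution net's raw output passes through softplus times a fixed scale
(the mean of y·exp(h) over the training subjects) so y_pred is strictly
positive and starts at the right order of magnitude regardless of the time
unit. Without the scale, a network initialized near zero would need thousands
of epochs merely to reach the magnitude of typical survival times.

## Optimization defaults

`NetworkSpec` defaults to Adam with learning rate 1e-5, epochs ≤ 2000, early
stopping on a 20% validation split with patience 100, seeding every source of
randomness (initialization, dropout, splits). The 1e-5 rate is the reference
setting for this architecture; it suits long training schedules. For the
full-batch regime and the cohort sizes exercised in the examples, tests and
the acceptance script, we pass `learning_rate=1e-2, epochs=1500`, which Adam's
step normalization makes stable and which converges in a few hundred epochs
(the early-stopping rule usually triggers well before the epoch cap). The
stopping rule and validation split are this package's choices; predictions are
deterministic at inference (dropout off).

## Evaluation metrics

**KM-curve IoU.** Predicted times are treated as fully observed events (the
model outputs times, not censoring), their Kaplan–Meier curve is compared
with the KM curve of the observed test data (which keeps real censoring
flags), and IoU = area(min of curves) / area(max of curves). Areas are
left-endpoint rectangle sums with grid spacing dx = 0.1 (configurable); the
shared horizon is the larger of the two curves' last observed times, each
curve extended beyond its last breakpoint at its final value (standard KM
plotting convention). Discretization error is bounded by dx per breakpoint
jump and vanishes as dx → 0; since both curves start at 1 the union area is
always positive.

**RMSE and Lin's CCC** are computed on uncensored test subjects only — a
censored time is not a ground-truth death time. CCC is implemented in its
standard form, 2·cov / (var + var + mean-gap²), which matches the intended
±1 = perfect concordance / 0 = none reading.

KM estimation itself delegates to lifelines' product-limit estimator behind
the `StepCurve` type; the test suite checks it against an independently coded
brute-force implementation on hundreds of random small datasets.

## Synthetic cohorts

`simulate_cohort` draws covariates uniformly on [0, 1]ᵖ and event times by
inverse transform through the cumulative baseline hazard scaled by
exp(β·x) — exactly the proportional-hazards structure the model assumes, for
exponential, Weibull (shape k, scale λ, cumulative hazard (t/λ)ᵏ) and
Gompertz (shape η, rate b, hazard b·e^{ηt}) baselines. Censoring is
independent exponential with the rate solved numerically (Brent) so the
expected censored fraction matches the requested rate given the realized
event times; this is the simplest mechanism satisfying random right
censoring. The reference conditions used throughout examples and acceptance
are n = 1000–2000, p = 5, β = (1, −1, 0.5, 0, 0), exponential baseline with
mean 100 time units, 30% censoring.

What the generator does *not* emulate: correlated or non-uniform covariates,
nonlinear or interaction effects on the log-hazard, informative censoring,
and measurement noise. Passing recovery tests therefore demonstrates the
machinery is correct under the model's own assumptions, not that it matches
clinical data behavior.

## Fixed-distribution comparators

The classical route draws a numerator u from a fixed family and emits
T = u / exp(h). Samplers use closed-form inverse CDFs (Gompertz:
t = ln(1 − (η/b)·ln(1−U)) / η) from seeded uniforms. The reference comparison
never specifies how the comparators' parameters are chosen; this package fits
them by maximum likelihood to the reconstructed numerators T·exp(h) of the
uncensored training-fold subjects (exponential: closed form; Weibull and
Gompertz via scipy with location fixed at 0) — one defensible convention,
applied uniformly.

**A deliberate honesty note on the head-to-head.** On synthetic data whose
generating family is among the comparators, the correctly-specified
comparator reproduces the true marginal time distribution stochastically, so
its predicted KM curve nearly coincides with the truth and its IoU is hard to
beat; the integrated model predicts a deterministic conditional-mean-like
time whose cohort distribution carries only covariate-driven spread, giving a
steeper KM curve and a lower IoU, even while it clearly wins on per-subject
RMSE. The corresponding end-to-end IoU-superiority test in the acceptance
suite documents this: it encodes the qualitative claim and currently fails
under well-specified synthetic truth. On real cohorts no comparator is
correctly specified, which is the regime where the integrated model's
advantage was originally observed.

## Grad-CAM for dense networks

Grad-CAM weights a layer's activations by the gradient of the output with
respect to them and rectifies. For a dense network on tabular data the first
hidden layer serves as the "feature map" — it is the only layer linearly tied
to named input features — and unit importances are projected back to features
through the absolute first-layer weights |W₁|. Each patient's attribution
vector is L1-normalized before averaging so patients contribute equally to
the cohort-level importances; networks with no hidden layer fall back to
rectified gradient×input. These are documented conventions for the 1D
extension, validated against permutation importance in the tests. The heat
map table orders patients by predicted survival time descending, ties broken
by original index.

## Cross-validation, grid search, reproducibility

`run_cv_experiment` applies k-fold CV (k = 5, i.e. 80/20) with per-fold
seeds derived deterministically from the global seed: per fold it trains both
networks and fits all comparator families on the training fold only, then
scores the test fold. Aggregates are plain means of per-fold values; folds
whose training part has no events are skipped with a warning. `grid_search`
enumerates {hidden layers 2–7} × {sizes 8, 16, 32, 64} × {sigmoid, relu,
tanh} × {dropout 0, 0.3, 0.5, 0.7, 0.9} (the continuous ranges discretized)
and selects by each network's own validation objective; a cap on the number
of configurations is available. The whole pipeline — simulate, train,
evaluate, explain — is bit-reproducible under a fixed global seed, which the
acceptance suite asserts by byte-comparing two complete runs.

## Known limitations

- The method emits one point time per subject, not a per-subject survival
  distribution S_i(t).
- Excluded-censored training biases predictions toward uncensored subjects'
  times (see above); no imputation of censored times is attempted.
- Very deep configurations can fail to converge under the Cox loss; the grid
  search's validation objective is the only guard.
- Tied event times use Breslow's approximation; with heavy ties Efron's
  correction would be more accurate but is not implemented.
- Time units are opaque; no calendar parsing or time-dependent covariates.
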