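# Methods

This note records the model, the training strategy, the choices made where
the design was genuinely open, and what the bundled synthetic experiments do
and do not demonstrate.

## Problem setting

A record is a strictly time-ordered sequence of multivariate observations
`x_1 … x_M` at times `t_1 … t_M`, with an observation mask (clinical
variables are measured irregularly and incompletely) and a single class
label fixed at the final time.  Continuous classification asks for a class
score at *every* prefix of the record.  We realise this by expanding a
cohort into a **prefix task stream**: for cut fractions
`f_1 < … < f_K = 1`, task `m` holds every record truncated to
`max(1, round_half_up(f_m · M))` observations.  Each task is treated as one
data distribution; a model trained through the stream in order experiences
the distribution drift a deployed model sees as records lengthen.  Tasks can
also be visited in a greedy similarity order (nearest-neighbour chaining on
per-task mean feature vectors, ties by original index); this ordering is an
approximation chosen for determinism and simplicity.

Missing cells are forward-filled within record, with the per-variable
dataset mean (0 if never observed) for leading gaps; masks are retained so
diagnostics can distinguish observed from imputed values.  Timestamps keep
their native units; the elapsed-time discount below is scale-sensitive, so
rescaling time rescales the model's memory horizon.

## Time-aware LSTM

Before each step the previous memory is decomposed as
`C^S = tanh(W_d C_{m−1} + b_d)`, `C^T = C_{m−1} − C^S`; the short-term part
is discounted by `g(Δ) = 1/ln(e + Δ)` (natural log, so `g(0) = 1` exactly
and the cell reduces to a plain LSTM at zero gap), and the adjusted memory
`C* = C^T + g(Δ)·C^S` feeds standard forget/input/candidate/output gate
arithmetic.  A subtraction convention `C* = C^T − g(Δ)·C^S` is exposed as
`memory_mode="subtract"` for comparison; addition is the default because it
is the convention under which the zero-gap reduction holds.  The head is one
tanh affine layer followed by an affine map to class logits and softmax.
Parameters are initialised uniformly in ±1/√H from an explicit seed.

All gradients are hand-written reverse-mode numpy (the forward pass caches
per-step activations; a backward sweep accumulates parameter gradients,
with padded batch rows carrying state through unchanged).  The test suite
pins them against central finite differences at relative tolerance 1e-4 in
both memory modes.

## Restricted-update training

Two mechanisms modify plain sequential minibatch training; with both
disabled the loop is bit-identical to plain SGD at the same seed, which is
the naive fine-tuning reference.

**Limitation (LM).**  After finishing task `m`, the diagonal empirical
Fisher information of each parameter is estimated as the mean over records
of the squared gradient of the observed label's log-probability, and `F` is
the running mean of these per-task contributions.  While training the next
task the loss carries `λ Σ_i F_i (θ_i − θ_i^{m−1})²` with the anchor at the
previous task's parameters.  Because Fisher information adds over a task's
independent records, the trainer scales the per-observation `F` by the mean
task record count — the penalty then approximates the Laplace weight of the
old data, under which `λ = 1/2` (the default) is the exact second-order
coefficient.  Under plain SGD an arbitrarily stiff quadratic is unstable,
so on that path the per-coordinate stiffness is capped at `0.5/lr`, the
stability limit of gradient descent on a quadratic; the Frank–Wolfe path
needs no cap because its steps are direction-normalised and bounded.

**Promotion (PM).**  Updates are projection-free Frank–Wolfe steps over the
L2 ball of radius `D_K` (default `10·‖θ_0‖ + 10`) centred at the initial
parameters: the linear minimisation oracle returns
`v = center − D_K · d/‖d‖`, and the iterate moves `θ ← θ + η_m (v − θ)`.
The driving direction is the variance-reduced recursive estimator
`d_m = ∇O(θ_m, ξ_m) + (1 − ρ_m)(d_{m−1} − ∇O(θ_{m−1}, ξ_m))`, where the
memory term is the gradient of the same objective at the previous iterate
on the current minibatch.  Recomputing that term (one extra backward pass
per round) is essential: substituting the previous *update direction* —
whose norm is of order `D_K`, orders of magnitude above gradient scale —
makes the estimator diverge, which we verified empirically before fixing
the construction.  Both `ρ` and `η` follow `(1/(m+1))^a` in the optimizer
round counter `m` (counted from 0 across the whole stream, so later tasks
take smaller steps); `a` defaults to the empirical relation
`a = 0.933·λ + 0.907`.  The recursion index deliberately counts optimizer
rounds while the LM anchor counts tasks: one update per distribution cannot
train a network, and the online-optimisation framing applies per round.

The gradient-sign series recorded for the fluctuation metric is the
gradient the trainer actually follows — the estimator `d` under PM, the raw
minibatch gradient under SGD.

Defaults: λ = 0.5, a = "auto", 20 epochs per task, batch 32, SGD learning
rate 0.05 (PM-disabled path only), Fisher sample 256 records per task, all
seeds explicit.  The per-task score matrix `R` uses AUC for binary problems
(0/1 accuracy otherwise), evaluated on each task's own records; `b̄` is one
random-initialisation evaluation per distribution at the run seed.

## Metrics

AUC-ROC is computed in its rank (Mann–Whitney) form with midrank ties; the
confidence interval is the Hanley–McNeil normal approximation.  Backward
transfer averages `R[last, i] − R[i, i]` over earlier distributions;
forward transfer averages `R[i−1, i] − b̄_i`.  Gradient fluctuation maps
each per-round gradient coordinate to a sign (zeros inherit the previous
sign, a leading zero counts +1) and averages
`(1/(n−1)) Σ (d_i − d_{i−1})²` over coordinates; it lies in [0, 4].  The
Bonferroni–Dunn critical difference is `q·√(k(k+1)/(6N))`, with the strict
decision rule `r̄_other − r̄_best > CD`.

Two printed values in the surrounding literature for k=6, N=10 (CD = 2.16
where the formula gives 2.24) and a k=2 average rank of 1.33 (impossible,
since two-method ranks must average to 1.5) are arithmetic inconsistencies;
they are not reproduced.  The reference interval printed alongside one
reported AUC is likewise not derivable from the plug-in formula with the
stated group sizes, so the interval routine is validated against its own
formula only.

## Interpretation: importance, stages, biomarkers

A feature's overall importance `α*(x_d)` is the summed Fisher importance of
the four gate input-weight columns touching it; gate importance sums each
gate's W, U and b; neuron importance sums a neuron's outgoing head weights.
Normalised profiles (unit total mass) make snapshots comparable across
tasks and invariant to positive rescaling of the Fisher.

Stage discovery segments the per-task importance trajectory with Bayesian
online changepoint detection under a constant hazard (expected run length
10 tasks) and a Normal–Gamma conjugate model (Student-t predictive; priors:
μ₀ = mean of the first 3 snapshots, κ₀ = 1, α₀ = 1, β₀ = series variance,
all overridable).  Two choices matter and were made after measurement:

* The trajectory fed to the detector is the per-task Fisher *contribution*
  (the task's own mean squared gradients), not the running mean, whose 1/m
  damping hides reorganisation.
* The detector runs on the normalised profile sequence itself, multivariate
  via independent Normal–Gamma models per dimension sharing one run length.
  Reducing the trajectory to the scalar series of consecutive-difference
  norms turns each boundary into a single-point outlier, which a mean-shift
  observation model cannot segment; that scalar series is still computed
  and exposed as a diagnostic (`StageAssignment.diffs`).

A changepoint is declared when the run-length posterior mode drops below
its previous value with more than 0.5 posterior mass below that mode, and
is located at the start of the new run (`t − mode_t`).  A record's prefix at
task `m` belongs to the stage containing task `m` (task-axis mapping), from
which the monotone staging rate follows; representation-space clustering is
deliberately out of scope.  Biomarkers per stage are the features with the
largest stage-averaged normalised `α*`, ties broken by index.

## Synthetic cohorts

The generator emulates the structure of multi-stage clinical cohorts:
class-conditional Gaussian feature means shifted piecewise-constantly over
fractional-position stages (effect sizes in within-stage SD units), AR(1)
within-record noise (φ = 0.5) so prefixes carry temporal signal,
exponential sampling gaps, Bernoulli missingness, and configurable class
balance.  "Congenital" markers (always-informative) separate classes in
every stage; "acute" markers (late-informative) activate only in the final
stage.  Ground truth (boundaries, shift matrix, per-stage Bayes AUC
`Φ(‖δ‖/√2)`) accompanies every cohort.

Named fixtures define the study conditions used by the acceptance tests:

* `forgetting-2d` — 400 records, D = 10, two stages whose feature-0 shift
  flips sign (+2σ/−2σ), prefix tasks at 50% and 100%; calibrated so naive
  sequential training forgets the first distribution (median BWT ≈ −0.33
  over seeds 0–4 at 10 epochs/task, H = 16).
* `staging-4` — 320 records, four stages with distinct informative feature
  pairs plus one always- and one late-informative feature, 16 uniform cut
  fractions; trained at 12 epochs/task with full-cohort Fisher sampling for
  the stage-recovery experiments.
* `null` — no class signal.

Problem sizes (n of a few hundred, H = 16, ~10 epochs per task) are chosen
so the full experiment grid — four trainer variants × five seeds on the
forgetting fixture, five staging runs — completes in a few minutes on one
CPU while leaving the qualitative effects far from threshold.

What passing these tests shows: the mechanisms behave as designed on data
matching the generator's assumptions (Gaussian shifts, stagewise drift,
moderate dimensionality).  What they do not show: performance on real vital
signs, whose missingness is informative, whose noise is non-Gaussian and
non-stationary, and whose class structure is not linear-Gaussian; no claim
about specific diseases or stage counts in real cohorts is made or tested.

## Numerical and degenerate-input conventions

Strictly increasing timestamps are enforced; the first elapsed gap is 0 by
convention.  Prefix rounding is round-half-up floored at one observation.
Probabilities are clamped at 1e-12 inside cross-entropy with a warning.
The linear minimisation oracle returns the ball center when ‖d‖ < 1e-12;
the schedule value is floored at 1e-300 to survive extreme exponents.  A
non-finite training loss aborts with the task and round named.  Constant
importance trajectories yield a single stage; degenerate AUCs (0 or 1)
yield zero-width confidence intervals with a warning.

## Known limitations

* The trainer assumes parameters addressable by name and a differentiable
  loss; only the time-aware LSTM backbone is provided (the extension point
  for other backbones is the parameter-dict contract).
* The similarity task ordering is a stand-in heuristic, not a canonical
  procedure.
* Fisher importance is a diagonal approximation; correlated-parameter
  importance is invisible to both the penalty and the interpretation.
* BOCD staging needs several tasks per stage to calibrate its predictive;
  with very short streams (fewer than ~3 tasks per stage) boundaries blur,
  and the first boundary after the initial learning transient is the
  hardest to localise.
* The acute-angle condition between task gradients is implemented as a
  diagnostic only; it is not an executable projection step in the trainer.
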