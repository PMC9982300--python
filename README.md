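# ccts — continual training for continuous classification of clinical time series

Bedside prediction models face a problem that single-shot classifiers do not:
a patient's record grows over time, its statistical character drifts as the
illness progresses, and the model is expected to score *every* prefix of the
record — hours or days before the label (sepsis onset, mortality, discharge
diagnosis) is fixed at the final time.  Training a recurrent classifier
sequentially on prefixes of increasing length treats each prefix length as
its own data distribution, and ordinary fine-tuning then forgets the early
distributions exactly when they matter most for early warning.

`ccts` implements a **restricted update** (RU) training strategy for this
*continuous classification of time series* setting, together with the
surrounding machinery needed to study it end to end:

* **Data model** (`ccts.data`) — irregularly sampled multivariate records
  with observation masks and final-time labels, long-format CSV I/O, and the
  *prefix task stream*: datasets `T*_m` holding every record truncated at a
  growing fraction of its own length, in time order or a greedy
  similarity order.
* **Classifier** (`ccts.tlstm`) — a time-aware LSTM: the memory cell is
  split into a learned short-term part `C^S = tanh(W_d C + b_d)` and its
  complement, and the short-term part is discounted by
  `g(Δ) = 1 / ln(e + Δ)` for the elapsed time Δ between observations, so
  long sampling gaps wash out short-term memory.  An MLP head maps the final
  hidden state to class probabilities.  Forward pass and reverse-mode
  gradients are hand-written numpy, verified against finite differences.
* **Trainer** (`ccts.ru`) — the two RU mechanisms:
  * *Limitation*: after each task the diagonal empirical Fisher information
    `F_i = (1/m) Σ_k (∂ log p(D_k|θ_i)/∂θ_i)²` scores parameter importance,
    and the next task's loss carries the quadratic penalty
    `λ Σ_i F_i (θ_i − θ_i^{m−1})²` anchoring important parameters.
  * *Promotion*: projection-free Frank–Wolfe steps over an L2 ball, driven
    by the variance-reduced recursive estimator
    `d_m = ∇O_m + (1 − ρ_m)(d_{m−1} − g_{m−1})` with the diminishing
    schedule `ρ_m = η_m = (1/(m+1))^a`.

  Disabling both mechanisms yields bit-identical plain sequential SGD — the
  naive fine-tuning baseline used in the ablations.
* **Metrics** (`ccts.metrics`) — AUC-ROC (Mann–Whitney form) with the
  Hanley–McNeil confidence interval, backward/forward transfer over the
  task-by-task score matrix `R_{i,j}`, gradient-sign fluctuation, average
  ranks and the Bonferroni–Dunn critical difference `CD = q·√(k(k+1)/6N)`.
* **Interpretation** (`ccts.interpret`) — block-wise importance aggregation
  (per input feature, per LSTM gate, per head neuron), Bayesian online
  changepoint detection over the per-task importance trajectory to discover
  *stages*, per-stage biomarker ranking, stage profiles and the monotone
  staging rate.
* **Synthetic cohorts** (`ccts.synthetic`) — a generator of irregular,
  partially missing, AR(1)-correlated records whose class-conditional means
  shift in known piecewise stages, with named fixtures (`forgetting-2d`,
  `staging-4`, `null`) used throughout the tests.

## Worked example

Train naive fine-tuning and the restricted update on the bundled two-stage
fixture, in which the class-separating direction of the first feature flips
sign between the early and the late half of every record:

```python
import numpy as np
from ccts import synthetic, data, tlstm, ru, metrics

spec = synthetic.standard_streams()["forgetting-2d"]
cohort, truth = synthetic.generate(spec.generator)          # 400 records, D=10
stream = data.build_prefix_stream(cohort, spec.cut_fractions)  # tasks at 50%, 100%

for label, flags in [("naive fine-tuning", dict(lm_enabled=False, pm_enabled=False)),
                     ("restricted update", {})]:
    params = tlstm.init_params(cohort.n_features, 16, 2, head_hidden=16, seed=0)
    cfg = ru.RUConfig(epochs_per_task=10, seed=0, **flags)
    params, hist = ru.train_ru(params, stream, cfg)
    print(f"{label:18s} R = {np.round(hist.R, 3).tolist()}  "
          f"BWT = {metrics.bwt(hist.R):+.3f}  "
          f"grad fluctuation = {metrics.gradient_fluctuation(hist.signs_matrix()):.2f}")
```

prints

```
naive fine-tuning  R = [[0.874, 0.026], [0.599, 0.998]]  BWT = -0.275  grad fluctuation = 1.11
restricted update  R = [[0.67, 0.82], [0.669, 0.825]]  BWT = -0.002  grad fluctuation = 0.05
```

`R[i][j]` is the AUC on prefix distribution `j` after finishing task `i`.
Naive fine-tuning reaches AUC 0.874 on the half-length distribution, then
drops to 0.599 after learning the full-length one — backward transfer
−0.275, the signature of catastrophic forgetting.  The restricted update
holds its half-length performance essentially unchanged (BWT −0.002) and
follows a far steadier gradient (fluctuation 0.05 vs 1.11).

The same pipeline is available from the shell:

```sh
ccts simulate --fixture forgetting-2d --out sim --seed 0
ccts train --data sim/data.csv --labels sim/labels.csv --out run \
     --fractions 0.5,1.0 --seed 0
ccts evaluate --run-dir run --data sim/data.csv --labels sim/labels.csv
ccts interpret --run-dir run --data sim/data.csv --labels sim/labels.csv
```

## Documentation

`docs/methods.md` describes the model, the training strategy, every tunable
parameter with its default and rationale, what the synthetic generator does
and does not emulate, and the package's known limitations.
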