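"""Restricted-update training for a stream of prefix distributions.

Two mechanisms govern every optimizer round:

* **Limitation (LM).**  After finishing a task, the diagonal empirical Fisher
  information of the log-likelihood measures how much each parameter mattered
  to that distribution.  While learning the next task the loss carries a
  quadratic penalty ``lam * sum_i F_i (theta_i - anchor_i)^2`` pulling
  important parameters toward their values at the end of the previous task,
  which suppresses catastrophic forgetting.

* **Promotion (PM).**  Updates are projection-free Frank-Wolfe steps over an
  L2 ball around the initial parameters: a variance-reduced recursive
  gradient estimator ``d_m = grad_m + (1 - rho_m)(d_{m-1} - g_{m-1})`` feeds
  a linear minimisation oracle, and the iterate moves a fraction ``eta_m``
  toward the oracle point.  The memory term ``g_{m-1}`` is the gradient of
  the same objective at the *previous* iterate evaluated on the *current*
  minibatch (the recursive/SARAH construction), so ``d`` tracks the full
  gradient with vanishing variance as the steps shrink.  Both rho and eta
  follow the diminishing schedule ``(1/(m+1))^a`` in the optimizer-round
  counter m.

With both mechanisms disabled the loop is bit-identical to plain sequential
minibatch SGD, which serves as the naive fine-tuning reference.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from . import metrics, tlstm
from .data import PrefixTaskStream

__all__ = [
    "RUConfig",
    "ImportanceState",
    "PMState",
    "TrainingHistory",
    "resolve_a",
    "schedule",
    "regularized_loss",
    "update_fisher",
    "recursive_gradient",
    "linear_minimization_oracle",
    "pm_step",
    "acute_angle_check",
    "train_ru",
]


@dataclasses.dataclass
class RUConfig:
    """Hyper-parameters of the restricted-update trainer.

    ``a="auto"`` resolves the schedule exponent through the empirical linear
    relation a = 0.933 * lam + 0.907.  ``learning_rate`` is only used by the
    plain-SGD path taken when the promotion mechanism is disabled.
    """

    lam: float = 0.5
    a: object = "auto"
    epochs_per_task: int = 20
    batch_size: int = 32
    radius: Optional[float] = None  # L2 feasible-ball radius D_K
    seed: int = 0
    pm_enabled: bool = True
    lm_enabled: bool = True
    learning_rate: float = 0.05
    fisher_samples: int = 256
    class_weights: Optional[Sequence[float]] = None
    memory_mode: str = "add"
    score: str = "auc"  # R-matrix entry: "auc" or "accuracy"

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.epochs_per_task < 1:
            raise ValueError("epochs_per_task must be >= 1")


def resolve_a(config: RUConfig) -> float:
    if config.a == "auto":
        return 0.933 * config.lam + 0.907
    a = float(config.a)
    if a <= 0:
        raise ValueError("schedule exponent must be positive")
    return a


def schedule(m: int, a: float) -> float:
    """Diminishing step/mixing schedule (1/(m+1))^a, with m counted from 0."""
    if m < 0 or a <= 0:
        raise ValueError("need m >= 0 and a > 0")
    return float((1.0 / (m + 1)) ** a)


@dataclasses.dataclass
class ImportanceState:
    """Fisher-diagonal importance plus the anchor parameters of the previous
    task.  ``sq_sum`` accumulates per-task mean squared log-likelihood
    gradients; ``F`` is their running mean over the tasks seen so far.
    ``mean_task_size`` (running mean of task record counts) lets the trainer
    scale the per-observation Fisher up to the task's total information."""

    sq_sum: dict
    anchor: dict
    task_count: int = 0
    mean_task_size: float = 0.0

    @classmethod
    def zeros_like(cls, params: dict) -> "ImportanceState":
        return cls(sq_sum={k: np.zeros_like(v) for k, v in params.items()},
                   anchor={k: v.copy() for k, v in params.items()},
                   task_count=0)

    @property
    def F(self) -> dict:
        if self.task_count == 0:
            return {k: np.zeros_like(v) for k, v in self.sq_sum.items()}
        return {k: v / self.task_count for k, v in self.sq_sum.items()}

    def copy_F(self) -> dict:
        return {k: v.copy() for k, v in self.F.items()}


@dataclasses.dataclass
class _PenaltyView:
    """Precomputed per-coordinate penalty coefficients with their anchor,
    shaped like an :class:`ImportanceState` for the loss routine."""

    F: dict
    anchor: dict


@dataclasses.dataclass
class PMState:
    """State of the promotion mechanism: recursive estimator d, gradient
    memory g (gradient at the previous iterate on the current minibatch),
    round counter and the feasible L2 ball (center, radius)."""

    d_prev: np.ndarray
    g_prev: np.ndarray
    round: int
    radius: float
    center: np.ndarray

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def regularized_loss(params: dict, X, deltas, lengths, labels,
                     importance: ImportanceState, lam: float,
                     memory_mode: str = "add", class_weights=None) -> float:
    """Cross-entropy of the batch plus lam * sum_i F_i (theta_i - anchor_i)^2."""
    loss, _, _ = tlstm.loss_and_grads(
        params, X, deltas, lengths, labels, memory_mode=memory_mode,
        class_weights=class_weights, importance=importance, lam=lam)
    return loss


def update_fisher(importance: ImportanceState, task_data, params: dict,
                  n_samples: int = 256,
                  rng: Optional[np.random.Generator] = None,
                  memory_mode: str = "add") -> ImportanceState:
    """End-of-task importance refresh.

    The task's Fisher contribution is the mean, over up to ``n_samples``
    records, of the squared gradient of the observed label's log-probability;
    F becomes the running mean of contributions over tasks, and the anchor is
    reset to the current parameters.
    """
    records = list(task_data.records if hasattr(task_data, "records") else task_data)
    if not records:
        raise ValueError("empty task")
    n_total = len(records)
    if rng is not None and len(records) > n_samples:
        idx = rng.choice(len(records), size=n_samples, replace=False)
        records = [records[i] for i in idx]
    else:
        records = records[:n_samples]
    contrib = {k: np.zeros_like(v) for k, v in params.items()}
    for r in records:
        X, dt, lengths, labels = tlstm.batch_arrays([r])
        # grad log p(y) = -grad of the single-record cross-entropy
        _, grads, _ = tlstm.loss_and_grads(params, X, dt, lengths, labels,
                                           memory_mode=memory_mode)
        for k in contrib:
            contrib[k] += grads[k] ** 2
    n = len(records)
    new_sq = {k: importance.sq_sum[k] + contrib[k] / n for k in contrib}
    m = importance.task_count
    return ImportanceState(
        sq_sum=new_sq,
        anchor={k: v.copy() for k, v in params.items()},
        task_count=m + 1,
        mean_task_size=(importance.mean_task_size * m + n_total) / (m + 1))


def recursive_gradient(grad_now: np.ndarray, pm: PMState,
                       rho: float) -> np.ndarray:
    """Variance-reduced estimator d = grad_now + (1 - rho)(d_prev - g_prev);
    rho = 1 reduces to the instantaneous gradient."""
    if not 0.0 < rho <= 1.0:
        raise ValueError("rho must lie in (0, 1]")
    if grad_now.shape != pm.d_prev.shape:
        raise ValueError("shape mismatch with estimator state")
    return grad_now + (1.0 - rho) * (pm.d_prev - pm.g_prev)


def linear_minimization_oracle(d: np.ndarray, radius: float,
                               center: np.ndarray) -> np.ndarray:
    """Minimiser of <d, v> over the L2 ball: v = center - radius * d/||d||;
    a (near-)zero d returns the center."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    nrm = float(np.linalg.norm(d))
    if nrm < 1e-12:
        return center.copy()
    return center - radius * d / nrm


def pm_step(theta: np.ndarray, pm: PMState, d: np.ndarray, eta: float):
    """Frank-Wolfe promotion step: v from the oracle, direction g = v - theta,
    new iterate theta + eta * g.  Returns (theta_new, g)."""
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    v = linear_minimization_oracle(d, pm.radius, pm.center)
    g = v - theta
    return theta + eta * g, g


def acute_angle_check(g_new: np.ndarray, stored_grads) -> float:
    """Diagnostic: fraction of stored task gradients forming a non-obtuse
    angle (inner product >= 0) with the new update direction."""
    stored = list(stored_grads)
    if not stored:
        return 1.0
    return float(np.mean([float(np.dot(g_new, g)) >= 0.0 for g in stored]))


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrainingHistory:
    """Per-round and per-task records of one training run."""

    losses: list = dataclasses.field(default_factory=list)
    grad_signs: list = dataclasses.field(default_factory=list)  # int8 arrays
    round_task: list = dataclasses.field(default_factory=list)
    task_end_rounds: list = dataclasses.field(default_factory=list)
    param_snapshots: list = dataclasses.field(default_factory=list)
    importance_snapshots: list = dataclasses.field(default_factory=list)
    importance_contribs: list = dataclasses.field(default_factory=list)
    acute_fractions: list = dataclasses.field(default_factory=list)
    R: Optional[np.ndarray] = None
    b_bar: Optional[np.ndarray] = None
    cut_fractions: tuple = ()

    def signs_matrix(self) -> np.ndarray:
        return np.vstack(self.grad_signs)

    def accuracy_matrix(self) -> metrics.AccuracyMatrix:
        return metrics.AccuracyMatrix(R=self.R, b_bar=self.b_bar)

    def n_rounds(self) -> int:
        return len(self.losses)


def _task_tensors(task):
    return tlstm.batch_arrays(task.data.records)


def _score_task(params, task, config: RUConfig) -> float:
    probs = tlstm.predict_proba(params, task.data, config.memory_mode)
    labels = task.data.labels()
    if config.score == "auc" and probs.shape[1] == 2:
        return metrics.auc_roc(probs[:, 1], labels)
    return metrics.accuracy(probs.argmax(axis=1).astype(float), labels,
                            threshold=0.5)


def train_ru(params: dict, stream: PrefixTaskStream, config: RUConfig):
    """Train over the task stream with the restricted-update strategy.

    Returns ``(trained params, TrainingHistory)``.  The history carries the
    per-round losses and gradient signs, per-task parameter and importance
    snapshots, and the task-by-task score matrix R plus the random-init
    reference b_bar used by the transfer metrics.
    """
    if len(stream) == 0:
        raise ValueError("empty task stream")
    rng = np.random.default_rng(config.seed)
    a = resolve_a(config)
    vec = tlstm.ParamVector(params)
    theta = vec.flatten(params)
    params = vec.unflatten(theta)

    n_tasks = len(stream)
    hist = TrainingHistory(R=np.full((n_tasks, n_tasks), np.nan),
                           b_bar=np.zeros(n_tasks),
                           cut_fractions=stream.cut_fractions)
    for j, task in enumerate(stream):
        hist.b_bar[j] = _score_task(params, task, config)

    importance = ImportanceState.zeros_like(params)
    radius = (config.radius if config.radius is not None
              else 10.0 * float(np.linalg.norm(theta)) + 10.0)
    pm = PMState(d_prev=np.zeros_like(theta), g_prev=np.zeros_like(theta),
                 round=0, radius=radius, center=theta.copy())
    task_grads = []  # final update direction per task, for the angle diagnostic

    theta_prev = theta.copy()
    for ti, task in enumerate(stream):
        X, dt, lengths, labels = _task_tensors(task)
        n = X.shape[0]
        last_g = None
        use_lm = config.lm_enabled and importance.task_count > 0
        penalty = None
        if use_lm:
            # per-observation Fisher scaled to the previous tasks' total
            # information (Laplace weight of the old data); under plain SGD
            # the per-coordinate stiffness is capped at the stability limit
            # of gradient descent on a quadratic (lr * 2c < 1)
            lam_eff = config.lam * importance.mean_task_size
            cap = (0.5 / config.learning_rate if not config.pm_enabled
                   else np.inf)
            penalty = _PenaltyView(
                F={k: np.minimum(lam_eff * v, cap)
                   for k, v in importance.F.items()},
                anchor=importance.anchor)
        for _ in range(config.epochs_per_task):
            perm = rng.permutation(n)
            for s in range(0, n, config.batch_size):
                idx = perm[s:s + config.batch_size]
                loss_kw = dict(memory_mode=config.memory_mode,
                               class_weights=config.class_weights,
                               importance=penalty,
                               lam=1.0 if use_lm else 0.0)
                try:
                    loss, grads, _ = tlstm.loss_and_grads(
                        params, X[idx], dt[idx], lengths[idx], labels[idx],
                        **loss_kw)
                except FloatingPointError as e:
                    raise RuntimeError(
                        f"non-finite loss at task {ti} round {pm.round}") from e
                flat = vec.flatten(grads)
                hist.losses.append(loss)
                hist.round_task.append(ti)
                if config.pm_enabled:
                    # floor guards underflow of (1/(m+1))^a at extreme a
                    rho = max(schedule(pm.round, a), 1e-300)
                    eta = schedule(pm.round, a)
                    if rho < 1.0:
                        # gradient memory: same objective and minibatch at the
                        # previous iterate (variance-reduced recursion)
                        _, g_old, _ = tlstm.loss_and_grads(
                            vec.unflatten(theta_prev), X[idx], dt[idx],
                            lengths[idx], labels[idx], **loss_kw)
                        pm = dataclasses.replace(pm, g_prev=vec.flatten(g_old))
                    else:
                        pm = dataclasses.replace(pm, g_prev=flat)
                    d = recursive_gradient(flat, pm, rho)
                    theta_prev = theta.copy()
                    theta, g = pm_step(theta, pm, d, eta)
                    pm = dataclasses.replace(pm, d_prev=d,
                                             round=pm.round + 1)
                    last_g = g
                    # the estimator d is the gradient the update follows
                    hist.grad_signs.append(np.sign(d).astype(np.int8))
                else:
                    theta_prev = theta.copy()
                    theta = theta - config.learning_rate * flat
                    pm = dataclasses.replace(pm, round=pm.round + 1)
                    last_g = -flat
                    hist.grad_signs.append(np.sign(flat).astype(np.int8))
                params = vec.unflatten(theta)

        if last_g is not None:
            hist.acute_fractions.append(acute_angle_check(last_g, task_grads))
            task_grads.append(last_g)
        if config.lm_enabled:
            prev_sq = importance.sq_sum
            importance = update_fisher(importance, task.data, params,
                                       n_samples=config.fisher_samples,
                                       rng=rng, memory_mode=config.memory_mode)
            # this task's own Fisher contribution (running mean removed):
            # the importance profile *at* task ti, used for staging
            hist.importance_contribs.append(
                {k: importance.sq_sum[k] - prev_sq[k] for k in prev_sq})
        hist.task_end_rounds.append(pm.round)
        hist.param_snapshots.append({k: v.copy() for k, v in params.items()})
        hist.importance_snapshots.append(importance.copy_F())
        for j, other in enumerate(stream):
            hist.R[ti, j] = _score_task(params, other, config)

    return params, hist
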