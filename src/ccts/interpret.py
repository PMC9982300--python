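"""Importance-based interpretation: feature/gate/neuron attributions,
changepoint staging of the importance trajectory, biomarker ranking and
per-stage feature profiles.

The trainer leaves one Fisher-importance snapshot per task.  Aggregating
snapshot entries over structural blocks of the network attributes importance
to input features (all first-layer weights touching a feature), to the four
LSTM gates, and to individual head neurons.  Treating the per-task snapshots
as a sequence and segmenting it with Bayesian online changepoint detection
(BOCD) yields data-driven *stages*: contiguous runs of tasks over which the
model relied on a stable set of parameters.  Features with large normalised
importance within a stage act as that stage's biomarkers.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StageAssignment",
    "feature_importance",
    "gate_importance",
    "neuron_importance",
    "bocd_posterior",
    "detect_changepoints",
    "detect_stages",
    "rank_biomarkers",
    "stage_profiles",
    "monotone_staging_rate",
    "assign_prefix_stages",
    "plot_importance_heatmap",
]

_GATES = ("forget", "input", "cand", "output")


def _snapshot(ledger, task_index: int) -> dict:
    try:
        return ledger[task_index]
    except IndexError as e:
        raise ValueError(f"invalid task index {task_index}") from e


def feature_importance(ledger: Sequence[dict], task_index: int,
                       normalize: bool = False) -> np.ndarray:
    """Overall importance of each input feature at one task: the sum of
    Fisher importance over all first-layer (gate input) weights touching the
    feature, i.e. column d of every gate's W matrix."""
    F = _snapshot(ledger, task_index)
    total = sum(F[f"{g}.W"].sum(axis=0) for g in _GATES)
    if normalize:
        s = total.sum()
        if s > 0:
            total = total / s
    return np.asarray(total, float)


def gate_importance(ledger: Sequence[dict], task_index: int) -> dict:
    """Total importance of each gate group's parameters (W, U and b)."""
    F = _snapshot(ledger, task_index)
    return {g: float(F[f"{g}.W"].sum() + F[f"{g}.U"].sum() + F[f"{g}.b"].sum())
            for g in _GATES}


_LAYER_OUTGOING = {"encoder": "head.W1", "hidden": "head.W2"}


def neuron_importance(ledger: Sequence[dict], task_index: int,
                      layer: str) -> np.ndarray:
    """Importance of each neuron of a layer as the summed importance of its
    outgoing weights.  ``layer`` is "encoder" (T-LSTM hidden state feeding
    the head) or "hidden" (the head's hidden layer); the output layer has no
    outgoing weights and raises."""
    if layer == "output":
        raise ValueError("output layer has no outgoing weights")
    if layer not in _LAYER_OUTGOING:
        raise ValueError(f"unknown layer {layer!r}")
    F = _snapshot(ledger, task_index)
    return np.asarray(F[_LAYER_OUTGOING[layer]].sum(axis=0), float)


# ---------------------------------------------------------------------------
# Bayesian online changepoint detection
# ---------------------------------------------------------------------------

def bocd_posterior(x, hazard: float = 10.0, prior: Optional[dict] = None):
    """Run-length posterior of a series under a constant hazard 1/hazard and
    a Normal-Gamma conjugate observation model (Student-t predictive).

    ``x`` may be a scalar series (n,) or a vector series (n, D); for vectors
    the dimensions share the run length and carry independent Normal-Gamma
    models whose predictive densities multiply.  Returns an (n+1, n+1)
    matrix whose row t is the posterior over run lengths after seeing x[:t];
    every row sums to 1.
    """
    X = np.asarray(x, float)
    if X.ndim == 1:
        X = X[:, None]
    n, D = X.shape
    if n < 1:
        raise ValueError("empty series")
    if prior is None:
        mu0 = X[: min(3, n)].mean(axis=0)
        var = X.var(axis=0, ddof=1) if n > 1 else np.ones(D)
        prior = dict(mu0=mu0, kappa0=1.0, alpha0=1.0,
                     beta0=np.maximum(var, 1e-8))
    mu0 = np.broadcast_to(np.asarray(prior["mu0"], float), (D,)).copy()
    beta0 = np.broadcast_to(np.asarray(prior["beta0"], float), (D,)).copy()
    kappa0, alpha0 = float(prior["kappa0"]), float(prior["alpha0"])
    h = 1.0 / float(hazard)

    R = np.zeros((n + 1, n + 1))
    R[0, 0] = 1.0
    mu = mu0[None, :].copy()
    beta = beta0[None, :].copy()
    kappa = np.array([kappa0])
    alpha = np.array([alpha0])
    for t in range(n):
        scale = np.sqrt(beta * (kappa[:, None] + 1.0)
                        / (alpha[:, None] * kappa[:, None]))
        logpred = stats.t.logpdf(X[t], df=2.0 * alpha[:, None], loc=mu,
                                 scale=scale).sum(axis=1)
        pred = np.exp(logpred - logpred.max())
        growth = R[t, : t + 1] * pred * (1.0 - h)
        cp = float(np.sum(R[t, : t + 1] * pred * h))
        R[t + 1, 1: t + 2] = growth
        R[t + 1, 0] = cp
        R[t + 1] /= R[t + 1].sum()
        # posterior parameter update, prepending the prior for run length 0
        mu_new = (kappa[:, None] * mu + X[t]) / (kappa[:, None] + 1.0)
        beta_new = beta + (kappa[:, None] * (X[t] - mu) ** 2
                           / (2.0 * (kappa[:, None] + 1.0)))
        mu = np.vstack([mu0, mu_new])
        beta = np.vstack([beta0, beta_new])
        kappa = np.concatenate([[kappa0], kappa + 1.0])
        alpha = np.concatenate([[alpha0], alpha + 0.5])
    return R


def detect_changepoints(x, hazard: float = 10.0,
                        prior: Optional[dict] = None) -> list:
    """Changepoint indices of a (scalar or vector) series from the BOCD
    run-length posterior: a changepoint is declared where the run-length
    mode drops below its previous value with more than 0.5 posterior mass
    below that previous mode; the reported location is the start of the new
    run, ``t - mode_t`` (a run of length r at time t began at index t - r)."""
    X = np.asarray(x, float)
    n = X.shape[0]
    R = bocd_posterior(X, hazard=hazard, prior=prior)
    modes = R.argmax(axis=1)
    cps = []
    for t in range(2, n + 1):
        prev_mode = modes[t - 1]
        if modes[t] < prev_mode and R[t, :prev_mode].sum() > 0.5:
            loc = t - int(modes[t])
            if not cps or loc > cps[-1]:
                cps.append(min(max(loc, 0), n - 1))
    return cps


@dataclasses.dataclass
class StageAssignment:
    """Stage segmentation of the task axis: ``changepoints[k]`` is the task
    index opening stage k+2; ``stage_per_task`` is 1-based and contiguous."""

    changepoints: list
    stage_per_task: np.ndarray
    diffs: np.ndarray
    record_stages: Optional[dict] = None
    monotone_fraction: Optional[float] = None

    @property
    def n_stages(self) -> int:
        return int(self.stage_per_task.max())


def _profile_matrix(trajectory) -> np.ndarray:
    """Per-task importance profiles as a (n_tasks, K) matrix, each row
    normalised to unit total mass.  Dict snapshots are aggregated to the
    input-feature block (see :func:`feature_importance`); arrays are used as
    given."""
    rows = []
    for snap in trajectory:
        if isinstance(snap, dict):
            v = sum(np.asarray(snap[f"{g}.W"], float).sum(axis=0)
                    for g in _GATES)
        else:
            v = np.asarray(snap, float).ravel()
        s = v.sum()
        rows.append(v / s if s > 0 else v)
    return np.vstack(rows)


def importance_change_series(trajectory) -> np.ndarray:
    """Scalar change series: L2 norm of the difference between consecutive
    normalised importance profiles (diagnostic companion to the stage
    segmentation)."""
    P = _profile_matrix(trajectory)
    return np.linalg.norm(np.diff(P, axis=0), axis=1)


def detect_stages(importance_trajectory, hazard: float = 10.0,
                  prior: Optional[dict] = None,
                  normalize: bool = None) -> StageAssignment:
    """Segment the per-task importance trajectory into stages.

    Dict snapshots (one Fisher snapshot per task) are reduced to normalised
    input-feature profiles; a raw array trajectory is used as given (set
    ``normalize=True`` to force row normalisation).  BOCD runs on the profile
    sequence — within a stage the model relies on a stable parameter profile,
    so stages appear as run-length growth and boundaries as posterior resets.
    A constant trajectory yields a single stage.
    """
    n_tasks = len(importance_trajectory)
    if n_tasks < 2:
        raise ValueError("need at least two snapshots")
    if isinstance(importance_trajectory[0], dict) or normalize:
        P = _profile_matrix(importance_trajectory)
    else:
        P = np.asarray(importance_trajectory, float)
        if P.ndim == 1:
            P = P[:, None]
    diffs = (np.linalg.norm(np.diff(P, axis=0), axis=1) if P.shape[1] > 1
             else np.abs(np.diff(P[:, 0])))
    if np.allclose(P, P[0]):
        cps = []
    else:
        cps = [c for c in detect_changepoints(P, hazard=hazard, prior=prior)
               if 0 < c < n_tasks]
    stage = np.ones(n_tasks, dtype=int)
    for c in cps:
        stage[c:] += 1
    return StageAssignment(changepoints=cps, stage_per_task=stage, diffs=diffs)


# ---------------------------------------------------------------------------
# Biomarkers and stage profiles
# ---------------------------------------------------------------------------

def rank_biomarkers(feature_importances, stage_per_task, top_k: int = 5):
    """Per stage, rank features by stage-averaged normalised importance.

    ``feature_importances`` is (n_tasks, D).  Returns a list (one entry per
    stage) of lists of (feature index, score) sorted by descending score,
    deterministic ties broken by feature index.
    """
    A = np.asarray(feature_importances, float)
    stage = np.asarray(stage_per_task, int)
    if A.shape[0] != stage.size:
        raise ValueError("one importance row per task required")
    D = A.shape[1]
    if top_k > D:
        warnings.warn(f"top_k={top_k} clipped to number of features {D}")
        top_k = D
    sums = A.sum(axis=1, keepdims=True)
    norm = np.where(sums > 0, A / np.maximum(sums, 1e-300), A)
    out = []
    for s in range(1, stage.max() + 1):
        avg = norm[stage == s].mean(axis=0)
        order = sorted(range(D), key=lambda d: (-avg[d], d))[:top_k]
        out.append([(d, float(avg[d])) for d in order])
    return out


def stage_profiles(dataset, stage_assignment: StageAssignment,
                   cut_fractions: Sequence[float],
                   features: Optional[Sequence[int]] = None) -> pd.DataFrame:
    """Per-stage, per-class mean and SD of each feature over the observations
    falling inside the stage's prefix window.

    Stage s spans the cut fractions of its tasks; an observation at position
    m of a record of length M (fractional position m/M) belongs to stage s if
    it falls in that window.  Returns a tidy frame with a class-difference
    column; empty strata are reported as NaN.
    """
    stage = stage_assignment.stage_per_task
    fr = np.asarray(cut_fractions, float)
    if fr.size != stage.size:
        raise ValueError("one cut fraction per task required")
    if features is None:
        features = range(dataset.n_features)
    # fraction window of each stage: (upper fraction of previous stage, upper]
    windows = {}
    for s in range(1, stage.max() + 1):
        hi = fr[stage == s].max()
        lo = fr[stage < s].max() if np.any(stage < s) else 0.0
        windows[s] = (lo, hi)

    rows = []
    for s, (lo, hi) in windows.items():
        per_class = {0: [], 1: []}
        for r in dataset:
            pos = (np.arange(1, r.n_obs + 1)) / r.n_obs
            sel = (pos > lo) & (pos <= hi)
            if sel.any():
                vals = np.where(r.mask[sel], r.values[sel], np.nan)
                per_class.setdefault(r.label, []).append(vals)
        for d in features:
            ms, sds, ns = {}, {}, {}
            for c, chunks in per_class.items():
                col = (np.concatenate([ch[:, d] for ch in chunks])
                       if chunks else np.array([]))
                col = col[np.isfinite(col)]
                ns[c] = col.size
                ms[c] = float(col.mean()) if col.size else np.nan
                sds[c] = float(col.std(ddof=1)) if col.size > 1 else np.nan
            rows.append(dict(stage=s, feature=int(d),
                             mean_class0=ms.get(0, np.nan),
                             sd_class0=sds.get(0, np.nan),
                             n_class0=ns.get(0, 0),
                             mean_class1=ms.get(1, np.nan),
                             sd_class1=sds.get(1, np.nan),
                             n_class1=ns.get(1, 0),
                             class_difference=ms.get(1, np.nan)
                             - ms.get(0, np.nan)))
    return pd.DataFrame(rows)


def assign_prefix_stages(stream, stage_per_task) -> dict:
    """Map every record's prefix sequence to stage ids: the prefix at task m
    belongs to the stage containing task m (task-axis mapping)."""
    stage = np.asarray(stage_per_task, int)
    out = {}
    for task_pos, task in enumerate(stream):
        for r in task.data:
            out.setdefault(r.record_id, []).append(int(stage[task_pos]))
    return out


def monotone_staging_rate(sequences) -> float:
    """Fraction of records whose stage sequence never decreases in time."""
    seqs = list(sequences.values()) if isinstance(sequences, dict) else list(sequences)
    if not seqs:
        return 1.0
    ok = 0
    for s in seqs:
        arr = np.asarray(s)
        if arr.size < 2 or np.all(np.diff(arr) >= 0):
            ok += 1
    return ok / len(seqs)


def plot_importance_heatmap(ledger, block: str, path,
                            layer: str = "encoder") -> None:
    """Task x unit importance heatmap for one block ("feature", "gate" or
    "neuron"), written as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_tasks = len(ledger)
    if block == "feature":
        M = np.vstack([feature_importance(ledger, t, normalize=True)
                       for t in range(n_tasks)])
        ylab = "input feature"
    elif block == "gate":
        M = np.vstack([list(gate_importance(ledger, t).values())
                       for t in range(n_tasks)])
        ylab = "gate"
    elif block == "neuron":
        M = np.vstack([neuron_importance(ledger, t, layer)
                       for t in range(n_tasks)])
        ylab = f"{layer} neuron"
    else:
        raise ValueError(f"unknown block {block!r}")
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(M.T, aspect="auto", interpolation="nearest")
    ax.set_xlabel("task")
    ax.set_ylabel(ylab)
    fig.colorbar(im, ax=ax, label="importance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
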