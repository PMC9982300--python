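"""Time-aware LSTM encoder with an MLP classification head, in plain numpy.

The cell is an LSTM variant for irregularly sampled sequences: before each
step the previous memory C_{m-1} is decomposed into a learned short-term part
C^S = tanh(W_d C_{m-1} + b_d) and its complement C^T = C_{m-1} - C^S.  The
short-term part is discounted by a decreasing function of the elapsed time
g(dt) = 1 / ln(e + dt), and the adjusted memory C* = C^T + g(dt) * C^S feeds
the ordinary LSTM gate arithmetic.  Long gaps therefore wash out short-term
memory while leaving long-term structure intact; at dt = 0 the cell reduces
exactly to a standard LSTM.

Reverse-mode gradients are implemented by hand (forward caches + backward
sweep) and are verified against central finite differences in the test suite.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional, Sequence

import numpy as np

from .data import Dataset, IrregularSeries, compute_deltas

__all__ = [
    "GATES",
    "CellState",
    "ParamVector",
    "init_params",
    "elapsed_weight",
    "tlstm_cell",
    "forward",
    "forward_batch",
    "predict_proba",
    "loss_and_grads",
    "batch_arrays",
    "save_params",
    "load_params",
]

GATES = ("forget", "input", "cand", "output")


@dataclasses.dataclass
class CellState:
    """Hidden state h and memory cell C of one step."""

    h: np.ndarray
    C: np.ndarray


def init_params(n_features: int, hidden: int, n_classes: int,
                head_hidden: int = 16, seed: int = 0,
                rng: Optional[np.random.Generator] = None) -> dict:
    """Uniform +-1/sqrt(H) initialisation of every parameter group.

    The returned dict maps hierarchical names to arrays::

        decomp.W (H,H)  decomp.b (H)          memory decomposition
        <gate>.W (H,D)  <gate>.U (H,H)  <gate>.b (H)   for forget/input/cand/output
        head.W1 (K,H)   head.b1 (K)           hidden head layer (tanh)
        head.W2 (C,K)   head.b2 (C)           logits
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    s = 1.0 / np.sqrt(hidden)
    u = lambda *shape: rng.uniform(-s, s, shape)
    p = {"decomp.W": u(hidden, hidden), "decomp.b": u(hidden)}
    for g in GATES:
        p[f"{g}.W"] = u(hidden, n_features)
        p[f"{g}.U"] = u(hidden, hidden)
        p[f"{g}.b"] = u(hidden)
    p["head.W1"] = u(head_hidden, hidden)
    p["head.b1"] = u(head_hidden)
    p["head.W2"] = u(n_classes, head_hidden)
    p["head.b2"] = u(n_classes)
    return p


class ParamVector:
    """Bijection between a named parameter dict and one flat vector."""

    def __init__(self, params: dict):
        self.names = list(params.keys())
        self.shapes = [params[k].shape for k in self.names]
        self.sizes = [int(np.prod(s)) if s else 1 for s in self.shapes]
        self.offsets = np.concatenate([[0], np.cumsum(self.sizes)])
        self.size = int(self.offsets[-1])

    def flatten(self, params: dict) -> np.ndarray:
        return np.concatenate([np.asarray(params[k], float).ravel()
                               for k in self.names])

    def unflatten(self, vec: np.ndarray) -> dict:
        out = {}
        for k, shape, o, n in zip(self.names, self.shapes,
                                  self.offsets[:-1], self.sizes):
            out[k] = vec[o:o + n].reshape(shape).copy()
        return out

    def slice_of(self, name: str) -> slice:
        i = self.names.index(name)
        return slice(int(self.offsets[i]), int(self.offsets[i] + self.sizes[i]))


def elapsed_weight(delta):
    """Memory discount g(dt) = 1 / ln(e + dt), natural log; g(0) = 1 and g is
    strictly decreasing toward 0."""
    d = np.asarray(delta, dtype=float)
    if np.any(d < 0):
        raise ValueError("elapsed time must be non-negative")
    out = 1.0 / np.log(np.e + d)
    return float(out) if np.isscalar(delta) or d.ndim == 0 else out


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _step(x, h_prev, C_prev, g_dt, p, memory_mode):
    """One batched cell step; all state arrays are (B, H), x is (B, D),
    g_dt is (B, 1).  Returns (h, C, cache)."""
    C_S = np.tanh(C_prev @ p["decomp.W"].T + p["decomp.b"])
    if memory_mode == "add":
        # C* = (C_prev - C_S) + g*C_S
        C_star = C_prev + (g_dt - 1.0) * C_S
    elif memory_mode == "subtract":
        C_star = C_prev - (1.0 + g_dt) * C_S
    else:
        raise ValueError(f"unknown memory_mode {memory_mode!r}")
    f = _sigmoid(x @ p["forget.W"].T + h_prev @ p["forget.U"].T + p["forget.b"])
    i = _sigmoid(x @ p["input.W"].T + h_prev @ p["input.U"].T + p["input.b"])
    o = _sigmoid(x @ p["output.W"].T + h_prev @ p["output.U"].T + p["output.b"])
    ctil = np.tanh(x @ p["cand.W"].T + h_prev @ p["cand.U"].T + p["cand.b"])
    C = f * C_star + i * ctil
    h = o * np.tanh(C)
    cache = dict(x=x, h_prev=h_prev, C_prev=C_prev, C_S=C_S, g_dt=g_dt,
                 C_star=C_star, f=f, i=i, o=o, ctil=ctil, C=C)
    return h, C, cache


def tlstm_cell(x, prev: CellState, delta: float, params: dict,
               memory_mode: str = "add") -> CellState:
    """Single cell step on vectors: x (D,), prev state (H,), elapsed time
    delta >= 0.  Raises on negative delta or shape mismatch."""
    x = np.asarray(x, float)
    h_prev = np.asarray(prev.h, float)
    C_prev = np.asarray(prev.C, float)
    H = params["decomp.b"].shape[0]
    if x.shape != (params["forget.W"].shape[1],):
        raise ValueError("input dimension mismatch")
    if h_prev.shape != (H,) or C_prev.shape != (H,):
        raise ValueError("state dimension mismatch")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(h_prev))
            and np.all(np.isfinite(C_prev))):
        raise ValueError("non-finite inputs")
    g = elapsed_weight(float(delta))
    h, C, _ = _step(x[None], h_prev[None], C_prev[None],
                    np.array([[g]]), params, memory_mode)
    return CellState(h=h[0], C=C[0])


def memory_decomposition(C_prev, params):
    """Return (C_S, C_T) with C_S + C_T = C_prev exactly (by construction)."""
    C_prev = np.asarray(C_prev, float)
    C_S = np.tanh(C_prev @ params["decomp.W"].T + params["decomp.b"])
    return C_S, C_prev - C_S


# ---------------------------------------------------------------------------
# Sequence forward / backward
# ---------------------------------------------------------------------------

def batch_arrays(records: Sequence[IrregularSeries]):
    """Pad records into (X, deltas, lengths, labels) batch tensors."""
    B = len(records)
    if B == 0:
        raise ValueError("empty batch")
    T = max(r.n_obs for r in records)
    D = records[0].n_features
    X = np.zeros((B, T, D))
    dt = np.zeros((B, T))
    lengths = np.zeros(B, dtype=int)
    labels = np.zeros(B, dtype=int)
    for b, r in enumerate(records):
        M = r.n_obs
        X[b, :M] = r.values
        dt[b, :M] = compute_deltas(r)
        lengths[b] = M
        labels[b] = r.label
    return X, dt, lengths, labels


def forward_batch(params: dict, X, deltas, lengths, memory_mode: str = "add",
                  return_cache: bool = False):
    """Run the cell over padded sequences.  Rows past a record's true length
    carry state forward unchanged, so the loop-final h equals each record's
    h at its own last observation.  Returns class probabilities (B, C)."""
    B, T, D = X.shape
    H = params["decomp.b"].shape[0]
    g = elapsed_weight(deltas)  # (B, T)
    h = np.zeros((B, H))
    C = np.zeros((B, H))
    caches = []
    for t in range(T):
        alive = (t < lengths).astype(float)[:, None]
        h_s, C_s, cache = _step(X[:, t], h, C, g[:, t:t + 1], params, memory_mode)
        cache["alive"] = alive
        h = alive * h_s + (1.0 - alive) * h
        C = alive * C_s + (1.0 - alive) * C
        caches.append(cache)
    z_pre = h @ params["head.W1"].T + params["head.b1"]
    z1 = np.tanh(z_pre)
    logits = z1 @ params["head.W2"].T + params["head.b2"]
    shifted = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(shifted)
    probs = expz / expz.sum(axis=1, keepdims=True)
    if return_cache:
        return probs, dict(caches=caches, h_final=h, z1=z1, probs=probs)
    return probs


def _backward_batch(params, cache, dlogits, memory_mode):
    """Backward sweep given d(loss)/d(logits); returns the gradient dict."""
    caches, h_final, z1 = cache["caches"], cache["h_final"], cache["z1"]
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    grads["head.W2"] = dlogits.T @ z1
    grads["head.b2"] = dlogits.sum(axis=0)
    dz1 = dlogits @ params["head.W2"]
    dz_pre = dz1 * (1.0 - z1 ** 2)
    grads["head.W1"] = dz_pre.T @ h_final
    grads["head.b1"] = dz_pre.sum(axis=0)
    dh = dz_pre @ params["head.W1"]
    dC = np.zeros_like(dh)
    for c in reversed(caches):
        alive = c["alive"]
        dh_t = dh * alive
        dC_t = dC * alive
        dh_carry = dh * (1.0 - alive)
        dC_carry = dC * (1.0 - alive)

        tC = np.tanh(c["C"])
        do = dh_t * tC
        dCn = dC_t + dh_t * c["o"] * (1.0 - tC ** 2)
        df = dCn * c["C_star"]
        dC_star = dCn * c["f"]
        di = dCn * c["ctil"]
        dctil = dCn * c["i"]

        pre = {
            "forget": df * c["f"] * (1.0 - c["f"]),
            "input": di * c["i"] * (1.0 - c["i"]),
            "output": do * c["o"] * (1.0 - c["o"]),
            "cand": dctil * (1.0 - c["ctil"] ** 2),
        }
        dh_prev = np.zeros_like(dh)
        for gname, dpre in pre.items():
            grads[f"{gname}.W"] += dpre.T @ c["x"]
            grads[f"{gname}.U"] += dpre.T @ c["h_prev"]
            grads[f"{gname}.b"] += dpre.sum(axis=0)
            dh_prev += dpre @ params[f"{gname}.U"]

        if memory_mode == "add":
            dC_S = dC_star * (c["g_dt"] - 1.0)
        else:
            dC_S = -dC_star * (1.0 + c["g_dt"])
        dC_prev = dC_star.copy()
        dpre_d = dC_S * (1.0 - c["C_S"] ** 2)
        grads["decomp.W"] += dpre_d.T @ c["C_prev"]
        grads["decomp.b"] += dpre_d.sum(axis=0)
        dC_prev += dpre_d @ params["decomp.W"]

        dh = dh_prev * alive + dh_carry
        dC = dC_prev * alive + dC_carry
    return grads


def loss_and_grads(params: dict, X, deltas, lengths, labels,
                   memory_mode: str = "add", class_weights=None,
                   importance=None, lam: float = 0.0):
    """Mean cross-entropy over the batch, optionally plus the importance
    penalty ``lam * sum_i F_i (theta_i - anchor_i)^2``, with its gradient.

    ``importance`` is any object exposing ``F`` and ``anchor`` dicts keyed
    like ``params`` (see :class:`ccts.ru.ImportanceState`).
    Returns (loss, grads dict, probs).
    """
    labels = np.asarray(labels, dtype=int)
    probs, cache = forward_batch(params, X, deltas, lengths, memory_mode,
                                 return_cache=True)
    B = probs.shape[0]
    if class_weights is None:
        w = np.ones(B)
    else:
        w = np.asarray(class_weights, float)[labels]
    wsum = w.sum()
    p_true = np.clip(probs[np.arange(B), labels], 1e-12, None)
    loss = float(-(w * np.log(p_true)).sum() / wsum)
    onehot = np.zeros_like(probs)
    onehot[np.arange(B), labels] = 1.0
    dlogits = (probs - onehot) * (w[:, None] / wsum)
    grads = _backward_batch(params, cache, dlogits, memory_mode)
    if importance is not None and lam > 0.0:
        F, anchor = importance.F, importance.anchor
        for k in params:
            diff = params[k] - anchor[k]
            loss += float(lam * np.sum(F[k] * diff ** 2))
            grads[k] += 2.0 * lam * F[k] * diff
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite loss")
    return loss, grads, probs


def forward(series: IrregularSeries, params: dict,
            memory_mode: str = "add") -> np.ndarray:
    """Class probability vector for one record (sums to 1)."""
    if series.n_obs < 1:
        raise ValueError("empty series")
    X, dt, lengths, _ = batch_arrays([series])
    return forward_batch(params, X, dt, lengths, memory_mode)[0]


def predict_proba(params: dict, dataset, memory_mode: str = "add",
                  batch_size: int = 256) -> np.ndarray:
    """Probabilities for every record of a dataset (batched)."""
    records = dataset.records if isinstance(dataset, Dataset) else list(dataset)
    out = []
    for s in range(0, len(records), batch_size):
        X, dt, lengths, _ = batch_arrays(records[s:s + batch_size])
        out.append(forward_batch(params, X, dt, lengths, memory_mode))
    return np.vstack(out)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_params(path, params: dict) -> None:
    """Flat named-array checkpoint (.npz) with a JSON name table alongside."""
    np.savez(path, **params)
    name_table = {k: list(v.shape) for k, v in params.items()}
    with open(str(path) + ".names.json", "w") as fh:
        json.dump(name_table, fh, indent=1)


def load_params(path) -> dict:
    with np.load(path) as z:
        return {k: z[k].copy() for k in z.files}
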