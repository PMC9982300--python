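"""Containers and I/O for labeled, irregularly sampled multivariate time series.

A record is a sequence of timestamped multivariate observations whose class
label (e.g. eventual sepsis / non-sepsis) is fixed at the final time.  For
continuous classification the full-length dataset is expanded into a *prefix
task stream*: an ordered sequence of datasets, each holding every record
truncated at a growing fraction of its own length.  Each prefix dataset is
treated as one data distribution / learning task, so a sequential trainer
that walks the stream experiences exactly the kind of distribution drift a
bedside model sees as patient trajectories lengthen.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IrregularSeries",
    "Dataset",
    "PrefixTask",
    "PrefixTaskStream",
    "compute_deltas",
    "load_long_csv",
    "write_long_csv",
    "impute_dataset",
    "build_prefix_stream",
    "order_tasks_by_similarity",
]


@dataclasses.dataclass
class IrregularSeries:
    """One record: strictly increasing timestamps, an M x D value matrix, an
    observation mask (True = actually measured) and a final-time class label.

    ``values`` always holds a number in every cell; cells where ``mask`` is
    False contain imputed values (see :func:`impute_dataset`).
    """

    record_id: str
    times: np.ndarray  # (M,)
    values: np.ndarray  # (M, D)
    mask: np.ndarray  # (M, D) bool
    label: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.times.ndim != 1 or self.times.size < 1:
            raise ValueError("times must be a 1-d array of length >= 1")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(
                f"record {self.record_id!r}: times must be strictly increasing"
            )
        if self.values.shape != (self.times.size, self.values.shape[-1]):
            raise ValueError("values must be (M, D)")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        self.label = int(self.label)

    @property
    def n_obs(self) -> int:
        return self.times.size

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def prefix(self, length: int) -> "IrregularSeries":
        """Return the record truncated to its first ``length`` observations."""
        length = int(length)
        if not 1 <= length <= self.n_obs:
            raise ValueError(f"prefix length {length} out of range")
        return IrregularSeries(
            record_id=self.record_id,
            times=self.times[:length].copy(),
            values=self.values[:length].copy(),
            mask=self.mask[:length].copy(),
            label=self.label,
        )


@dataclasses.dataclass
class Dataset:
    """An ordered collection of records sharing one variable layout."""

    records: list
    variables: list

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[IrregularSeries]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def n_features(self) -> int:
        return len(self.variables)

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def n_classes(self) -> int:
        return int(self.labels().max()) + 1


@dataclasses.dataclass
class PrefixTask:
    """One element of the stream: all records truncated at ``cut_fraction``."""

    index: int
    cut_fraction: float
    data: Dataset


@dataclasses.dataclass
class PrefixTaskStream:
    """Ordered prefix datasets; ``permutation[k]`` is the original (time-order)
    index of the task now in position k."""

    tasks: list
    order_mode: str = "time"
    permutation: tuple = ()

    def __post_init__(self) -> None:
        if not self.permutation:
            self.permutation = tuple(range(len(self.tasks)))

    def __len__(self) -> int:
        return len(self.tasks)

    def __iter__(self) -> Iterator[PrefixTask]:
        return iter(self.tasks)

    @property
    def cut_fractions(self):
        return tuple(t.cut_fraction for t in self.tasks)


def compute_deltas(series) -> np.ndarray:
    """Elapsed time between consecutive observations; the first gap is 0.

    Accepts an :class:`IrregularSeries` or a raw timestamp array.
    """
    times = series.times if isinstance(series, IrregularSeries) else np.asarray(series, float)
    if times.ndim != 1 or times.size < 1:
        raise ValueError("need a 1-d array of at least one timestamp")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    deltas = np.empty_like(times)
    deltas[0] = 0.0
    deltas[1:] = np.diff(times)
    return deltas


# ---------------------------------------------------------------------------
# Long-format I/O
# ---------------------------------------------------------------------------

def load_long_csv(data_path, label_path, variable_order=None) -> Dataset:
    """Read a long-format table (record_id,time,variable,value) plus a label
    table (record_id,label) into a :class:`Dataset`.

    Rows are sorted by time within record; (record, time, variable) cells not
    present in the file are masked as unobserved and imputed (forward fill,
    then per-variable dataset mean for leading gaps).
    """
    df = pd.read_csv(data_path, dtype={"record_id": str})
    labels = pd.read_csv(label_path, dtype={"record_id": str})
    if labels.empty:
        raise ValueError("missing labels: label file is empty")
    dup = df.duplicated(subset=["record_id", "time", "variable"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            "duplicate (record, time, variable) triplet: "
            f"({row['record_id']}, {row['time']}, {row['variable']})"
        )
    label_map = dict(zip(labels["record_id"], labels["label"].astype(int)))
    if variable_order is None:
        variable_order = sorted(df["variable"].unique())
    variables = list(variable_order)
    vidx = {v: i for i, v in enumerate(variables)}
    unknown = set(df["variable"]) - set(variables)
    if unknown:
        raise ValueError(f"variables not in variable_order: {sorted(unknown)}")

    records = []
    for rid, grp in df.groupby("record_id", sort=True):
        if rid not in label_map:
            raise ValueError(f"record without label: {rid}")
        times = np.sort(grp["time"].unique())
        M, D = times.size, len(variables)
        values = np.zeros((M, D))
        mask = np.zeros((M, D), dtype=bool)
        tpos = {t: i for i, t in enumerate(times)}
        for t, v, x in zip(grp["time"], grp["variable"], grp["value"]):
            i, j = tpos[t], vidx[v]
            values[i, j] = x
            mask[i, j] = True
        records.append(
            IrregularSeries(record_id=str(rid), times=times, values=values,
                            mask=mask, label=label_map[rid])
        )
    ds = Dataset(records=records, variables=variables)
    impute_dataset(ds)
    return ds


def write_long_csv(dataset: Dataset, data_path, label_path) -> None:
    """Write observed cells (mask True) in the long dialect read by
    :func:`load_long_csv`; the round trip preserves times, observed values,
    mask and label."""
    rows = []
    for r in dataset:
        ii, jj = np.nonzero(r.mask)
        for i, j in zip(ii, jj):
            rows.append((r.record_id, repr(float(r.times[i])),
                         dataset.variables[j], repr(float(r.values[i, j]))))
    pd.DataFrame(rows, columns=["record_id", "time", "variable", "value"]).to_csv(
        data_path, index=False)
    pd.DataFrame(
        {"record_id": [r.record_id for r in dataset],
         "label": [r.label for r in dataset]}
    ).to_csv(label_path, index=False)


def impute_dataset(dataset: Dataset) -> Dataset:
    """Fill unobserved cells in place: forward fill within each record, then
    the per-variable mean of all observed cells in the dataset for leading
    gaps (0 if a variable is never observed).  Masks are untouched."""
    D = dataset.n_features
    tot = np.zeros(D)
    cnt = np.zeros(D)
    for r in dataset:
        tot += np.where(r.mask, r.values, 0.0).sum(axis=0)
        cnt += r.mask.sum(axis=0)
    global_mean = np.where(cnt > 0, tot / np.maximum(cnt, 1), 0.0)
    for r in dataset:
        for j in range(D):
            col, m = r.values[:, j], r.mask[:, j]
            last = None
            for i in range(r.n_obs):
                if m[i]:
                    last = col[i]
                elif last is not None:
                    col[i] = last
                else:
                    col[i] = global_mean[j]
    return dataset


# ---------------------------------------------------------------------------
# Prefix task stream
# ---------------------------------------------------------------------------

def _prefix_length(fraction: float, n_obs: int) -> int:
    # round half up, floored at one observation
    return max(1, int(math.floor(fraction * n_obs + 0.5)))


def build_prefix_stream(dataset: Dataset, cut_fractions: Sequence[float],
                        order_mode: str = "time") -> PrefixTaskStream:
    """Expand a dataset into the ordered prefix datasets that define the
    distribution sequence.  Each task m truncates every record to
    ``max(1, round(fraction * M_record))`` observations (round half up)."""
    fr = [float(f) for f in cut_fractions]
    if not fr:
        raise ValueError("cut_fractions must be non-empty")
    if any(not (0.0 < f <= 1.0) for f in fr):
        raise ValueError("cut fractions must lie in (0, 1]")
    if any(b <= a for a, b in zip(fr, fr[1:])):
        raise ValueError("cut fractions must be strictly increasing")
    if abs(fr[-1] - 1.0) > 1e-12:
        raise ValueError("last cut fraction must be 1.0")
    if order_mode not in ("time", "similarity"):
        raise ValueError(f"unknown order_mode {order_mode!r}")

    tasks = []
    for m, f in enumerate(fr):
        recs = [r.prefix(_prefix_length(f, r.n_obs)) for r in dataset]
        tasks.append(PrefixTask(index=m, cut_fraction=f,
                                data=Dataset(records=recs,
                                             variables=list(dataset.variables))))
    stream = PrefixTaskStream(tasks=tasks, order_mode="time")
    if order_mode == "similarity":
        stream = order_tasks_by_similarity(stream)
    return stream


def task_mean_vector(task: PrefixTask) -> np.ndarray:
    """Per-variable mean over observed cells of every record in the task."""
    D = task.data.n_features
    tot, cnt = np.zeros(D), np.zeros(D)
    for r in task.data:
        tot += np.where(r.mask, r.values, 0.0).sum(axis=0)
        cnt += r.mask.sum(axis=0)
    return np.where(cnt > 0, tot / np.maximum(cnt, 1), 0.0)


def order_tasks_by_similarity(stream: PrefixTaskStream) -> PrefixTaskStream:
    """Deterministic similarity ordering: keep task 1, then repeatedly append
    the unvisited task whose mean feature vector is closest (Euclidean) to the
    current task's, ties broken by original index.

    This greedy centroid chain is an approximation: it realises the idea of
    presenting similar distributions consecutively without claiming to be the
    canonical procedure.
    """
    if stream.order_mode != "time":
        raise ValueError("expects a stream built in time order")
    n = len(stream.tasks)
    cents = [task_mean_vector(t) for t in stream.tasks]
    perm = [0]
    remaining = list(range(1, n))
    while remaining:
        cur = cents[perm[-1]]
        dists = [(float(np.linalg.norm(cents[j] - cur)), j) for j in remaining]
        _, best = min(dists)
        perm.append(best)
        remaining.remove(best)
    tasks = [stream.tasks[j] for j in perm]
    return PrefixTaskStream(tasks=tasks, order_mode="similarity",
                            permutation=tuple(perm))
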