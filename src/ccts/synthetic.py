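"""Synthetic multi-distribution clinical-style time series with known truth.

Each record is an irregularly sampled multivariate series whose class label
(fixed at the final time) shifts the class-conditional mean of informative
features.  The shift pattern is piecewise constant over *stages* defined by
fractional position within the record, emulating evolving vital-sign
distributions: "congenital" markers (always-informative features) separate
the classes in every stage, while "acute" markers (late-informative
features) only activate near the end of the record.  Within-record noise is
AR(1) so prefixes carry temporal signal; sampling gaps are exponential and
observations are masked at a configurable missing rate.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .data import Dataset, IrregularSeries, impute_dataset

__all__ = [
    "GeneratorConfig",
    "FixtureSpec",
    "generate",
    "standard_streams",
    "bayes_scores",
]


@dataclasses.dataclass
class GeneratorConfig:
    """Study conditions of one synthetic cohort.

    ``stage_shifts`` (n_stages x D, in units of the within-stage SD) gives
    the class-1 mean shift of each feature in each stage; when None it is
    assembled from ``always_informative`` / ``late_informative`` and
    ``effect_size`` (late features activate only in the final stage).
    """

    n_records: int = 400
    n_features: int = 10
    length_range: tuple = (16, 32)
    stage_boundaries: tuple = (0.5,)
    stage_shifts: Optional[np.ndarray] = None
    always_informative: tuple = (0, 1, 2)
    late_informative: tuple = ()
    effect_size: float = 1.5
    noise_sd: float = 1.0
    ar_phi: float = 0.5
    missing_rate: float = 0.1
    mean_gap: float = 1.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.stage_boundaries)
        if any(not 0.0 < x < 1.0 for x in b) or list(b) != sorted(b):
            raise ValueError("stage boundaries must be sorted and in (0, 1)")
        if set(self.always_informative) & set(self.late_informative):
            raise ValueError("informative feature sets must be disjoint")
        for s in (*self.always_informative, *self.late_informative):
            if not 0 <= s < self.n_features:
                raise ValueError(f"feature index {s} out of range")
        if not (0.0 <= self.missing_rate <= 1.0
                and 0.0 <= self.class_balance <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
        self.stage_boundaries = b

    @property
    def n_stages(self) -> int:
        return len(self.stage_boundaries) + 1


def shift_matrix(config: GeneratorConfig) -> np.ndarray:
    """(n_stages, D) class-1 mean shifts in SD units."""
    if config.stage_shifts is not None:
        M = np.asarray(config.stage_shifts, float)
        if M.shape != (config.n_stages, config.n_features):
            raise ValueError("stage_shifts must be (n_stages, n_features)")
        return M
    M = np.zeros((config.n_stages, config.n_features))
    for d in config.always_informative:
        M[:, d] = config.effect_size
    for d in config.late_informative:
        M[-1, d] = config.effect_size
    return M


def _stage_of(positions: np.ndarray, boundaries) -> np.ndarray:
    """Stage index of fractional positions in (0, 1]; position == boundary
    still belongs to the earlier stage."""
    return np.searchsorted(np.asarray(boundaries, float), positions,
                           side="left")


def generate(config: GeneratorConfig):
    """Draw a cohort.  Returns ``(Dataset, ground_truth dict)``; identical
    seeds give identical cohorts."""
    rng = np.random.default_rng(config.seed)
    shifts = shift_matrix(config)
    lo, hi = config.length_range
    phi, sd = config.ar_phi, config.noise_sd
    records = []
    for n in range(config.n_records):
        M = int(rng.integers(lo, hi + 1))
        gaps = rng.exponential(config.mean_gap, M)
        gaps[0] = 0.0
        gaps[1:] = np.maximum(gaps[1:], 1e-6)
        times = np.cumsum(gaps)
        y = int(rng.random() < config.class_balance)
        pos = np.arange(1, M + 1) / M
        stage = _stage_of(pos, config.stage_boundaries)
        # AR(1) noise with stationary SD = noise_sd
        eps = np.empty((M, config.n_features))
        eps[0] = rng.standard_normal(config.n_features)
        innov = rng.standard_normal((M, config.n_features))
        for m in range(1, M):
            eps[m] = phi * eps[m - 1] + np.sqrt(1.0 - phi ** 2) * innov[m]
        values = sd * eps + y * sd * shifts[stage]
        mask = rng.random((M, config.n_features)) >= config.missing_rate
        if not mask.any():
            mask[0, 0] = True
        records.append(IrregularSeries(record_id=f"r{n:04d}", times=times,
                                       values=values, mask=mask, label=y))
    ds = Dataset(records=records,
                 variables=[f"v{d}" for d in range(config.n_features)])
    impute_dataset(ds)
    truth = dict(
        stage_boundaries=list(config.stage_boundaries),
        shift_matrix=shifts.tolist(),
        always_informative=list(config.always_informative),
        late_informative=list(config.late_informative),
        # single-observation Bayes AUC per stage for equal-covariance
        # Gaussian classes: Phi(||delta|| / sqrt(2))
        stage_effect_norms=[float(np.linalg.norm(s)) for s in shifts],
        stage_bayes_auc=[float(stats.norm.cdf(np.linalg.norm(s) / np.sqrt(2)))
                         for s in shifts],
        seed=config.seed,
    )
    return ds, truth


def bayes_scores(dataset: Dataset, truth: dict) -> np.ndarray:
    """Score each record with the Bayes-optimal linear rule for its final
    observation (true final-stage shift direction); all-zero shifts give a
    constant score."""
    delta = np.asarray(truth["shift_matrix"], float)[-1]
    return np.array([float(r.values[-1] @ delta) for r in dataset])


@dataclasses.dataclass
class FixtureSpec:
    """A named study condition: generator config plus the cut fractions that
    define its prefix task stream."""

    generator: GeneratorConfig
    cut_fractions: tuple
    description: str = ""


def standard_streams() -> dict:
    """The fixed fixture conditions used throughout the test suite.

    * ``forgetting-2d`` — two stages whose class-separating directions
      conflict (the sign of the first feature's shift flips between stages),
      so naive sequential training on the two prefix tasks forgets the first
      distribution.
    * ``staging-4`` — four stages, each separating the classes through a
      distinct feature pair, plus one always-informative and one
      late-informative feature; used for stage discovery and biomarker tests.
    * ``null`` — no class signal at all.
    """
    forgetting = GeneratorConfig(
        n_records=400, n_features=10, length_range=(16, 32),
        stage_boundaries=(0.5,),
        stage_shifts=np.array([
            # stage 1: feature 0 separates the classes
            [2.0] + [0.0] * 9,
            # stage 2: feature 0 flips sign, feature 1 joins
            [-2.0, 2.0] + [0.0] * 8,
        ]),
        always_informative=(0,), late_informative=(1,),
        noise_sd=1.0, missing_rate=0.1, mean_gap=1.0, class_balance=0.5)
    staging = GeneratorConfig(
        n_records=320, n_features=10, length_range=(16, 32),
        stage_boundaries=(0.25, 0.5, 0.75),
        stage_shifts=np.array([
            [1.5, 0.0, 2.0, 2.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            [1.5, 0.0, 0.0, 0.0, 2.0, 2.0, 0.0, 0.0, 0.0, 0.0],
            [1.5, 0.0, 0.0, 0.0, 0.0, 0.0, 2.0, 2.0, 0.0, 0.0],
            [1.5, 2.5, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 2.0, 2.0],
        ]),
        always_informative=(0,), late_informative=(1,),
        noise_sd=1.0, missing_rate=0.1, mean_gap=1.0, class_balance=0.5)
    null = GeneratorConfig(
        n_records=400, n_features=10, length_range=(16, 32),
        stage_boundaries=(0.5,),
        stage_shifts=np.zeros((2, 10)),
        always_informative=(), late_informative=(),
        noise_sd=1.0, missing_rate=0.1, mean_gap=1.0, class_balance=0.5)
    return {
        "forgetting-2d": FixtureSpec(
            generator=forgetting, cut_fractions=(0.5, 1.0),
            description="two conflicting stages; naive sequential training "
                        "forgets the first prefix distribution"),
        "staging-4": FixtureSpec(
            generator=staging,
            cut_fractions=tuple(k / 16 for k in range(1, 17)),
            description="four stages with distinct informative feature pairs"),
        "null": FixtureSpec(
            generator=null, cut_fractions=(0.5, 1.0),
            description="no class signal"),
    }
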