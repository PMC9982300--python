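"""Shared fixtures: small cohorts for unit tests and the two session-scoped
experiment caches (forgetting/recovery and staging) reused across modules."""

import dataclasses

import numpy as np
import pytest

from ccts import data, ru, synthetic, tlstm

TRAINER_VARIANTS = {
    "naive": dict(lm_enabled=False, pm_enabled=False),
    "full": dict(lm_enabled=True, pm_enabled=True),
    "lm": dict(lm_enabled=True, pm_enabled=False),
    "pm": dict(lm_enabled=False, pm_enabled=True),
}

SEEDS = (0, 1, 2, 3, 4)


def _with_seed(gen, seed):
    return dataclasses.replace(gen, seed=seed)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = synthetic.GeneratorConfig(n_records=24, n_features=4,
                                    length_range=(4, 8), seed=42,
                                    always_informative=(0,),
                                    missing_rate=0.15)
    ds, truth = synthetic.generate(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def forgetting_runs():
    """Histories of all four trainer variants on the two-stage conflicting
    fixture, five seeds each; drives the forgetting-recovery and
    gradient-stability checks."""
    spec = synthetic.standard_streams()["forgetting-2d"]
    runs = {}
    for seed in SEEDS:
        ds, _ = synthetic.generate(_with_seed(spec.generator, seed))
        stream = data.build_prefix_stream(ds, spec.cut_fractions)
        for name, flags in TRAINER_VARIANTS.items():
            params = tlstm.init_params(ds.n_features, 16, 2, head_hidden=16,
                                       seed=seed)
            cfg = ru.RUConfig(epochs_per_task=10, seed=seed, **flags)
            _, hist = ru.train_ru(params, stream, cfg)
            runs[(name, seed)] = hist
    return runs


@pytest.fixture(scope="session")
def staging_runs():
    """Full-RU histories on the four-stage fixture (16 prefix tasks), five
    seeds, with each run's ground truth; drives stage-recovery and
    biomarker checks."""
    spec = synthetic.standard_streams()["staging-4"]
    runs = {}
    for seed in SEEDS:
        gen = _with_seed(spec.generator, seed)
        ds, truth = synthetic.generate(gen)
        stream = data.build_prefix_stream(ds, spec.cut_fractions)
        params = tlstm.init_params(ds.n_features, 16, 2, head_hidden=16,
                                   seed=seed)
        cfg = ru.RUConfig(epochs_per_task=12, seed=seed, fisher_samples=320)
        _, hist = ru.train_ru(params, stream, cfg)
        truth = dict(truth)
        truth["boundary_tasks"] = [
            int(np.searchsorted(
                np.array(spec.cut_fractions), b, side="right"))
            for b in truth["stage_boundaries"]]
        runs[seed] = (hist, truth, spec)
    return runs
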