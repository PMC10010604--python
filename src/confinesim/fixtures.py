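"""Synthetic (drivers, diversity) sample tables for testing the fitting mode.

Real multi-sample tumour cohorts reduce, for fitting purposes, to a handful
of points in the (mean drivers per cell, clonal diversity) plane.  The
fixture generator emits synthetic tables clustered where the four
qualitative evolutionary modes live:

``nonspatial``
    Unconstrained growth: few drivers (mean 2.0), diversity near the floor
    of 1 (leukaemia-like).
``linear``
    Repeated clonal sweeps under global confinement: more drivers
    (mean 5.7), still low diversity (~1.9).
``branched``
    Parallel clonal expansions under local confinement: low-to-moderate
    drivers (mean 4.0), very high diversity (lognormal around ~80).
``mixed``
    Linear-to-branched evolution under combined confinement: many drivers
    (mean 8.2) and high diversity (lognormal around ~12.6).

These synthetic stand-ins exist so the fitting machinery can be exercised
and tested without any external cohort; they mimic only the location and
spread of the summary points, not any sequencing noise model.

``simulate_dataset`` builds a dataset from actual simulation runs instead,
which is what parameter-recovery checks use.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .core import Parameters
from .engine import RunConfig, run
from .fit import Dataset, RunFailedError
from .metrics import MetricPoint

__all__ = ["FIXTURE_KINDS", "generate_fixture", "simulate_dataset"]

# kind -> (drivers mean, drivers sd, diversity law)
_MODES = {
    "nonspatial": (2.0, 0.6, ("near_one", 0.35)),
    "linear": (5.7, 1.2, ("near_one", 0.9)),
    "branched": (4.0, 1.0, ("lognormal", 80.0, 0.5)),
    "mixed": (8.2, 1.5, ("lognormal", 12.6, 0.4)),
}

FIXTURE_KINDS = tuple(_MODES)


def generate_fixture(
    kind: str,
    n_samples: int,
    seed: int,
    path: str | Path | None = None,
) -> Dataset:
    """Generate a synthetic per-sample summary table for one evolutionary mode.

    Deterministic given ``seed``.  If ``path`` is given the dataset is also
    written as CSV in the ``sample,mean_drivers,diversity`` schema.
    """
    if kind not in _MODES:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    mu_d, sd_d, div_law = _MODES[kind]
    rng = np.random.default_rng(seed)
    drivers = np.clip(rng.normal(mu_d, sd_d, n_samples), 1.0, None)
    if div_law[0] == "near_one":
        diversity = 1.0 + np.abs(rng.normal(0.0, div_law[1], n_samples))
    else:
        _, med, sigma = div_law
        diversity = np.maximum(rng.lognormal(np.log(med), sigma, n_samples), 1.0)
    dataset = Dataset(
        label=kind,
        points=tuple(
            MetricPoint(float(d), float(v)) for d, v in zip(drivers, diversity)
        ),
    )
    if path is not None:
        from .io import write_dataset

        write_dataset(dataset, path)
    return dataset


def simulate_dataset(
    params: Parameters,
    config: RunConfig,
    n_runs: int,
    label: str = "simulated",
) -> Dataset:
    """Dataset of final (drivers, diversity) points from ``n_runs`` simulations.

    Run seeds derive deterministically from ``config.seed``.
    """
    points = []
    for i in range(n_runs):
        seed = int(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(i,)).generate_state(1)[0]
            % (2**31)
        )
        cfg = RunConfig(
            step_size=config.step_size,
            min_pop=config.min_pop,
            max_pop=config.max_pop,
            max_steps=config.max_steps,
            metric_cutoff=config.metric_cutoff,
            seed=seed,
            max_restarts=config.max_restarts,
            init_cells=config.init_cells,
        )
        result = run(params, cfg)
        if result.failed:
            raise RunFailedError(f"fixture run {i} exhausted restarts")
        md, dv = result.final_metric_point
        points.append(MetricPoint(md, dv))
    return Dataset(label=label, points=tuple(points))
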