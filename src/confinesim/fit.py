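"""Fit confinement parameters to observed (drivers, diversity) sample points.

Real tumour cohorts enter as a small set of per-sample summary points in the
(mean drivers per cell, clonal diversity) plane.  Simulations are compared
to such a dataset with a symmetric iterative-closest-point style score: the
mean nearest-neighbour Euclidean distance from each simulated point to the
data, plus the mean nearest-neighbour distance from each data point to the
simulation.  No axis normalization is applied — the score uses raw
coordinates, so drivers and diversity contribute on their natural scales.

``grid_fit`` evaluates this score over a grid of (theta_conf, theta_local)
combinations, running a batch of seeded simulations per grid cell and
pooling their final metric points into one simulated point set (per-run
scoring with averaging is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Parameters
from .engine import RunConfig, run
from .metrics import MetricPoint

__all__ = [
    "Dataset",
    "FitResult",
    "RunFailedError",
    "nearest_distance",
    "icp_score",
    "grid_fit",
]


class RunFailedError(RuntimeError):
    """A simulation inside the grid search exhausted its restarts."""


@dataclass(frozen=True)
class Dataset:
    """A labelled collection of per-sample (drivers, diversity) points."""

    label: str
    points: tuple[MetricPoint, ...]

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("dataset must contain at least one point")
        for p in self.points:
            if p.diversity < 1.0:
                raise ValueError(f"diversity must be >= 1, got {p.diversity}")


@dataclass
class FitResult:
    """Grid of mean scores and the best-scoring confinement pair."""

    grid: dict[tuple[float, float], float]
    best_pair: tuple[float, float]
    runs_per_cell: int
    points: dict[tuple[float, float], list[MetricPoint]]

    def to_records(self) -> list[dict]:
        return [
            {"theta_conf": tc, "theta_local": tl, "score": s}
            for (tc, tl), s in sorted(self.grid.items())
        ]


def _as_array(points: Sequence[MetricPoint]) -> np.ndarray:
    return np.array([[p.mean_drivers, p.diversity] for p in points], dtype=float)


def nearest_distance(x: MetricPoint, others: Sequence[MetricPoint]) -> float:
    """Shortest Euclidean distance from ``x`` to any point of ``others``."""
    if not others:
        raise ValueError("nearest_distance requires a non-empty point set")
    arr = _as_array(others)
    d = arr - np.array([x.mean_drivers, x.diversity])
    return float(np.sqrt((d**2).sum(axis=1)).min())


def icp_score(
    sim_points: Sequence[MetricPoint], data_points: Sequence[MetricPoint]
) -> float:
    """Symmetric mean nearest-neighbour distance between two point sets."""
    if not sim_points or not data_points:
        raise ValueError("icp_score requires two non-empty point sets")
    a = _as_array(sim_points)
    b = _as_array(data_points)
    dists = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))
    return float(dists.min(axis=1).mean() + dists.min(axis=0).mean())


def grid_fit(
    dataset: Dataset,
    params_base: Parameters,
    config: RunConfig,
    grid_values: Sequence[float] = (0.0, 0.125, 0.25, 0.5, 1.0, 2.0),
    runs_per_cell: int = 100,
    local_values: Sequence[float] | None = None,
    pooling: str = "pooled",
) -> FitResult:
    """Grid-search (theta_conf, theta_local) against a dataset.

    For every combination of ``grid_values`` (theta_conf) and
    ``local_values`` (theta_local; defaults to ``grid_values``),
    ``runs_per_cell`` seeded simulations are run and each run's final
    (drivers, diversity) point collected.  With ``pooling='pooled'`` the
    cell's score is the symmetric score of the pooled point cloud against
    the dataset; with ``pooling='per_run'`` it is the mean of single-point
    scores.  Seeds derive deterministically from ``config.seed`` and the
    cell/run indices.
    """
    if runs_per_cell < 1:
        raise ValueError("runs_per_cell must be at least 1")
    if pooling not in ("pooled", "per_run"):
        raise ValueError("pooling must be 'pooled' or 'per_run'")
    if local_values is None:
        local_values = grid_values
    grid: dict[tuple[float, float], float] = {}
    points: dict[tuple[float, float], list[MetricPoint]] = {}
    for ci, theta_conf in enumerate(grid_values):
        for li, theta_local in enumerate(local_values):
            cell = (float(theta_conf), float(theta_local))
            params = Parameters(
                theta_mut=params_base.theta_mut,
                theta_fit=params_base.theta_fit,
                theta_conf=float(theta_conf),
                theta_local=float(theta_local),
                dist=params_base.dist,
            )
            cell_points: list[MetricPoint] = []
            for ri in range(runs_per_cell):
                seed = int(
                    np.random.SeedSequence(
                        entropy=config.seed, spawn_key=(ci, li, ri)
                    ).generate_state(1)[0]
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
                    raise RunFailedError(
                        f"run {ri} exhausted restarts in grid cell "
                        f"theta_conf={theta_conf}, theta_local={theta_local}"
                    )
                md, dv = result.final_metric_point
                cell_points.append(MetricPoint(md, dv))
            if pooling == "pooled":
                score = icp_score(cell_points, dataset.points)
            else:
                score = float(
                    np.mean([icp_score([p], dataset.points) for p in cell_points])
                )
            grid[cell] = score
            points[cell] = cell_points
    best_pair = min(grid, key=lambda k: (grid[k], k))
    return FitResult(
        grid=grid, best_pair=best_pair, runs_per_cell=runs_per_cell, points=points
    )
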