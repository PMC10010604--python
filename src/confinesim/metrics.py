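"""Population summary statistics: mean drivers per cell and clonal diversity.

Both metrics are computed over the *filtered* clone set — clones holding at
least a ``cutoff`` fraction of the alive population — and use alive cells
only; necrotic cells never enter the formulas.  The mean number of drivers
per cell tracks mutational burden; the clonal diversity index is the
inverse Simpson index of clone alive-cell fractions, i.e. the effective
number of equally sized clones, with a floor of 1 attained by a
single-clone (post-sweep) population.
"""

from __future__ import annotations

from collections.abc import Collection
from dataclasses import dataclass

from .core import Clone, Population

__all__ = [
    "MetricPoint",
    "MetricsUndefinedError",
    "filter_clones",
    "mean_drivers",
    "clonal_diversity",
    "metric_point",
]


class MetricsUndefinedError(ValueError):
    """Raised when a metric is requested for a population with no alive cells."""


@dataclass(frozen=True)
class MetricPoint:
    """A point in the (mean drivers per cell, clonal diversity) plane."""

    mean_drivers: float
    diversity: float

    def as_tuple(self) -> tuple[float, float]:
        return (self.mean_drivers, self.diversity)


def filter_clones(pop: Population, cutoff: float) -> list[Clone]:
    """Clones holding at least ``cutoff`` of the total alive population.

    The threshold is ``C_a * cutoff`` with ``C_a`` the unfiltered alive
    total; ``cutoff = 0`` retains every clone with alive cells.
    """
    if not 0.0 <= cutoff < 1.0:
        raise ValueError("cutoff must be in [0, 1)")
    total_alive = pop.total_alive
    if total_alive == 0:
        raise MetricsUndefinedError("population has no alive cells")
    threshold = total_alive * cutoff
    return [
        c
        for c in sorted(pop.clones.values(), key=lambda c: c.clone_id)
        if c.c_a >= threshold and c.c_a > 0
    ]


def mean_drivers(clones: Collection[Clone]) -> float:
    """Alive-cell-weighted mean mutation-set size over the given clones."""
    total = sum(c.c_a for c in clones)
    if total == 0:
        raise MetricsUndefinedError("no alive cells in clone collection")
    return sum(c.n_drivers * c.c_a for c in clones) / total


def clonal_diversity(clones: Collection[Clone]) -> float:
    """Inverse Simpson index of clone alive-cell fractions (>= 1)."""
    total = sum(c.c_a for c in clones)
    if total == 0:
        raise MetricsUndefinedError("no alive cells in clone collection")
    return total**2 / sum(c.c_a**2 for c in clones)


def metric_point(pop: Population, cutoff: float) -> MetricPoint:
    """Both metrics of a population after cutoff filtering."""
    clones = filter_clones(pop, cutoff)
    return MetricPoint(mean_drivers(clones), clonal_diversity(clones))
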