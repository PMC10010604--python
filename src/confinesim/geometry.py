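"""Spherical confinement geometry.

The tumour is idealized as a sphere in which each cell occupies unit volume,
so the tumour volume equals the total cell count C_a + C_n.  Confinement
splits the sphere into a proliferating outer *shell* of width 1/theta_conf
and a quiescent *core*: cells divide only in the shell, and cells dying in
the core are retained as necrotic rather than removed.  The shell fraction
(shell volume relative to the alive population) scales the birth
probability, and its complement gives the necrosis probability.  For
theta_conf -> 1 the shell volume approaches the sphere's surface area
(surface growth); for theta_conf -> 0 the whole sphere is shell and the
model reduces to an unconstrained branching process.

Local confinement applies the identical geometry to a single clone's own
cells with theta_local in place of theta_conf.
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .core import Clone

__all__ = [
    "core_radius",
    "shell_fraction",
    "local_fraction",
    "birth_probability",
    "necrosis_probability",
]

_FOUR_THIRDS_PI = 4.0 * math.pi / 3.0


def _check_counts(c_a: int, c_n: int) -> None:
    if c_a < 0 or c_n < 0:
        raise ValueError(f"cell counts must be non-negative, got ({c_a}, {c_n})")


def core_radius(c_a: int, c_n: int, theta_conf: float) -> float:
    """Radius of the quiescent core, in cell lengths.

    The total sphere radius is (3 (C_a + C_n) / (4 pi))^(1/3); the core is
    what remains after removing the shell of width 1/theta_conf, clamped at
    0 when the whole sphere fits inside one shell width.  Callers must
    short-circuit theta_conf = 0 (no confinement, no core).
    """
    _check_counts(c_a, c_n)
    if theta_conf <= 0:
        raise ValueError("core_radius requires theta_conf > 0")
    r_total = (3.0 * (c_a + c_n) / (4.0 * math.pi)) ** (1.0 / 3.0)
    return max(r_total - 1.0 / theta_conf, 0.0)


def shell_fraction(c_a: int, c_n: int, theta_conf: float) -> float:
    """Fraction of the alive population sitting in the proliferating shell.

    Returns 0 for an extinct population and 1 without confinement; otherwise
    the shell volume (total volume minus core volume) relative to the alive
    count, clamped into [0, 1].
    """
    _check_counts(c_a, c_n)
    if c_a == 0:
        return 0.0
    if theta_conf == 0.0:
        return 1.0
    r_core = core_radius(c_a, c_n, theta_conf)
    shell_volume = (c_a + c_n) - _FOUR_THIRDS_PI * r_core**3
    return min(shell_volume / c_a, 1.0)


def local_fraction(clone: "Clone", theta_local: float) -> float:
    """Shell fraction of a single clone's own cells under local confinement."""
    return shell_fraction(clone.c_a, clone.c_n, theta_local)


def birth_probability(
    fitness: float, frac: float, local: float, step_size: float
) -> float:
    """Per-cell birth probability: min(1, fitness * frac * local * step_size)."""
    return min(1.0, fitness * frac * local * step_size)


def necrosis_probability(frac: float, local: float) -> float:
    """Probability that a dying cell is retained as necrotic: 1 - frac * local."""
    return 1.0 - frac * local
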