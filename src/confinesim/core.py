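"""Domain types and single-clone stochastic update rules.

The simulator tracks a tumour as a set of *clones*, where a clone is the
triplet (alive count, necrotic count, mutation set): cells sharing an
identical mutation set are never distinguished individually.  Mutations obey
the infinite-sites assumption — every mutation is unique, so each new
mutation founds a new clone.  Clone ids are identified 1:1 with the mutation
that created the clone; the founder clone (id 0) carries the identifying
mutation 0, which has fitness effect 0 so that the unmutated system has
fitness exactly 1.

Per time step, each clone draws independent binomial birth/death counts from
its step-start alive count (simultaneous-update semantics); mutated newborns
leave the clone and each founds a child clone of one cell.  Deaths are split
into removed and necrotic cells by the confinement geometry (see
:mod:`confinesim.geometry`).

Reproducibility contract: all draws come from a single seeded
``numpy.random.Generator`` per run.  Clones are iterated in ascending clone
id, drawing in the order B_d, B_b, B_m, B_n, then one fitness effect per
child.  Degenerate draws (``n == 0`` or ``p == 0``; fitness draws with
``theta_fit == 0``) are skipped without consuming generator state, so that
e.g. a run with ``theta_mut = 0`` consumes the identical stream as a pure
birth–death process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FITNESS_DISTRIBUTIONS",
    "Parameters",
    "Clone",
    "MutationRegistry",
    "Population",
    "StepDraws",
    "sample_fitness_effect",
    "sample_fitness_effects",
    "clone_fitness",
    "step_clone",
    "spawn_children",
]

#: Supported driver-fitness-effect distributions, all with mean ~theta_fit.
FITNESS_DISTRIBUTIONS = ("const", "uni", "exp", "norm")


@dataclass(frozen=True)
class Parameters:
    """Model parameters theta = (theta_mut, theta_fit, theta_conf, theta_local).

    Parameters
    ----------
    theta_mut:
        Probability that a newborn cell carries a new driver mutation,
        per cell division, in [0, 1].
    theta_fit:
        Mean fitness increase conferred by one driver mutation (>= 0).
    theta_conf:
        Global confinement; the proliferating shell of the whole tumour has
        width 1/theta_conf (in cell lengths).  0 disables global confinement.
    theta_local:
        Local confinement; same geometry applied to each clone's own cells.
        0 disables local confinement.
    dist:
        Fitness-effect distribution, one of ``const``, ``uni``, ``exp``,
        ``norm`` (truncated normal on [0, inf)).
    """

    theta_mut: float = 2e-5
    theta_fit: float = 0.1
    theta_conf: float = 0.0
    theta_local: float = 0.0
    dist: str = "exp"

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_mut <= 1.0:
            raise ValueError(f"theta_mut must be in [0, 1], got {self.theta_mut}")
        for name in ("theta_fit", "theta_conf", "theta_local"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.dist not in FITNESS_DISTRIBUTIONS:
            raise ValueError(
                f"unknown fitness distribution {self.dist!r}; "
                f"expected one of {FITNESS_DISTRIBUTIONS}"
            )


@dataclass(frozen=True)
class Clone:
    """A clone: cells sharing one mutation set, plus lineage bookkeeping."""

    clone_id: int
    parent_id: int | None
    birth_step: int
    c_a: int
    c_n: int
    mutation_ids: frozenset[int]

    def __post_init__(self) -> None:
        if self.c_a < 0 or self.c_n < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n_drivers(self) -> int:
        return len(self.mutation_ids)


class MutationRegistry:
    """Infinite-sites mutation supply: id -> fitness effect F(m).

    Ids are handed out by a monotone counter and never reused.  The founder
    mutation (id 0) has effect 0 so the founder clone has fitness exactly 1.
    """

    def __init__(self) -> None:
        self._effects: dict[int, float] = {0: 0.0}
        self._next_id: int = 1

    def new_mutation(self, effect: float) -> int:
        if effect < 0:
            raise ValueError("fitness effects must be non-negative")
        mid = self._next_id
        self._next_id += 1
        self._effects[mid] = float(effect)
        return mid

    def effect(self, mutation_id: int) -> float:
        try:
            return self._effects[mutation_id]
        except KeyError:
            raise KeyError(f"unknown mutation id {mutation_id}") from None

    def __len__(self) -> int:
        return len(self._effects)

    def __contains__(self, mutation_id: int) -> bool:
        return mutation_id in self._effects


@dataclass
class Population:
    """The set of clones at time step t, with cached alive/necrotic totals."""

    clones: dict[int, Clone] = field(default_factory=dict)
    t: int = 0

    @property
    def total_alive(self) -> int:
        return sum(c.c_a for c in self.clones.values())

    @property
    def total_necrotic(self) -> int:
        return sum(c.c_n for c in self.clones.values())

    @property
    def total_cells(self) -> int:
        return self.total_alive + self.total_necrotic


@dataclass(frozen=True)
class StepDraws:
    """Per-clone stochastic counts for one step (transient)."""

    births: int
    deaths: int
    mutants: int
    necrotic: int

    def __post_init__(self) -> None:
        if min(self.births, self.deaths, self.mutants, self.necrotic) < 0:
            raise ValueError("draws must be non-negative")


def _binomial(rng: np.random.Generator, n: int, p: float) -> int:
    """Binomial draw that skips degenerate cases without consuming RNG state."""
    if n == 0 or p == 0.0:
        return 0
    if p >= 1.0:
        return n
    return int(rng.binomial(n, p))


def sample_fitness_effect(params: Parameters, rng: np.random.Generator) -> float:
    """Draw one driver fitness effect F(m) >= 0 from the configured distribution.

    ``const`` returns exactly ``theta_fit``; ``uni`` is uniform on
    [0, 2*theta_fit]; ``exp`` is exponential with mean ``theta_fit``;
    ``norm`` is the normal with location ``theta_fit`` and scale
    ``theta_fit / 2`` truncated to [0, inf), which has mean
    ~1.0276*theta_fit.  With ``theta_fit == 0`` every distribution is the
    point mass at 0 and no RNG state is consumed.
    """
    mu = params.theta_fit
    if mu == 0.0:
        return 0.0
    if params.dist == "const":
        return mu
    if params.dist == "uni":
        return float(rng.uniform(0.0, 2.0 * mu))
    if params.dist == "exp":
        return float(rng.exponential(mu))
    if params.dist == "norm":
        # Rejection sampling of the [0, inf)-truncated normal; the lower
        # bound sits 2 sigma below the location, so acceptance is ~0.977.
        sigma = mu / 2.0
        while True:
            x = float(rng.normal(mu, sigma))
            if x >= 0.0:
                return x
    raise ValueError(f"unknown fitness distribution {params.dist!r}")


def sample_fitness_effects(
    params: Parameters, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Vectorized :func:`sample_fitness_effect` (for analysis, not the engine)."""
    mu = params.theta_fit
    if mu == 0.0:
        return np.zeros(size)
    if params.dist == "const":
        return np.full(size, mu)
    if params.dist == "uni":
        return rng.uniform(0.0, 2.0 * mu, size)
    if params.dist == "exp":
        return rng.exponential(mu, size)
    out = rng.normal(mu, mu / 2.0, size)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mu, mu / 2.0, int(bad.sum()))
        bad = out < 0
    return out


def clone_fitness(clone: Clone, registry: MutationRegistry) -> float:
    """Clone fitness: 1 plus the sum of its mutations' effects (additive)."""
    return 1.0 + math.fsum(registry.effect(m) for m in clone.mutation_ids)


def step_clone(
    clone: Clone,
    p_birth: float,
    p_death: float,
    p_necro: float,
    theta_mut: float,
    rng: np.random.Generator,
) -> tuple[Clone, StepDraws]:
    """Advance one clone by one step; returns the updated clone and its draws.

    Births and deaths are independent binomials from the step-start alive
    count; mutated newborns (B_m ~ Bin(B_b, theta_mut)) leave the clone, and
    B_n ~ Bin(B_d, p_necro) of the dead cells become necrotic rather than
    being removed.  A clone with no alive cells is returned unchanged.
    """
    for name, p in (("p_birth", p_birth), ("p_death", p_death), ("p_necro", p_necro)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be a probability, got {p}")
    if clone.c_a == 0:
        return clone, StepDraws(0, 0, 0, 0)
    b_d = _binomial(rng, clone.c_a, p_death)
    b_b = _binomial(rng, clone.c_a, p_birth)
    b_m = _binomial(rng, b_b, theta_mut)
    b_n = _binomial(rng, b_d, p_necro)
    assert b_m <= b_b and b_n <= b_d
    updated = replace(clone, c_a=clone.c_a + b_b - b_d - b_m, c_n=clone.c_n + b_n)
    return updated, StepDraws(b_b, b_d, b_m, b_n)


def spawn_children(
    parent: Clone,
    mut: int,
    registry: MutationRegistry,
    params: Parameters,
    birth_step: int,
    rng: np.random.Generator,
) -> list[Clone]:
    """Create ``mut`` child clones, each one cell with one fresh mutation.

    Each child's mutation set is the parent's plus one new id whose effect
    is drawn from the fitness distribution; the child's clone id equals its
    new mutation id.
    """
    if mut < 0:
        raise ValueError("mut must be non-negative")
    children = []
    for _ in range(mut):
        effect = sample_fitness_effect(params, rng)
        mid = registry.new_mutation(effect)
        children.append(
            Clone(
                clone_id=mid,
                parent_id=parent.clone_id,
                birth_step=birth_step,
                c_a=1,
                c_n=0,
                mutation_ids=parent.mutation_ids | {mid},
            )
        )
    return children
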