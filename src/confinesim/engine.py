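"""Drive full simulations from a founder cell to a stopping condition.

A run starts from ``C0 = {(init_cells, 0, {m0})}`` and repeatedly applies
the per-step update (confinement geometry, then birth/death/mutation/
necrosis draws per clone) until one of three stop conditions: the alive
population goes extinct, the total cell count exceeds ``max_pop``, or
``max_steps`` is reached.  A run that terminates below ``min_pop`` before
``max_steps`` is discarded and restarted from a fresh deterministic
sub-stream, so every accepted run describes a tumour that actually grew.

Two execution paths exist: :func:`advance` steps a :class:`~confinesim.core.
Population` of clone objects one step at a time (the reference semantics,
used by tests and small experiments), while :func:`run` executes whole runs
through the jitted array kernel in :mod:`confinesim._kernel` (required to
make the founder-attempt restart phase affordable).  Checkpoints are
recorded the first time the alive population reaches each power of two, and
at the terminal state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .core import (
    Clone,
    MutationRegistry,
    Parameters,
    Population,
    clone_fitness,
    spawn_children,
    step_clone,
)
from .geometry import (
    birth_probability,
    local_fraction,
    necrosis_probability,
    shell_fraction,
)

__all__ = [
    "RunConfig",
    "Checkpoint",
    "RunResult",
    "initial_population",
    "advance",
    "run",
]

#: Termination labels, indexed by the kernel's status codes.
TERMINATION_LABELS = ("max_steps_reached", "max_pop_exceeded", "extinct")


@dataclass(frozen=True)
class RunConfig:
    """Execution configuration for one simulation run.

    Defaults target a realistically sized tumour: runs must reach
    ``min_pop`` = 1000 cells to count, and stop above ``max_pop`` =
    1000 * 2**20 (~1e9) cells, i.e. 20 population doublings from
    ``min_pop``.  ``step_size`` = 0.01 is the turnover probability per step
    calibrated so that homeostatic populations of >= 100 cells essentially
    never go extinct within 1000 steps.
    """

    step_size: float = 0.01
    min_pop: int = 1000
    max_pop: int = 1000 * 2**20
    max_steps: int = 10**6
    metric_cutoff: float = 0.001
    seed: int = 0
    max_restarts: int = 1000
    init_cells: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.step_size <= 1.0:
            raise ValueError("step_size must be in (0, 1]")
        if self.min_pop > self.max_pop:
            raise ValueError("min_pop must not exceed max_pop")
        if not 0.0 <= self.metric_cutoff < 1.0:
            raise ValueError("metric_cutoff must be in [0, 1)")
        if self.init_cells < 1:
            raise ValueError("init_cells must be at least 1")
        if self.max_restarts < 0:
            raise ValueError("max_restarts must be non-negative")


@dataclass(frozen=True)
class Checkpoint:
    """Population summary recorded at an alive-population doubling."""

    step: int
    pop_alive: int
    pop_necrotic: int
    mean_drivers: float
    diversity: float


@dataclass
class RunResult:
    """Outcome of one accepted simulation run.

    ``clones`` is the full lineage (one row per clone ever created in the
    accepted attempt), ``checkpoints`` one row per recorded checkpoint, and
    ``clone_populations`` the per-clone alive counts at every checkpoint
    (the raw material for Muller/fish plots).
    """

    params: Parameters
    config: RunConfig
    termination: str
    restarts_used: int
    final_step: int
    final_alive: int
    final_necrotic: int
    clones: pd.DataFrame
    checkpoints: pd.DataFrame
    clone_populations: pd.DataFrame
    failed: bool = False
    log: dict = field(default_factory=dict)

    @property
    def final_metric_point(self) -> tuple[float, float]:
        """(mean drivers per cell, clonal diversity) at the final checkpoint.

        Metrics are undefined at an extinct terminal state (no alive
        cells); in that rare case the last checkpoint at which they are
        defined is used.
        """
        defined = self.checkpoints.dropna(subset=["mean_drivers", "diversity"])
        row = defined.iloc[-1]
        return float(row["mean_drivers"]), float(row["diversity"])

    def checkpoint_records(self) -> list[Checkpoint]:
        """The checkpoint table as typed records."""
        return [
            Checkpoint(
                step=int(r.step),
                pop_alive=int(r.pop_alive),
                pop_necrotic=int(r.pop_necrotic),
                mean_drivers=float(r.mean_drivers),
                diversity=float(r.diversity),
            )
            for r in self.checkpoints.itertuples()
        ]

    def to_population(self) -> Population:
        """Materialize the surviving clones as a :class:`Population` of objects."""
        sets: dict[int, frozenset[int]] = {}
        by_id = self.clones.set_index("clone_id")
        parents = by_id["parent_id"].to_dict()

        def mset(cid: int) -> frozenset[int]:
            if cid not in sets:
                pid = parents[cid]
                if pid < 0:
                    sets[cid] = frozenset({0})
                else:
                    sets[cid] = mset(pid) | {cid}
            return sets[cid]

        clones = {}
        for row in self.clones.itertuples():
            if row.n_alive > 0 or row.n_necrotic > 0:
                clones[row.clone_id] = Clone(
                    clone_id=int(row.clone_id),
                    parent_id=None if row.parent_id < 0 else int(row.parent_id),
                    birth_step=int(row.birth_step),
                    c_a=int(row.n_alive),
                    c_n=int(row.n_necrotic),
                    mutation_ids=mset(int(row.clone_id)),
                )
        return Population(clones=clones, t=self.final_step)


def initial_population(init_cells: int = 1) -> tuple[Population, MutationRegistry]:
    """The starting state: one clone of ``init_cells`` alive cells, mutation {0}."""
    if init_cells < 1:
        raise ValueError("init_cells must be at least 1")
    founder = Clone(
        clone_id=0,
        parent_id=None,
        birth_step=0,
        c_a=init_cells,
        c_n=0,
        mutation_ids=frozenset({0}),
    )
    return Population(clones={0: founder}, t=0), MutationRegistry()


def advance(
    pop: Population,
    params: Parameters,
    config: RunConfig,
    registry: MutationRegistry,
    rng: np.random.Generator,
) -> Population:
    """Apply one simulation step to every clone, returning the next population.

    The global shell fraction is computed once from the step-start totals;
    each clone's local fraction from its own step-start counts.  Clones are
    processed in ascending clone id (the reproducibility contract), and
    children spawned by mutated newborns join the next population with one
    cell each.
    """
    ca_tot = pop.total_alive
    cn_tot = pop.total_necrotic
    frac = shell_fraction(ca_tot, cn_tot, params.theta_conf)
    new_clones: dict[int, Clone] = {}
    children: list[Clone] = []
    for cid in sorted(pop.clones):
        clone = pop.clones[cid]
        if clone.c_a == 0:
            new_clones[cid] = clone
            continue
        local = local_fraction(clone, params.theta_local)
        p_b = birth_probability(clone_fitness(clone, registry), frac, local, config.step_size)
        p_n = necrosis_probability(frac, local)
        updated, draws = step_clone(clone, p_b, config.step_size, p_n, params.theta_mut, rng)
        new_clones[cid] = updated
        if draws.mutants:
            children.extend(
                spawn_children(clone, draws.mutants, registry, params, pop.t + 1, rng)
            )
    for child in children:
        new_clones[child.clone_id] = child
    return Population(clones=new_clones, t=pop.t + 1)


def _result_from_attempt(
    params: Parameters, config: RunConfig, attempt: tuple, restarts: int, failed: bool
) -> RunResult:
    (
        status,
        t,
        parent,
        birth_step,
        n_drivers,
        fitness,
        effect,
        c_a,
        c_n,
        chk_step,
        chk_ca,
        chk_cn,
        chk_md,
        chk_div,
        snap_chk,
        snap_clone,
        snap_pop,
    ) = attempt
    clones = pd.DataFrame(
        {
            "clone_id": np.arange(len(parent), dtype=np.int64),
            "parent_id": parent,
            "birth_step": birth_step,
            "n_drivers": n_drivers,
            "fitness": fitness,
            "fitness_effect": effect,
            "n_alive": c_a,
            "n_necrotic": c_n,
        }
    )
    checkpoints = pd.DataFrame(
        {
            "step": chk_step,
            "pop_alive": chk_ca,
            "pop_necrotic": chk_cn,
            "mean_drivers": chk_md,
            "diversity": chk_div,
        }
    )
    clone_pops = pd.DataFrame(
        {
            "step": chk_step[snap_chk],
            "clone_id": snap_clone,
            "pop": snap_pop,
        }
    )
    final_alive = int(chk_ca[-1])
    final_necrotic = int(chk_cn[-1])
    return RunResult(
        params=params,
        config=config,
        termination="restarts_exhausted" if failed else TERMINATION_LABELS[status],
        restarts_used=restarts,
        final_step=int(t),
        final_alive=final_alive,
        final_necrotic=final_necrotic,
        clones=clones,
        checkpoints=checkpoints,
        clone_populations=clone_pops,
        failed=failed,
        log={
            "seed": config.seed,
            "restarts_used": restarts,
            "termination": "restarts_exhausted" if failed else TERMINATION_LABELS[status],
            "steps": int(t),
            "final_alive": final_alive,
            "final_necrotic": final_necrotic,
        },
    )


def run(params: Parameters, config: RunConfig) -> RunResult:
    """Execute one full simulation with restart-on-early-extinction semantics.

    Attempts are drawn from deterministic sub-streams of ``config.seed``
    (one per restart index).  An attempt that terminates with fewer than
    ``min_pop`` total cells before ``max_steps`` is discarded; after
    ``max_restarts`` discarded attempts the last attempt is returned with
    ``failed=True`` and ``termination='restarts_exhausted'``.
    """
    dist_code = _kernel.DIST_CODES[params.dist]
    attempt = None
    for restart in range(config.max_restarts + 1):
        attempt = _kernel.simulate_attempt(
            _kernel.mix_seed(config.seed, restart),
            params.theta_mut,
            params.theta_fit,
            params.theta_conf,
            params.theta_local,
            dist_code,
            config.step_size,
            config.init_cells,
            config.max_pop,
            config.max_steps,
            config.metric_cutoff,
        )
        status = attempt[0]
        total = int(attempt[10][-1] + attempt[11][-1])  # chk_ca[-1] + chk_cn[-1]
        if status == _kernel.MAX_STEPS or total >= config.min_pop:
            return _result_from_attempt(params, config, attempt, restart, failed=False)
    return _result_from_attempt(
        params, config, attempt, config.max_restarts, failed=True
    )
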