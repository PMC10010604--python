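"""Engine tests: initial state, stepping semantics, reduction chain, run().

The reduction-chain tests pit :func:`confinesim.engine.advance` against
independent minimal simulators of the nested sub-models (pure turnover;
turnover + mutation; + fitness; + global confinement), written here from
scratch.  Because degenerate draws consume no generator state, a run of the
full engine with the corresponding parameters zeroed must be *bitwise*
identical to the sub-model under the same seed.
"""

from __future__ import annotations


import numpy as np
import pytest
import scipy.stats

from confinesim import (
    Parameters,
    RunConfig,
    advance,
    initial_population,
    run,
)
from confinesim import _kernel
from confinesim.core import MutationRegistry


def grow_population(seed=5, init_cells=300, steps=25, theta_mut=0.02, theta_fit=0.3):
    """A seeded multi-clone population to start equivalence tests from."""
    params = Parameters(theta_mut=theta_mut, theta_fit=theta_fit, dist="exp")
    config = RunConfig(seed=seed)
    pop, registry = initial_population(init_cells)
    gen = np.random.default_rng(seed)
    for _ in range(steps):
        pop = advance(pop, params, config, registry, gen)
    return pop, registry


# independent sub-model oracles live in tests/_oracles.py (same draw-order
# contract as the engine; degenerate draws skipped)
from _oracles import oracle_advance


def _as_state(pop, registry):
    from confinesim.core import clone_fitness

    return {
        cid: [c.c_a, c.c_n, clone_fitness(c, registry)]
        for cid, c in pop.clones.items()
    }


@pytest.mark.parametrize(
    "level,params",
    [
        ("turnover", Parameters(theta_mut=0.0, theta_fit=0.0)),
        ("mutation", Parameters(theta_mut=0.02, theta_fit=0.0)),
        ("fitness", Parameters(theta_mut=0.02, theta_fit=0.3)),
        ("global", Parameters(theta_mut=0.02, theta_fit=0.3, theta_conf=0.8)),
    ],
)
def test_reduction_chain_bitwise(level, params):
    """Zeroed parameters reproduce each nested sub-model bitwise."""
    # sub-models without selection require an all-neutral mutation registry
    pop, registry = grow_population(theta_fit=params.theta_fit)
    config = RunConfig(seed=0)
    state = _as_state(pop, registry)

    gen_engine = np.random.default_rng(424242)
    gen_oracle = np.random.default_rng(424242)
    for _ in range(40):
        pop = advance(pop, params, config, registry, gen_engine)
        state = oracle_advance(state, level, params, config.step_size, gen_oracle)

    from confinesim.core import clone_fitness

    engine_state = {
        cid: (c.c_a, c.c_n, clone_fitness(c, registry))
        for cid, c in pop.clones.items()
    }
    oracle_state = {cid: tuple(v) for cid, v in state.items()}
    assert set(engine_state) == set(oracle_state)
    for cid in engine_state:
        e_ca, e_cn, e_fit = engine_state[cid]
        o_ca, o_cn, o_fit = oracle_state[cid]
        assert (e_ca, e_cn) == (o_ca, o_cn), f"clone {cid} differs"
        assert e_fit == pytest.approx(o_fit, rel=1e-12)


def test_turnover_submodel_never_accrues_necrosis():
    """Without confinement C_n stays 0 for all t."""
    params = Parameters(theta_mut=0.01, theta_fit=0.1)
    config = RunConfig(seed=1)
    pop, registry = initial_population(200)
    gen = np.random.default_rng(11)
    for _ in range(100):
        pop = advance(pop, params, config, registry, gen)
    assert pop.total_necrotic == 0
    assert pop.t == 100


# ---------------------------------------------------------------------------
# basic engine semantics
# ---------------------------------------------------------------------------


class TestInitialPopulation:
    def test_founder_state(self):
        pop, registry = initial_population()
        assert (pop.total_alive, pop.total_necrotic, pop.t) == (1, 0, 0)
        (founder,) = pop.clones.values()
        assert founder.mutation_ids == frozenset({0})
        assert registry.effect(0) == 0.0

    def test_founder_metrics(self):
        from confinesim.metrics import metric_point

        pop, _ = initial_population()
        point = metric_point(pop, 0.0)
        assert (point.mean_drivers, point.diversity) == (1.0, 1.0)

    def test_rejects_empty_start(self):
        with pytest.raises(ValueError):
            initial_population(0)


class TestAdvance:
    def test_extinct_population_only_ticks_clock(self, rng):
        from confinesim.core import Clone, Population

        dead = Population(
            clones={
                0: Clone(0, None, 0, c_a=0, c_n=4, mutation_ids=frozenset({0}))
            },
            t=17,
        )
        registry = MutationRegistry()
        after = advance(dead, Parameters(), RunConfig(), registry, rng)
        assert after.t == 18
        assert {c.clone_id: (c.c_a, c.c_n) for c in after.clones.values()} == {
            0: (0, 4)
        }

    def test_no_mutation_keeps_clone_count(self, rng):
        pop, registry = grow_population()
        n = len(pop.clones)
        stepped = advance(pop, Parameters(theta_mut=0.0), RunConfig(), registry, rng)
        assert len(stepped.clones) == n

    def test_homeostatic_mean_is_conserved(self):
        """E[C_a] is a martingale when birth and death probabilities match."""
        params = Parameters(theta_mut=0.0, theta_fit=0.0)
        config = RunConfig(seed=0)
        finals = []
        for rep in range(200):
            pop, registry = initial_population(100)
            gen = np.random.default_rng(1000 + rep)
            for _ in range(200):
                pop = advance(pop, params, config, registry, gen)
            finals.append(pop.total_alive)
        mean = np.mean(finals)
        se = np.std(finals) / np.sqrt(len(finals))
        assert abs(mean - 100) < 4 * max(se, 1e-9)

    def test_supercritical_growth_matches_expectation(self):
        """With fitness f > 1 unconfined, E[C_a] grows as (1 + ss (f-1))^t."""
        config = RunConfig(seed=0)
        params = Parameters(theta_mut=0.0, theta_fit=0.5, dist="const")
        finals = []
        for rep in range(60):
            pop, registry = initial_population(500)
            mid = registry.new_mutation(0.5)
            founder = pop.clones[0]
            from dataclasses import replace

            pop.clones[0] = replace(founder, mutation_ids=frozenset({0, mid}))
            gen = np.random.default_rng(2000 + rep)
            for _ in range(100):
                pop = advance(pop, params, config, registry, gen)
            finals.append(pop.total_alive)
        expected = 500 * (1 + 0.01 * 0.5) ** 100
        mean = np.mean(finals)
        se = np.std(finals) / np.sqrt(len(finals))
        assert abs(mean - expected) < 4 * se


class TestRun:
    def test_zero_max_steps_returns_initial_state(self):
        result = run(Parameters(), RunConfig(max_steps=0, min_pop=1, seed=1))
        assert result.termination == "max_steps_reached"
        assert result.final_alive == 1 and result.final_necrotic == 0
        assert len(result.checkpoints) == 1
        assert result.checkpoints.iloc[0]["step"] == 0

    def test_determinism_same_seed_same_tables(self):
        params = Parameters(theta_mut=2e-3, theta_fit=0.5, dist="const")
        config = RunConfig(min_pop=100, max_pop=20_000, seed=9, max_restarts=50_000)
        a, b = run(params, config), run(params, config)
        assert a.termination == b.termination
        assert a.restarts_used == b.restarts_used
        assert a.clones.equals(b.clones)
        assert a.checkpoints.equals(b.checkpoints)
        assert a.clone_populations.equals(b.clone_populations)

    def test_lineage_is_a_tree_rooted_at_founder(self, fast_run):
        clones = fast_run.clones
        assert clones.iloc[0]["parent_id"] == -1
        nonroot = clones.iloc[1:]
        assert (nonroot["parent_id"] < nonroot["clone_id"]).all()
        assert (nonroot["n_drivers"] == 1 +
                clones.set_index("clone_id").loc[nonroot["parent_id"], "n_drivers"].values).all()

    def test_checkpoints_ordered_with_diversity_floor(self, fast_run):
        chk = fast_run.checkpoints
        assert chk["step"].is_monotonic_increasing
        assert chk["step"].is_unique
        assert (chk["pop_necrotic"].diff().dropna() >= 0).all()
        defined = chk["diversity"].dropna()
        assert (defined >= 1.0).all()
        records = fast_run.checkpoint_records()
        assert len(records) == len(chk)
        assert records[0].step == 0 and records[0].pop_alive == 1

    def test_growth_run_terminates_at_max_pop(self, fast_run):
        assert fast_run.termination == "max_pop_exceeded"
        assert fast_run.final_alive + fast_run.final_necrotic > fast_run.config.max_pop

    def test_restarts_exhausted_surfaces_failure(self):
        # neutral, mutation-free runs from one cell essentially always die
        # before reaching min_pop=10^4
        params = Parameters(theta_mut=0.0, theta_fit=0.0)
        config = RunConfig(
            min_pop=10**4, max_pop=10**5, max_steps=50_000, seed=3, max_restarts=2
        )
        result = run(params, config)
        assert result.failed
        assert result.termination == "restarts_exhausted"
        assert result.restarts_used == 2

    def test_to_population_round_trip(self, fast_run):
        pop = fast_run.to_population()
        assert pop.total_alive == fast_run.final_alive
        assert pop.total_necrotic == fast_run.final_necrotic
        for clone in pop.clones.values():
            if clone.parent_id is not None:
                parent = fast_run.clones.set_index("clone_id").loc[clone.parent_id]
                assert clone.n_drivers == parent["n_drivers"] + 1


def test_kernel_and_object_layer_agree_in_law():
    """Final alive counts of the jitted kernel match the Python engine."""
    params = Parameters(theta_mut=0.0, theta_fit=0.0, theta_conf=0.6)
    config = RunConfig(seed=0, min_pop=0, max_steps=120)
    kernel_finals = []
    for rep in range(1500):
        a = _kernel.simulate_attempt(
            _kernel.mix_seed(rep, 0), 0.0, 0.0, 0.6, 0.0, 2, 0.01, 150,
            10**12, 120, 0.001,
        )
        kernel_finals.append(a[10][-1])
    py_finals = []
    for rep in range(300):
        pop, registry = initial_population(150)
        gen = np.random.default_rng(50_000 + rep)
        for _ in range(120):
            pop = advance(pop, params, config, registry, gen)
        py_finals.append(pop.total_alive)
    stat, pval = scipy.stats.ks_2samp(kernel_finals, py_finals)
    assert pval > 1e-3
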