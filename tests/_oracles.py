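"""Independent reference implementations used as oracles by the tests.

Everything here is deliberately written from scratch against the model
definition (no imports from the package's stepping code) so that agreement
with the engine is an actual cross-check.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_shell_fraction(c_a: int, c_n: int, theta: float) -> float:
    if c_a == 0:
        return 0.0
    if theta == 0.0:
        return 1.0
    r = ((c_a + c_n) * 3.0 / (4.0 * math.pi)) ** (1.0 / 3.0) - 1.0 / theta
    r = max(r, 0.0)
    return min(((c_a + c_n) - (4.0 * math.pi / 3.0) * r**3) / c_a, 1.0)


def oracle_advance(state, level, params, step_size, gen):
    """One step of the nested sub-model ``level`` on ``state``.

    ``state`` maps clone id -> [c_a, c_n, fitness]; levels are
    ``turnover`` (birth/death only), ``mutation`` (+ neutral mutations),
    ``fitness`` (+ selection), ``global`` (+ global confinement/necrosis).
    Draw order per clone (ascending id): B_d, B_b, B_m, B_n, then one
    fitness effect per child; degenerate draws skipped.
    """
    theta_mut = params.theta_mut if level in ("mutation", "fitness", "global") else 0.0
    use_fit = level in ("fitness", "global")
    frac = 1.0
    if level == "global":
        ca_tot = sum(v[0] for v in state.values())
        cn_tot = sum(v[1] for v in state.values())
        frac = oracle_shell_fraction(ca_tot, cn_tot, params.theta_conf)
    next_id = max(state) + 1
    children = {}
    for cid in sorted(state):
        c_a, c_n, fit = state[cid]
        if c_a == 0:
            continue
        p_b = min(1.0, (fit if use_fit else 1.0) * frac * step_size)
        b_d = gen.binomial(c_a, step_size) if step_size > 0 else 0
        b_b = gen.binomial(c_a, p_b) if p_b > 0 else 0
        b_m = gen.binomial(b_b, theta_mut) if (b_b > 0 and theta_mut > 0) else 0
        p_n = 1.0 - frac
        b_n = gen.binomial(b_d, p_n) if (b_d > 0 and p_n > 0) else 0
        state[cid] = [c_a + b_b - b_d - b_m, c_n + b_n, fit]
        for _ in range(b_m):
            eff = gen.exponential(params.theta_fit) if params.theta_fit > 0 else 0.0
            children[next_id] = [1, 0, fit + eff]
            next_id += 1
    state.update(children)
    return state


def per_cell_step(n_cells, p_birth, p_death, p_necro, theta_mut, gen, n_rep):
    """Per-cell Bernoulli simulator of one clone step, ``n_rep`` replicates.

    Each of the ``n_cells`` cells flips an independent birth coin and an
    independent death coin; each newborn flips a mutation coin and each
    dead cell a necrosis coin.  Returns (B_b, B_d, mut, B_n) arrays.
    """
    births = (gen.random((n_rep, n_cells)) < p_birth).sum(axis=1)
    deaths = (gen.random((n_rep, n_cells)) < p_death).sum(axis=1)
    mut = np.array([(gen.random(int(b)) < theta_mut).sum() for b in births])
    necro = np.array([(gen.random(int(d)) < p_necro).sum() for d in deaths])
    return births, deaths, mut, necro


def two_sample_chisquare(sample_a, sample_b, min_count=25):
    """Two-sample chi-square p-value over lumped discrete categories.

    ``sample_a``/``sample_b`` are sequences of hashable category labels;
    categories with fewer than ``min_count`` combined observations are
    lumped into one.
    """
    import scipy.stats
    from collections import Counter

    ca, cb = Counter(sample_a), Counter(sample_b)
    keys = sorted(set(ca) | set(cb))
    big = [k for k in keys if ca[k] + cb[k] >= min_count]
    table_a = [ca[k] for k in big] + [sum(ca[k] for k in keys if k not in big)]
    table_b = [cb[k] for k in big] + [sum(cb[k] for k in keys if k not in big)]
    table = np.array([table_a, table_b])
    table = table[:, table.sum(axis=0) > 0]
    _, pval, _, _ = scipy.stats.chi2_contingency(table)
    return pval
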