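"""Array-based jitted simulation kernel behind :func:`confinesim.engine.run`.

One accepted run at default parameters burns millions of tiny steps in
discarded founder attempts (restart-on-early-extinction), so the hot loop is
compiled with numba and operates on flat clone arrays instead of the object
layer in :mod:`confinesim.core`.  The two implementations share the model
contract and are cross-checked distributionally in the test suite.

Clone mutation sets are never materialized here: each clone is created by
exactly one new mutation, so the lineage (parent links) encodes the sets and
``n_drivers`` is the lineage depth plus one.

The kernel uses numba's internal PRNG, reseeded per attempt from a
splitmix-style hash of (run seed, restart index), which keeps every run
reproducible regardless of how many restarts occur.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Termination codes shared with the engine layer.
MAX_STEPS = 0
MAX_POP = 1
EXTINCT = 2

DIST_CODES = {"const": 0, "uni": 1, "exp": 2, "norm": 3}

_FOUR_THIRDS_PI = 4.0 * np.pi / 3.0


def mix_seed(seed: int, restart: int) -> int:
    """Derive the 32-bit attempt seed for a (run seed, restart index) pair."""
    x = (int(seed) + int(restart) * 0x9E3779B9) & 0xFFFFFFFF
    x ^= x >> 16
    x = (x * 0x85EBCA6B) & 0xFFFFFFFF
    x ^= x >> 13
    x = (x * 0xC2B2AE35) & 0xFFFFFFFF
    x ^= x >> 16
    return x


@njit(cache=True, inline="always")
def _shell_fraction(c_a, c_n, theta):
    if c_a == 0:
        return 0.0
    if theta == 0.0:
        return 1.0
    r_total = (3.0 * (c_a + c_n) / (4.0 * np.pi)) ** (1.0 / 3.0)
    r_core = r_total - 1.0 / theta
    if r_core < 0.0:
        r_core = 0.0
    shell_volume = (c_a + c_n) - _FOUR_THIRDS_PI * r_core**3
    frac = shell_volume / c_a
    return frac if frac < 1.0 else 1.0


@njit(cache=True, inline="always")
def _sample_effect(dist_code, mu):
    if mu == 0.0:
        return 0.0
    if dist_code == 0:
        return mu
    if dist_code == 1:
        return np.random.uniform(0.0, 2.0 * mu)
    if dist_code == 2:
        return np.random.exponential(mu)
    while True:  # [0, inf)-truncated normal, ~0.977 acceptance
        x = np.random.normal(mu, mu / 2.0)
        if x >= 0.0:
            return x


@njit(cache=True)
def simulate_attempt(
    seed32,
    theta_mut,
    theta_fit,
    theta_conf,
    theta_local,
    dist_code,
    step_size,
    init_cells,
    max_pop,
    max_steps,
    cutoff,
):
    """Run one attempt from ``init_cells`` founder cells to a stop condition.

    Returns (status, t, clone arrays, checkpoint arrays, snapshot arrays,
    C_a, C_n).  Checkpoints are taken the first time the alive population
    reaches each power of two (collapsed to one record per step) and at the
    terminal state; snapshots record every alive clone's size per checkpoint.
    """
    np.random.seed(seed32)

    cap = 1024
    parent = np.full(cap, -1, np.int64)
    birth_step = np.zeros(cap, np.int64)
    n_drivers = np.zeros(cap, np.int64)
    fitness = np.zeros(cap, np.float64)
    effect = np.zeros(cap, np.float64)
    c_a = np.zeros(cap, np.int64)
    c_n = np.zeros(cap, np.int64)
    n_clones = 1
    n_drivers[0] = 1
    fitness[0] = 1.0
    c_a[0] = init_cells

    active = np.empty(cap, np.int64)
    active[0] = 0
    n_active = 1
    scratch = np.empty(cap, np.int64)

    ca_tot = np.int64(init_cells)
    cn_tot = np.int64(0)

    chk_cap = 256
    chk_step = np.empty(chk_cap, np.int64)
    chk_ca = np.empty(chk_cap, np.int64)
    chk_cn = np.empty(chk_cap, np.int64)
    chk_md = np.empty(chk_cap, np.float64)
    chk_div = np.empty(chk_cap, np.float64)
    n_chk = 0

    snap_cap = 4096
    snap_chk = np.empty(snap_cap, np.int64)
    snap_clone = np.empty(snap_cap, np.int64)
    snap_pop = np.empty(snap_cap, np.int64)
    n_snap = 0

    next_thr = np.int64(1)
    t = np.int64(0)

    while True:
        # --- checkpoint on alive-population doubling (thresholds 2^k) ---
        if ca_tot >= next_thr:
            while next_thr <= ca_tot:
                next_thr *= 2
            thr = ca_tot * cutoff
            f_ca = 0.0
            f_dca = 0.0
            f_ca2 = 0.0
            for j in range(n_active):
                i = active[j]
                cai = c_a[i]
                if cai >= thr:
                    f_ca += cai
                    f_dca += n_drivers[i] * cai
                    f_ca2 += float(cai) * float(cai)
            if n_chk >= chk_cap:
                chk_cap *= 2
                chk_step = _grow_i(chk_step, chk_cap)
                chk_ca = _grow_i(chk_ca, chk_cap)
                chk_cn = _grow_i(chk_cn, chk_cap)
                chk_md = _grow_f(chk_md, chk_cap)
                chk_div = _grow_f(chk_div, chk_cap)
            chk_step[n_chk] = t
            chk_ca[n_chk] = ca_tot
            chk_cn[n_chk] = cn_tot
            chk_md[n_chk] = f_dca / f_ca if f_ca > 0 else np.nan
            chk_div[n_chk] = f_ca * f_ca / f_ca2 if f_ca2 > 0 else np.nan
            for j in range(n_active):
                i = active[j]
                if c_a[i] > 0:
                    if n_snap >= snap_cap:
                        snap_cap *= 2
                        snap_chk = _grow_i(snap_chk, snap_cap)
                        snap_clone = _grow_i(snap_clone, snap_cap)
                        snap_pop = _grow_i(snap_pop, snap_cap)
                    snap_chk[n_snap] = n_chk
                    snap_clone[n_snap] = i
                    snap_pop[n_snap] = c_a[i]
                    n_snap += 1
            n_chk += 1

        # --- stop conditions (extinction, max_pop, max_steps) ---
        status = -1
        if ca_tot == 0:
            status = EXTINCT
        elif ca_tot + cn_tot > max_pop:
            status = MAX_POP
        elif t >= max_steps:
            status = MAX_STEPS
        if status >= 0:
            # terminal checkpoint (if this step is not already recorded)
            if n_chk == 0 or chk_step[n_chk - 1] != t:
                thr = ca_tot * cutoff
                f_ca = 0.0
                f_dca = 0.0
                f_ca2 = 0.0
                for j in range(n_active):
                    i = active[j]
                    cai = c_a[i]
                    if cai >= thr and cai > 0:
                        f_ca += cai
                        f_dca += n_drivers[i] * cai
                        f_ca2 += float(cai) * float(cai)
                if n_chk >= chk_cap:
                    chk_cap *= 2
                    chk_step = _grow_i(chk_step, chk_cap)
                    chk_ca = _grow_i(chk_ca, chk_cap)
                    chk_cn = _grow_i(chk_cn, chk_cap)
                    chk_md = _grow_f(chk_md, chk_cap)
                    chk_div = _grow_f(chk_div, chk_cap)
                chk_step[n_chk] = t
                chk_ca[n_chk] = ca_tot
                chk_cn[n_chk] = cn_tot
                chk_md[n_chk] = f_dca / f_ca if f_ca > 0 else np.nan
                chk_div[n_chk] = f_ca * f_ca / f_ca2 if f_ca2 > 0 else np.nan
                for j in range(n_active):
                    i = active[j]
                    if c_a[i] > 0:
                        if n_snap >= snap_cap:
                            snap_cap *= 2
                            snap_chk = _grow_i(snap_chk, snap_cap)
                            snap_clone = _grow_i(snap_clone, snap_cap)
                            snap_pop = _grow_i(snap_pop, snap_cap)
                        snap_chk[n_snap] = n_chk
                        snap_clone[n_snap] = i
                        snap_pop[n_snap] = c_a[i]
                        n_snap += 1
                n_chk += 1
            return (
                status,
                t,
                parent[:n_clones].copy(),
                birth_step[:n_clones].copy(),
                n_drivers[:n_clones].copy(),
                fitness[:n_clones].copy(),
                effect[:n_clones].copy(),
                c_a[:n_clones].copy(),
                c_n[:n_clones].copy(),
                chk_step[:n_chk].copy(),
                chk_ca[:n_chk].copy(),
                chk_cn[:n_chk].copy(),
                chk_md[:n_chk].copy(),
                chk_div[:n_chk].copy(),
                snap_chk[:n_snap].copy(),
                snap_clone[:n_snap].copy(),
                snap_pop[:n_snap].copy(),
            )

        # --- one simulation step (frac/local from step-start state) ---
        frac = _shell_fraction(ca_tot, cn_tot, theta_conf)
        new_ca_tot = np.int64(0)
        n_new = 0
        n_born = 0
        for j in range(n_active):
            i = active[j]
            cai = c_a[i]
            local = _shell_fraction(cai, c_n[i], theta_local)
            pb = fitness[i] * frac * local * step_size
            if pb > 1.0:
                pb = 1.0
            b_d = np.random.binomial(cai, step_size) if cai > 0 else 0
            b_b = np.random.binomial(cai, pb) if (cai > 0 and pb > 0.0) else 0
            b_m = np.random.binomial(b_b, theta_mut) if (b_b > 0 and theta_mut > 0.0) else 0
            p_n = 1.0 - frac * local
            b_n = np.random.binomial(b_d, p_n) if (b_d > 0 and p_n > 0.0) else 0
            c_a[i] = cai + b_b - b_d - b_m
            c_n[i] += b_n
            new_ca_tot += c_a[i]
            cn_tot += b_n
            for _ in range(b_m):
                if n_clones >= cap:
                    cap *= 2
                    parent = _grow_i(parent, cap)
                    birth_step = _grow_i(birth_step, cap)
                    n_drivers = _grow_i(n_drivers, cap)
                    fitness = _grow_f(fitness, cap)
                    effect = _grow_f(effect, cap)
                    c_a = _grow_i(c_a, cap)
                    c_n = _grow_i(c_n, cap)
                    active = _grow_i(active, cap)
                    scratch = np.empty(cap, np.int64)
                eff = _sample_effect(dist_code, theta_fit)
                parent[n_clones] = i
                birth_step[n_clones] = t + 1
                n_drivers[n_clones] = n_drivers[i] + 1
                fitness[n_clones] = fitness[i] + eff
                effect[n_clones] = eff
                c_a[n_clones] = 1
                c_n[n_clones] = 0
                n_clones += 1
                n_new += 1
                n_born += 1
        # rebuild active list: surviving old actives, then newborn clones
        # (ids ascend, so the list stays sorted by clone id)
        m = 0
        for j in range(n_active):
            i = active[j]
            if c_a[i] > 0:
                scratch[m] = i
                m += 1
        for i in range(n_clones - n_new, n_clones):
            scratch[m] = i
            m += 1
        active, scratch = scratch, active
        n_active = m
        ca_tot = new_ca_tot + n_new
        t += 1


@njit(cache=True)
def _grow_i(arr, newcap):
    out = np.empty(newcap, np.int64)
    out[: arr.shape[0]] = arr
    return out


@njit(cache=True)
def _grow_f(arr, newcap):
    out = np.empty(newcap, np.float64)
    out[: arr.shape[0]] = arr
    return out
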