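"""Compiled inner loop of the tau-leaping stochastic simulator.

One realization advances integer compartment counts with bounded binomial /
trinomial / Poisson draws per adaptive time step (step chosen so the most
likely single-event probability is ``p_events``).  The trinomial virion-fate
draw is realized by the exact factorization Binomial(V, p1) followed by
Binomial(V - V_decay, p2/(1 - p1)).

These functions are internal; the public API with validation, trajectory
recording and reference (pure-numpy) step functions lives in ``simulate``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_once(
    beta_s: float,
    p: float,
    c: float,
    gamma: float,
    n_E: int,
    n_I: int,
    rate_E: float,
    rate_I: float,
    N_cells: int,
    p_events: float,
    max_time: float,
    V0: int,
    I0: int,
    seed: int,
):
    """Simulate one infection to completion; returns (T_final, t_final, censored)."""
    np.random.seed(seed)
    T = N_cells
    E = np.zeros(n_E, np.int64)
    I = np.zeros(n_I, np.int64)
    I[0] = I0
    V = V0
    t = 0.0
    E_out = np.zeros(n_E, np.int64)
    I_out = np.zeros(n_I, np.int64)

    while True:
        e_tot = 0
        for i in range(n_E):
            e_tot += E[i]
        i_tot = 0
        for j in range(n_I):
            i_tot += I[j]
        if V == 0 and e_tot == 0 and i_tot == 0:
            return T, t, False
        if t >= max_time:
            return T, t, True

        rmax = c
        bT = beta_s * T
        if bT > rmax:
            rmax = bT
        if rate_E > rmax:
            rmax = rate_E
        if rate_I > rmax:
            rmax = rate_I
        dt = p_events / rmax

        pE = dt * rate_E
        pI = dt * rate_I
        for i in range(n_E):
            E_out[i] = np.random.binomial(E[i], pE) if E[i] > 0 else 0
        for j in range(n_I):
            I_out[j] = np.random.binomial(I[j], pI) if I[j] > 0 else 0
        V_prod = np.random.poisson(dt * p * i_tot) if i_tot > 0 else 0
        p1 = dt * c
        V_decay = np.random.binomial(V, p1) if V > 0 else 0
        rem = V - V_decay
        p2 = dt * bT
        V_enter = np.random.binomial(rem, p2 / (1.0 - p1)) if rem > 0 else 0
        if V_enter > 0 and gamma < 1.0:
            V_suc = np.random.binomial(V_enter, gamma)
        else:
            V_suc = V_enter

        if T == 0 or V_suc == 0:
            N_inf = 0
        elif V_suc == 1:
            N_inf = 1
        else:
            draws = np.random.randint(0, T, V_suc)
            draws.sort()
            N_inf = 1
            for k in range(1, V_suc):
                if draws[k] != draws[k - 1]:
                    N_inf += 1

        T -= N_inf
        carry = N_inf
        for i in range(n_E):
            out = E_out[i]
            E[i] += carry - out
            carry = out
        for j in range(n_I):
            out = I_out[j]
            I[j] += carry - out
            carry = out
        V += V_prod - V_decay - V_enter
        t += dt


@njit(cache=True)
def run_ensemble(
    beta_s: float,
    p: float,
    c: float,
    gamma: float,
    n_E: int,
    n_I: int,
    rate_E: float,
    rate_I: float,
    N_cells: int,
    p_events: float,
    max_time: float,
    V0: int,
    I0: int,
    seeds: np.ndarray,
):
    """Run one realization per seed; returns (T_final, t_final, censored) arrays."""
    n = seeds.size
    T_final = np.empty(n, np.int64)
    t_final = np.empty(n, np.float64)
    censored = np.zeros(n, np.uint8)
    for k in range(n):
        Tf, tf, cen = run_once(
            beta_s,
            p,
            c,
            gamma,
            n_E,
            n_I,
            rate_E,
            rate_I,
            N_cells,
            p_events,
            max_time,
            V0,
            I0,
            seeds[k],
        )
        T_final[k] = Tf
        t_final[k] = tf
        if cen:
            censored[k] = 1
    return T_final, t_final, censored
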