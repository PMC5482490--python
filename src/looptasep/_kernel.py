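"""Compiled Gillespie kernel for the closed-loop TASEP.

Mirrors the reference engine exactly: two uniforms per event in the order
(waiting time, channel); channel enumeration order is de novo initiation,
elongation per ribosome in 5'→3' order, release, reinitiation.  Ribosome
A-site positions live in a circular buffer ordered 5'→3'; initiation and
reinitiation push at the front (site 1), release pops at the back (site L).
Ribosomes cannot overtake, so the order never changes.

``elong`` is indexed by site: ``elong[i]`` is the hop rate out of site ``i``
for ``1 <= i <= L-1`` (``elong[0]`` unused).
"""

import numpy as np
from numba import njit

__all__ = ["run_transcript", "run_batch"]


@njit(cache=True)
def run_transcript(
    L,
    elong,
    alpha,
    reinit_rate,
    release_rate,
    footprint,
    lifetime,
    seed,
    init_site,
    stop_on_arrival,
    grid,
    grid_counts,
):
    """Simulate one trajectory.

    Returns an array ``[occupancy_integral, de_novo, reinits, releases,
    completions, first_arrival_time, n_on_board]``; ``first_arrival_time`` is
    -1 if no ribosome ever reached the terminal site.  ``grid`` (ascending
    times <= lifetime) receives the instantaneous ribosome count at each grid
    time, added into ``grid_counts``.
    """
    np.random.seed(seed)
    cap = L // footprint + 2
    pos = np.zeros(cap, dtype=np.int64)
    head = 0
    n = 0
    if init_site > 0:
        pos[0] = init_site
        n = 1
    t = 0.0
    occ = 0.0
    de_novo = 0
    reinits = 0
    releases = 0
    completions = 0
    first_arrival = -1.0
    ngrid = grid.shape[0]
    gi = 0
    SENTINEL = L + footprint + 1

    while True:
        # --- enumerate total rate ---------------------------------------
        total = 0.0
        if n > 0:
            front = pos[head]
        else:
            front = SENTINEL
        init_ok = front > footprint
        if init_ok:
            total += alpha
        for k in range(n):
            idx = head + k
            if idx >= cap:
                idx -= cap
            i = pos[idx]
            if i < L:
                if k + 1 < n:
                    idx2 = idx + 1
                    if idx2 >= cap:
                        idx2 -= cap
                    nxt = pos[idx2]
                else:
                    nxt = SENTINEL
                if nxt - i > footprint:
                    total += elong[i]
        at_term = False
        if n > 0:
            idxb = head + n - 1
            if idxb >= cap:
                idxb -= cap
            at_term = pos[idxb] == L
        if at_term:
            total += release_rate
            if init_ok:
                total += reinit_rate
        if total <= 0.0:
            break  # frozen: close at lifetime below
        # --- waiting time ------------------------------------------------
        dt = -np.log(np.random.random()) / total
        if t + dt > lifetime:
            t_evt = lifetime  # discard the event
        else:
            t_evt = t + dt
        while gi < ngrid and grid[gi] < t_evt:
            grid_counts[gi] += n
            gi += 1
        if t + dt > lifetime:
            occ += n * (lifetime - t)
            t = lifetime
            break
        occ += n * dt
        t = t_evt
        # --- channel selection (same order as the rate sum) ---------------
        u = np.random.random() * total
        action = -1  # 0 init, 1 elong, 2 release, 3 reinit
        rib = -1
        last_action = -1
        last_rib = -1
        acc = 0.0
        if init_ok and alpha > 0.0:
            acc += alpha
            last_action = 0
            if u < acc:
                action = 0
        if action < 0:
            for k in range(n):
                idx = head + k
                if idx >= cap:
                    idx -= cap
                i = pos[idx]
                if i < L:
                    if k + 1 < n:
                        idx2 = idx + 1
                        if idx2 >= cap:
                            idx2 -= cap
                        nxt = pos[idx2]
                    else:
                        nxt = SENTINEL
                    if nxt - i > footprint:
                        acc += elong[i]
                        last_action = 1
                        last_rib = idx
                        if u < acc:
                            action = 1
                            rib = idx
                            break
        if action < 0 and at_term:
            if release_rate > 0.0:
                acc += release_rate
                last_action = 2
                if u < acc:
                    action = 2
            if action < 0 and init_ok and reinit_rate > 0.0:
                acc += reinit_rate
                last_action = 3
                if u < acc:
                    action = 3
        if action < 0:  # floating-point fall-through: take the last channel
            action = last_action
            rib = last_rib
        # --- apply ---------------------------------------------------------
        if action == 0:
            head = head - 1 if head > 0 else cap - 1
            pos[head] = 1
            n += 1
            de_novo += 1
        elif action == 1:
            pos[rib] += 1
            if pos[rib] == L:
                completions += 1
                if first_arrival < 0.0:
                    first_arrival = t
                if stop_on_arrival:
                    break
        elif action == 2:
            n -= 1
            releases += 1
        elif action == 3:
            n -= 1
            head = head - 1 if head > 0 else cap - 1
            pos[head] = 1
            n += 1
            reinits += 1
    # close integral and flush grid at the lifetime
    if t < lifetime and np.isfinite(lifetime):
        occ += n * (lifetime - t)
        t = lifetime
    while gi < ngrid and grid[gi] <= lifetime:
        grid_counts[gi] += n
        gi += 1
    out = np.empty(7, dtype=np.float64)
    out[0] = occ
    out[1] = de_novo
    out[2] = reinits
    out[3] = releases
    out[4] = completions
    out[5] = first_arrival
    out[6] = n
    return out


@njit(cache=True)
def run_batch(
    L,
    elong,
    alpha,
    reinit_rate,
    release_rate,
    footprint,
    lifetime,
    seeds,
    grid,
    grid_acc,
    out,
):
    """Run independent replicates; fill ``out[k] = (mean_ribosomes, de_novo,
    reinits, releases, completions)`` and accumulate grid counts over runs
    into ``grid_acc``."""
    n_runs = seeds.shape[0]
    inv_T = 1.0 / lifetime if lifetime > 0 else 0.0
    for k in range(n_runs):
        gc = np.zeros(grid.shape[0], dtype=np.float64)
        res = run_transcript(
            L,
            elong,
            alpha,
            reinit_rate,
            release_rate,
            footprint,
            lifetime,
            seeds[k],
            0,
            False,
            grid,
            gc,
        )
        out[k, 0] = res[0] * inv_T
        out[k, 1] = res[1]
        out[k, 2] = res[2]
        out[k, 3] = res[3]
        out[k, 4] = res[4]
        for g in range(grid.shape[0]):
            grid_acc[g] += gc[g]
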