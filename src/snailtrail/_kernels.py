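"""Numba-accelerated CA kernel.

Bit-identical to the pure-Python reference engine in :mod:`snailtrail.ca`:
both consume a single MT19937 stream (numba's ``np.random`` implements the
same generator as ``numpy.random.RandomState``) with the same draws in the
same order, so a given (config, seed) yields identical trajectories under
either engine.  The Model 2 self-loop trail is represented here as an
EC-owner grid; in Model 2 an EC site has exactly one depositor for the
lifetime of the run (ECs are never removed and a TC can never subsequently
occupy an EC site), so owner-grid membership coincides with the per-agent
trail sets of the reference engine.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_realization_numba"]


@njit(cache=True)
def _kill(aid, pos_i, pos_j, alive, slot, tc, who, n_alive):
    tc[pos_i[aid], pos_j[aid]] = 0
    who[pos_i[aid], pos_j[aid]] = -1
    s = slot[aid]
    last = alive[n_alive - 1]
    n_alive -= 1
    if last != aid:
        alive[s] = last
        slot[last] = s
    return n_alive


@njit(cache=True)
def _run(R, h, P_m, P_p, a_n, a_e, mode, seed, record_K, pxp, pxm):
    np.random.seed(seed)
    size = R + 1
    tc = np.zeros((size, size), dtype=np.int8)
    ec = np.zeros((size, size), dtype=np.int64)
    owner = np.full((size, size), -1, dtype=np.int64)
    who = np.full((size, size), -1, dtype=np.int64)

    cap = 4 * size + 64
    pos_i = np.empty(cap, dtype=np.int64)
    pos_j = np.empty(cap, dtype=np.int64)
    alive = np.empty(cap, dtype=np.int64)
    slot = np.empty(cap, dtype=np.int64)
    n_alive = 0
    next_id = 0
    for j in range(1, R, 2):
        pos_i[next_id] = 0
        pos_j[next_id] = j
        alive[n_alive] = next_id
        slot[next_id] = n_alive
        tc[0, j] = 1
        who[0, j] = next_id
        n_alive += 1
        next_id += 1

    n_rec = record_K.shape[0]
    tc_out = np.zeros((n_rec, size, size), dtype=np.int8)
    ec_out = np.zeros((n_rec, size, size), dtype=np.int64)
    rec_ptr = 0
    while rec_ptr < n_rec and record_K[rec_ptr] == 0:
        tc_out[rec_ptr] = tc
        ec_out[rec_ptr] = ec
        rec_ptr += 1
    K_stop = 0
    if n_rec > 0:
        K_stop = record_K[n_rec - 1]

    for K in range(1, K_stop + 1):
        # --- motility phase ---
        n_bar = n_alive
        for _ in range(n_bar):
            if n_alive == 0:
                break
            idx = int(np.random.random() * n_alive)
            if idx == n_alive:
                idx = n_alive - 1
            aid = alive[idx]
            if np.random.random() >= P_m:
                continue
            i = pos_i[aid]
            j = pos_j[aid]
            u = np.random.random()
            pp = pxp[i]
            pm = pxm[i]
            if u < pp:
                ti, tj = i + 1, j
            elif u < pp + pm:
                ti, tj = i - 1, j
            elif u < pp + pm + 0.25:
                ti, tj = i, j + 1
            else:
                ti, tj = i, j - 1
            if ti < 0 or ti > R or tj < 0 or tj > R:
                continue  # boundary_aborted
            if tc[ti, tj] == 1:
                if np.random.random() < a_n:
                    # tip-to-tip anastomosis: both TCs become ECs
                    other = who[ti, tj]
                    n_alive = _kill(aid, pos_i, pos_j, alive, slot, tc, who, n_alive)
                    n_alive = _kill(other, pos_i, pos_j, alive, slot, tc, who, n_alive)
                    ec[i, j] += 1
                    owner[i, j] = aid
                    ec[ti, tj] += 1
                    owner[ti, tj] = other
                # else excluded_tc
                continue
            if mode == 2 and ec[ti, tj] > 0:
                if owner[ti, tj] == aid:
                    continue  # self-loop prohibited, no anastomosis draw
                if np.random.random() < a_e:
                    # tip-to-sprout anastomosis: TC removed, EC deposited at origin
                    n_alive = _kill(aid, pos_i, pos_j, alive, slot, tc, who, n_alive)
                    ec[i, j] += 1
                    owner[i, j] = aid
                # else excluded_ec
                continue
            # vacant target: snail-trail move
            tc[i, j] = 0
            who[i, j] = -1
            tc[ti, tj] = 1
            who[ti, tj] = aid
            pos_i[aid] = ti
            pos_j[aid] = tj
            ec[i, j] += 1
            owner[i, j] = aid

        # --- branching phase ---
        n_bar2 = n_alive
        for _ in range(n_bar2):
            if n_alive == 0:
                break
            idx = int(np.random.random() * n_alive)
            if idx == n_alive:
                idx = n_alive - 1
            aid = alive[idx]
            i = pos_i[aid]
            j = pos_j[aid]
            if np.random.random() >= P_p * (i * h):
                continue
            if j - 1 < 0 or j + 1 > R:
                continue  # one daughter site off-lattice: blocked
            if tc[i, j - 1] == 1 or tc[i, j + 1] == 1:
                continue
            if mode == 2 and (ec[i, j - 1] > 0 or ec[i, j + 1] > 0):
                continue
            n_alive = _kill(aid, pos_i, pos_j, alive, slot, tc, who, n_alive)
            if next_id + 2 > cap:
                new_cap = cap * 2
                npi = np.empty(new_cap, dtype=np.int64)
                npj = np.empty(new_cap, dtype=np.int64)
                nal = np.empty(new_cap, dtype=np.int64)
                nsl = np.empty(new_cap, dtype=np.int64)
                npi[:cap] = pos_i
                npj[:cap] = pos_j
                nal[:cap] = alive
                nsl[:cap] = slot
                pos_i, pos_j, alive, slot = npi, npj, nal, nsl
                cap = new_cap
            for tj in (j - 1, j + 1):
                pos_i[next_id] = i
                pos_j[next_id] = tj
                alive[n_alive] = next_id
                slot[next_id] = n_alive
                tc[i, tj] = 1
                who[i, tj] = next_id
                n_alive += 1
                next_id += 1

        if rec_ptr < n_rec and record_K[rec_ptr] == K:
            while rec_ptr < n_rec and record_K[rec_ptr] == K:
                tc_out[rec_ptr] = tc
                ec_out[rec_ptr] = ec
                rec_ptr += 1

    return tc_out, ec_out


def run_realization_numba(config, seed: int, record_K: np.ndarray):
    """Run one realization through the compiled kernel."""
    pxp, pxm = config.taf().gradient_stencil(config.k)
    return _run(config.R, config.h, config.P_m, config.P_p, config.a_n,
                config.a_e, config.mode, seed,
                np.asarray(record_K, dtype=np.int64),
                np.ascontiguousarray(pxp), np.ascontiguousarray(pxm))
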