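"""Numba-accelerated Monte-Carlo kernel.

One generation is ``N = L*L`` pair-event attempts; a failed reaction still
consumes an attempt.  Randomness comes from an inline xorshift64* stream
(numba's Mersenne Twister is several times slower in this loop) whose state
is derived from the run seed by splitmix64.  The draw order per attempt is
fixed: actor site (redrawn until occupied under ``occupied`` sampling),
neighbor direction, event type, and -- for applied intraspecific events --
the loser coin.

Run status codes returned by :func:`run_kernel`:

===== =======================================================
0     completed all ``T_max`` generations
1     absorbing composition reached (no label-changing event
      can ever fire again), including the single-label case
2     the requested ``stop_mode`` extinction condition was met
3     lattice entirely empty
===== =======================================================
"""

from __future__ import annotations

import numpy as np
from numba import njit

# stop_mode values
STOP_NONE = 0
STOP_GENUS = 1  # every species has lost at least one genus
STOP_TWO_SPECIES = 2  # at least two species fully extinct

STATUS_COMPLETED = 0
STATUS_ABSORBED = 1
STATUS_STOP_CONDITION = 2
STATUS_ALL_DEAD = 3

_U64 = np.uint64
_MASK = _U64(0xFFFFFFFFFFFFFFFF)
_STAR = _U64(2685821657736338717)  # xorshift64* output multiplier
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(inline="always")
def _next(s):
    """Advance the xorshift64* state; return (state, scrambled output)."""
    s ^= s >> _U64(12)
    s = (s ^ (s << _U64(25))) & _MASK
    s ^= s >> _U64(27)
    return s, (s * _STAR) & _MASK


@njit(inline="always")
def _randint(s, n):
    """Uniform integer in [0, n) via the high-bits multiply trick."""
    s, x = _next(s)
    return s, int(((x >> _U64(32)) * _U64(n)) >> _U64(32))


@njit(inline="always")
def _uniform(s):
    s, x = _next(s)
    return s, float(x >> _U64(11)) * _INV53


@njit(cache=True)
def _seed_state(seed):
    """splitmix64 mixing so that nearby integer seeds decorrelate."""
    z = (_U64(seed) + _U64(0x9E3779B97F4A7C15)) & _MASK
    for _ in range(2):
        z = ((z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)) & _MASK
        z = ((z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)) & _MASK
        z ^= z >> _U64(31)
    if z == _U64(0):
        z = _U64(0x9E3779B97F4A7C15)
    return z


@njit(cache=True)
def _absorbing(counts, k_by_species, traditional):
    """True when no interspecific or intraspecific event can ever fire again."""
    n_alive = 0
    alive_s = -1
    for s in range(3):
        if counts[2 * s] + counts[2 * s + 1] > 0:
            n_alive += 1
            alive_s = s
    if n_alive == 0:
        return True
    if n_alive > 1:
        return False
    # exactly one species left: only intraspecific events could still matter
    if k_by_species[alive_s] == 0.0:
        return True
    if traditional:
        # same-genus pairs fight too; composition can still change while
        # more than one individual remains
        return counts[2 * alive_s] + counts[2 * alive_s + 1] <= 1
    return not (counts[2 * alive_s] > 0 and counts[2 * alive_s + 1] > 0)


@njit(cache=True)
def _stop_condition(counts, stop_mode):
    if stop_mode == STOP_GENUS:
        for s in range(3):
            if counts[2 * s] > 0 and counts[2 * s + 1] > 0:
                return False
        return True
    if stop_mode == STOP_TWO_SPECIES:
        dead = 0
        for s in range(3):
            if counts[2 * s] + counts[2 * s + 1] == 0:
                dead += 1
        return dead >= 2
    return False


def neighbor_table(L: int) -> np.ndarray:
    """Flat ``(4*N,)`` table: entry ``4*a + d`` is site a's neighbor in
    direction d (up, down, left, right) under periodic wrap."""
    N = L * L
    rows, cols = np.divmod(np.arange(N), L)
    nbr = np.empty(4 * N, dtype=np.int32)
    nbr[0::4] = ((rows - 1) % L) * L + cols
    nbr[1::4] = ((rows + 1) % L) * L + cols
    nbr[2::4] = rows * L + (cols - 1) % L
    nbr[3::4] = rows * L + (cols + 1) % L
    return nbr


@njit(cache=True)
def run_kernel(
    grid,            # int8[N] flattened lattice, modified in place
    L,               # lattice side
    nbr,             # int32[4*N] neighbor table from neighbor_table(L)
    cum_probs,       # float64[3, 3] cumulative event thresholds per species
    k_by_species,    # float64[3]
    traditional,     # bool: intraspecific ignores the genus condition
    any_site_actor,  # bool: actor drawn over all sites, empty = wasted attempt
    T_max,           # generations to run
    record_every,    # density recording stride
    stop_mode,       # STOP_NONE / STOP_GENUS / STOP_TWO_SPECIES
    seed,            # RNG seed
    snap_gens,       # int64[:] sorted generations at which to copy the grid
):
    """Run up to ``T_max`` generations; return trajectory and bookkeeping.

    Returns ``(records, snaps, n_snaps, attempted, applied, status, gen)``
    where ``records`` rows are ``(generation, count_A1..count_C2, count_E)``.
    """
    N = L * L
    prey = np.array([1, 2, 0], dtype=np.int64)  # A beats B beats C beats A
    s = _seed_state(seed)

    counts = np.zeros(7, dtype=np.int64)
    for i in range(N):
        counts[grid[i]] += 1

    max_records = T_max // record_every + 3
    records = np.zeros((max_records, 8), dtype=np.int64)
    n_rec = 0
    records[n_rec, 0] = 0
    records[n_rec, 1:] = counts
    n_rec += 1
    last_recorded = 0

    n_snap_slots = snap_gens.shape[0]
    snaps = np.zeros((max(n_snap_slots, 1), N), dtype=np.int8)
    n_snaps = 0
    snap_ptr = 0
    while snap_ptr < n_snap_slots and snap_gens[snap_ptr] <= 0:
        if snap_gens[snap_ptr] == 0:
            snaps[n_snaps] = grid
            n_snaps += 1
        snap_ptr += 1

    attempted = np.zeros(5, dtype=np.int64)  # inter, intra, repro, migr, wasted
    applied = np.zeros(4, dtype=np.int64)

    status = STATUS_COMPLETED
    gen = 0

    if counts[6] == N:
        status = STATUS_ALL_DEAD
    elif _stop_condition(counts, stop_mode):
        status = STATUS_STOP_CONDITION
    elif _absorbing(counts, k_by_species, traditional):
        status = STATUS_ABSORBED

    while gen < T_max and status == STATUS_COMPLETED:
        gen += 1
        all_dead = False
        for _ in range(N):
            if any_site_actor:
                s, a = _randint(s, N)
                ga = grid[a]
                if ga == 6:
                    attempted[4] += 1
                    continue
            else:
                while True:
                    s, a = _randint(s, N)
                    ga = grid[a]
                    if ga != 6:
                        break
            s, d = _randint(s, 4)
            b = nbr[(a << 2) + d]
            gb = grid[b]
            sa = ga >> 1
            s, u = _uniform(s)
            if u < cum_probs[sa, 0]:
                attempted[0] += 1
                if gb != 6 and (gb >> 1) == prey[sa]:
                    grid[b] = 6
                    counts[gb] -= 1
                    counts[6] += 1
                    applied[0] += 1
            elif u < cum_probs[sa, 1]:
                attempted[1] += 1
                if gb != 6 and (gb >> 1) == sa and (traditional or (gb & 1) != (ga & 1)):
                    s, x = _next(s)
                    if (x >> _U64(32)) & _U64(1):
                        grid[a] = 6
                        counts[ga] -= 1
                    else:
                        grid[b] = 6
                        counts[gb] -= 1
                    counts[6] += 1
                    applied[1] += 1
                    if counts[6] == N:
                        all_dead = True
                        break
            elif u < cum_probs[sa, 2]:
                attempted[2] += 1
                if gb == 6:
                    grid[b] = ga
                    counts[6] -= 1
                    counts[ga] += 1
                    applied[2] += 1
            else:
                attempted[3] += 1
                applied[3] += 1
                grid[a] = gb
                grid[b] = ga

        if gen % record_every == 0:
            records[n_rec, 0] = gen
            records[n_rec, 1:] = counts
            n_rec += 1
            last_recorded = gen

        while snap_ptr < n_snap_slots and snap_gens[snap_ptr] <= gen:
            if snap_gens[snap_ptr] == gen:
                snaps[n_snaps] = grid
                n_snaps += 1
            snap_ptr += 1

        if all_dead:
            status = STATUS_ALL_DEAD
        elif _stop_condition(counts, stop_mode):
            status = STATUS_STOP_CONDITION
        elif _absorbing(counts, k_by_species, traditional):
            status = STATUS_ABSORBED

    if last_recorded != gen:
        records[n_rec, 0] = gen
        records[n_rec, 1:] = counts
        n_rec += 1

    return records[:n_rec], snaps, n_snaps, attempted, applied, status, gen


def cumulative_probs(config) -> np.ndarray:
    """Per-species cumulative event thresholds (inter, +intra, +repro).

    The migration probability is the remainder to 1, so only three
    thresholds are stored per species.
    """
    from .model_core import event_probabilities

    out = np.empty((3, 3), dtype=np.float64)
    for s, k in enumerate((config.k_A, config.k_B, config.k_C)):
        p = event_probabilities(config, k)
        out[s, 0] = p.p_inter
        out[s, 1] = p.p_inter + p.p_intra
        out[s, 2] = p.p_inter + p.p_intra + p.p_repro
    return out
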