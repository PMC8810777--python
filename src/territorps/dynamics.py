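"""Monte-Carlo dynamics: pair events, the generation loop and full runs.

Two engines share the same rules:

* a plain-Python reference (:func:`attempt_pair_event`, :func:`step_generation`)
  used for unit and property tests, and
* the numba kernel (:mod:`territorps._kernel`) used by :func:`run_simulation`
  for anything longer than a handful of generations.

Both draw from a single seeded generator per run in a fixed order (actor,
neighbor direction, event type, intraspecific loser coin), so every run is
replayable from its config and seed.  The two engines use different RNG
back-ends and are not draw-for-draw identical to each other; each is
individually deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernel
from .model_core import (
    EMPTY,
    EventProbabilities,
    LatticeState,
    SimulationConfig,
    event_probabilities,
    init_lattice,
    validate_config,
)

__all__ = [
    "EventOutcome",
    "DensityTrajectory",
    "RunTrajectory",
    "attempt_pair_event",
    "step_generation",
    "run_simulation",
]

EVENT_TYPES = ("interspecific", "intraspecific", "reproduction", "migration")
_PREY = (1, 2, 0)  # A beats B, B beats C, C beats A


@dataclass(frozen=True)
class EventOutcome:
    """Result of one pair-event attempt."""

    event_type: str  # one of EVENT_TYPES or "none"
    applied: bool
    sites_changed: tuple = ()


@dataclass
class DensityTrajectory:
    """Per-generation label counts.

    ``generations`` is strictly increasing; ``counts`` has one row per
    recorded generation and seven columns in :class:`SiteState` code order.
    """

    generations: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.generations.shape[0], 7):
            raise ValueError("counts must have shape (len(generations), 7)")
        if self.generations.size and np.any(np.diff(self.generations) <= 0):
            raise ValueError("generations must be strictly increasing")

    def to_dataframe(self):
        import pandas as pd
        from .model_core import LABEL_NAMES

        df = pd.DataFrame(self.counts, columns=[f"count_{n}" for n in LABEL_NAMES])
        df.insert(0, "generation", self.generations)
        return df


@dataclass
class RunTrajectory:
    """Everything a single run produced."""

    config: SimulationConfig
    densities: DensityTrajectory
    final_state: LatticeState
    event_counts: dict
    status: str  # completed | absorbed | stop_condition | all_dead
    snapshots: list = field(default_factory=list)  # (generation, LatticeState)


def _neighbors(L: int, r: int, c: int):
    return ((r - 1) % L, c), ((r + 1) % L, c), (r, (c - 1) % L), (r, (c + 1) % L)


def attempt_pair_event(
    state: LatticeState,
    actor: tuple,
    neighbor: tuple,
    probs: EventProbabilities,
    rng: np.random.Generator,
    traditional: bool = False,
) -> EventOutcome:
    """Draw one event type and apply it iff the pair matches the rule.

    ``actor`` and ``neighbor`` are 0-based ``(row, col)`` coordinates and must
    be von-Neumann adjacent under periodic wrap; the actor site must be
    occupied.  A drawn event whose precondition fails leaves the grid
    untouched (``applied=False``) -- the attempt is still consumed.
    With ``traditional=True`` the intraspecific rule drops its
    different-genus condition.
    """
    return _attempt(state, actor, neighbor, probs, rng, traditional=traditional)


def _attempt(state, actor, neighbor, probs, rng, traditional):
    grid = state.grid
    L = state.L
    ga = int(grid[actor])
    if ga == EMPTY:
        raise ValueError("actor site is empty")
    if neighbor not in _neighbors(L, *actor):
        raise ValueError(f"sites {actor} and {neighbor} are not adjacent")
    gb = int(grid[neighbor])
    sa = ga >> 1

    u = rng.random()
    cum = np.cumsum(probs.as_array())
    if u < cum[0]:
        if gb != EMPTY and (gb >> 1) == _PREY[sa]:
            grid[neighbor] = EMPTY
            return EventOutcome("interspecific", True, (neighbor,))
        return EventOutcome("interspecific", False)
    if u < cum[1]:
        same_species = gb != EMPTY and (gb >> 1) == sa
        genus_ok = traditional or (gb != EMPTY and (gb & 1) != (ga & 1))
        if same_species and genus_ok:
            victim = actor if rng.random() < 0.5 else neighbor
            grid[victim] = EMPTY
            return EventOutcome("intraspecific", True, (victim,))
        return EventOutcome("intraspecific", False)
    if u < cum[2]:
        if gb == EMPTY:
            grid[neighbor] = np.int8(ga)
            return EventOutcome("reproduction", True, (neighbor,))
        return EventOutcome("reproduction", False)
    grid[actor], grid[neighbor] = np.int8(gb), np.int8(ga)
    return EventOutcome("migration", True, (actor, neighbor))


def step_generation(
    state: LatticeState,
    config: SimulationConfig,
    rng: np.random.Generator,
    event_counts: Optional[dict] = None,
) -> LatticeState:
    """Perform exactly ``N`` pair-event attempts and bump the generation.

    Failed attempts count toward the N.  Under ``occupied`` actor sampling
    the actor is uniform over currently occupied sites (rejection sampling);
    under ``any_site`` an empty actor wastes the attempt.  Raises
    ``RuntimeError`` if the lattice is entirely empty.
    """
    L = config.L
    N = config.N
    grid = state.grid
    traditional = config.intraspecific_mode == "traditional"
    probs_by_species = [
        event_probabilities(config, k) for k in (config.k_A, config.k_B, config.k_C)
    ]
    if int(np.sum(grid != EMPTY)) == 0:
        raise RuntimeError("all-dead: lattice is entirely empty")
    for _ in range(N):
        if config.actor_sampling == "any_site":
            a = int(rng.integers(N))
            if grid.flat[a] == EMPTY:
                if event_counts is not None:
                    event_counts["wasted"] = event_counts.get("wasted", 0) + 1
                continue
        else:
            while True:
                a = int(rng.integers(N))
                if grid.flat[a] != EMPTY:
                    break
        actor = (a // L, a % L)
        neighbor = _neighbors(L, *actor)[int(rng.integers(4))]
        sa = int(grid[actor]) >> 1
        out = _attempt(state, actor, neighbor, probs_by_species[sa], rng, traditional)
        if event_counts is not None:
            key = out.event_type + ("" if out.applied else "_failed")
            event_counts[key] = event_counts.get(key, 0) + 1
        if (
            out.applied
            and out.event_type in ("interspecific", "intraspecific")
            and not np.any(grid != EMPTY)
        ):
            break
    state.generation += 1
    return state


_STATUS_NAMES = {
    _kernel.STATUS_COMPLETED: "completed",
    _kernel.STATUS_ABSORBED: "absorbed",
    _kernel.STATUS_STOP_CONDITION: "stop_condition",
    _kernel.STATUS_ALL_DEAD: "all_dead",
}

_STOP_MODES = {
    "none": _kernel.STOP_NONE,
    "genus_extinct": _kernel.STOP_GENUS,
    "two_species_extinct": _kernel.STOP_TWO_SPECIES,
}


def run_simulation(
    config: SimulationConfig,
    snapshots_at: tuple = (),
    stop_mode: str = "none",
    engine: str = "numba",
    initial_state: Optional[LatticeState] = None,
) -> RunTrajectory:
    """Initialize and run a full simulation, fully determined by the seed.

    A run halts early when the label composition becomes absorbing (no
    interspecific or intraspecific event can ever fire again -- in
    particular when at most one label is left), when the lattice dies out,
    or when the optional ``stop_mode`` extinction condition
    (``genus_extinct`` / ``two_species_extinct``) is first met.  Densities
    are recorded every ``record_every`` generations, always including
    generation 0 and the final generation.
    """
    validate_config(config)
    if stop_mode not in _STOP_MODES:
        raise ValueError(f"unknown stop_mode {stop_mode!r}")
    rng = np.random.default_rng(config.seed)
    if initial_state is None:
        state = init_lattice(config, rng)
    else:
        state = initial_state.copy()

    if engine == "numba":
        return _run_numba(config, state, snapshots_at, stop_mode)
    if engine == "python":
        return _run_python(config, state, snapshots_at, stop_mode, rng)
    raise ValueError(f"unknown engine {engine!r}")


def _run_numba(config, state, snapshots_at, stop_mode):
    snap_gens = np.array(sorted(g for g in snapshots_at if g >= 0), dtype=np.int64)
    kernel_seed = int(
        np.random.SeedSequence(config.seed).generate_state(1, np.uint32)[0]
    )
    grid = state.grid.ravel().copy()
    records, snaps, n_snaps, attempted, applied, status, gen = _kernel.run_kernel(
        grid,
        config.L,
        _kernel.neighbor_table(config.L),
        _kernel.cumulative_probs(config),
        np.array([config.k_A, config.k_B, config.k_C], dtype=np.float64),
        config.intraspecific_mode == "traditional",
        config.actor_sampling == "any_site",
        config.T_max,
        config.record_every,
        _STOP_MODES[stop_mode],
        kernel_seed,
        snap_gens,
    )
    densities = DensityTrajectory(records[:, 0].copy(), records[:, 1:].copy())
    final = LatticeState(grid.reshape(config.L, config.L), generation=gen)
    event_counts = {name: int(applied[i]) for i, name in enumerate(EVENT_TYPES)}
    event_counts.update(
        {f"{name}_failed": int(attempted[i] - applied[i])
         for i, name in enumerate(EVENT_TYPES)}
    )
    event_counts["wasted"] = int(attempted[4])
    snapshots = [
        (int(snap_gens[i]), LatticeState(snaps[i].reshape(config.L, config.L),
                                         generation=int(snap_gens[i])))
        for i in range(n_snaps)
    ]
    return RunTrajectory(
        config=config,
        densities=densities,
        final_state=final,
        event_counts=event_counts,
        status=_STATUS_NAMES[status],
        snapshots=snapshots,
    )


def _counts_of(grid):
    return np.bincount(grid.ravel(), minlength=7).astype(np.int64)


def _python_absorbing(counts, config):
    ks = (config.k_A, config.k_B, config.k_C)
    alive = [s for s in range(3) if counts[2 * s] + counts[2 * s + 1] > 0]
    if len(alive) == 0:
        return True
    if len(alive) > 1:
        return False
    s = alive[0]
    if ks[s] == 0:
        return True
    if config.intraspecific_mode == "traditional":
        return counts[2 * s] + counts[2 * s + 1] <= 1
    return not (counts[2 * s] > 0 and counts[2 * s + 1] > 0)


def _python_stop(counts, stop_mode):
    if stop_mode == "genus_extinct":
        return all(min(counts[2 * s], counts[2 * s + 1]) == 0 for s in range(3))
    if stop_mode == "two_species_extinct":
        return sum(counts[2 * s] + counts[2 * s + 1] == 0 for s in range(3)) >= 2
    return False


def _run_python(config, state, snapshots_at, stop_mode, rng):
    snapshots_at = set(snapshots_at)
    gens = [0]
    counts_rows = [_counts_of(state.grid)]
    snapshots = []
    if 0 in snapshots_at:
        snapshots.append((0, state.copy()))
    event_counts: dict = {}
    status = "completed"
    counts = counts_rows[0]
    if counts[EMPTY] == config.N:
        status = "all_dead"
    elif _python_stop(counts, stop_mode):
        status = "stop_condition"
    elif _python_absorbing(counts, config):
        status = "absorbed"
    gen = 0
    while gen < config.T_max and status == "completed":
        step_generation(state, config, rng, event_counts)
        gen = state.generation
        counts = _counts_of(state.grid)
        if gen % config.record_every == 0:
            gens.append(gen)
            counts_rows.append(counts)
        if gen in snapshots_at:
            snapshots.append((gen, state.copy()))
        if counts[EMPTY] == config.N:
            status = "all_dead"
        elif _python_stop(counts, stop_mode):
            status = "stop_condition"
        elif _python_absorbing(counts, config):
            status = "absorbed"
    if gens[-1] != gen:
        gens.append(gen)
        counts_rows.append(counts)
    for name in EVENT_TYPES:
        event_counts.setdefault(name, 0)
    return RunTrajectory(
        config=config,
        densities=DensityTrajectory(np.array(gens), np.array(counts_rows)),
        final_state=state,
        event_counts=event_counts,
        status=status,
        snapshots=snapshots,
    )
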