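"""Domain types, parameter validation, lattice construction and the RNG contract.

The lattice is an ``L x L`` square grid with periodic boundaries and von
Neumann (4-site) neighborhoods.  Each site holds one of seven states: six
individual labels ``A1, A2, B1, B2, C1, C2`` or ``E`` (empty).  The letter is
the species, the digit is the *genus* -- a heritable territory-of-origin tag.
Rows are numbered ``1..L`` top to bottom; territory 1 is the top half
(rows ``1..L/2``) and territory 2 the bottom half.

Internally grids are ``numpy.int8`` arrays with the integer coding of
:class:`SiteState` (``A1=0 .. C2=5, E=6``); species of a code is ``code >> 1``
and genus is ``(code & 1) + 1``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "SiteState",
    "SimulationConfig",
    "LatticeState",
    "EventProbabilities",
    "ConfigError",
    "validate_config",
    "init_lattice",
    "event_probabilities",
    "EMPTY",
    "N_LABELS",
    "GENUS1_CODES",
    "GENUS2_CODES",
    "LABEL_NAMES",
]


class SiteState(enum.IntEnum):
    """The seven admissible site states; ``E`` is an empty site."""

    A1 = 0
    A2 = 1
    B1 = 2
    B2 = 3
    C1 = 4
    C2 = 5
    E = 6


N_LABELS = 7
EMPTY = int(SiteState.E)
GENUS1_CODES = (0, 2, 4)
GENUS2_CODES = (1, 3, 5)
LABEL_NAMES = ("A1", "A2", "B1", "B2", "C1", "C2", "E")
SPECIES_NAMES = ("A", "B", "C")


def species_of(code: int) -> int:
    """Species index (0=A, 1=B, 2=C) of a non-empty site code."""
    if code == EMPTY:
        raise ValueError("empty site has no species")
    return code >> 1


def genus_of(code: int) -> int:
    """Genus (1 or 2) of a non-empty site code."""
    if code == EMPTY:
        raise ValueError("empty site has no genus")
    return (code & 1) + 1


class ConfigError(ValueError):
    """Raised when a :class:`SimulationConfig` is invalid; names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of a single run.

    The microscopic exchange rate ``m = 2*M*N`` is derived from the mobility
    ``M`` and the system size ``N = L*L``; it is never set independently.
    Default rates mirror the common convention ``p1 = p2 = r = 1`` with a
    single shared sensitivity ``k`` for all species.
    """

    L: int = 300
    M: float = 1e-5
    k_A: float = 0.0
    k_B: float = 0.0
    k_C: float = 0.0
    p1: float = 1.0
    p2: float = 1.0
    r: float = 1.0
    T_max: int = 1000
    seed: int = 0
    intraspecific_mode: str = "territorial"  # or "traditional"
    record_every: int = 1
    empty_fraction: float = 0.25
    actor_sampling: str = "occupied"  # or "any_site"

    @property
    def N(self) -> int:
        return self.L * self.L

    @property
    def m(self) -> float:
        """Microscopic exchange rate, m = 2*M*N."""
        return 2.0 * self.M * self.N

    def with_k(self, k: float) -> "SimulationConfig":
        """Copy of this config with a common sensitivity k for all species."""
        return replace(self, k_A=k, k_B=k, k_C=k)

    @property
    def k(self) -> float:
        """The common sensitivity, defined only when k_A == k_B == k_C."""
        if not (self.k_A == self.k_B == self.k_C):
            raise ValueError("k is undefined for asymmetric sensitivities")
        return self.k_A


@dataclass(frozen=True)
class EventProbabilities:
    """Normalized pair-event probabilities for a given actor sensitivity."""

    p_inter: float
    p_intra: float
    p_repro: float
    p_migr: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_inter, self.p_intra, self.p_repro, self.p_migr])


@dataclass
class LatticeState:
    """An ``L x L`` grid of site codes plus the generation counter."""

    grid: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("grid must be a square 2-D array")
        if self.grid.min() < 0 or self.grid.max() > EMPTY:
            raise ValueError("grid contains invalid site codes")

    @property
    def L(self) -> int:
        return self.grid.shape[0]

    def counts(self) -> np.ndarray:
        """Length-7 array of label counts in :class:`SiteState` code order."""
        return np.bincount(self.grid.ravel(), minlength=N_LABELS).astype(np.int64)

    def copy(self) -> "LatticeState":
        return LatticeState(self.grid.copy(), self.generation)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LatticeState):
            return NotImplemented
        return self.generation == other.generation and np.array_equal(
            self.grid, other.grid
        )


def validate_config(config: SimulationConfig) -> SimulationConfig:
    """Check a config and return it unchanged if valid.

    Raises :class:`ConfigError` naming the offending field otherwise.
    """
    if config.L < 4:
        raise ConfigError(f"L must be >= 4, got {config.L}")
    if config.L % 2 != 0:
        raise ConfigError(f"L must be even, got {config.L}")
    if config.M <= 0:
        raise ConfigError(f"M must be positive, got {config.M}")
    for name in ("k_A", "k_B", "k_C"):
        if getattr(config, name) < 0:
            raise ConfigError(f"{name} must be non-negative, got {getattr(config, name)}")
    if config.p1 <= 0:
        raise ConfigError(f"p1 must be positive, got {config.p1}")
    if config.p2 < 0:
        raise ConfigError(f"p2 must be non-negative, got {config.p2}")
    if config.r <= 0:
        raise ConfigError(f"r must be positive, got {config.r}")
    if config.T_max <= 0:
        raise ConfigError(f"T_max must be positive, got {config.T_max}")
    if config.record_every <= 0:
        raise ConfigError(f"record_every must be positive, got {config.record_every}")
    if not (0.0 <= config.empty_fraction < 1.0):
        raise ConfigError(
            f"empty_fraction must be in [0, 1), got {config.empty_fraction}"
        )
    if config.intraspecific_mode not in ("territorial", "traditional"):
        raise ConfigError(
            f"intraspecific_mode must be 'territorial' or 'traditional', "
            f"got {config.intraspecific_mode!r}"
        )
    if config.actor_sampling not in ("occupied", "any_site"):
        raise ConfigError(
            f"actor_sampling must be 'occupied' or 'any_site', "
            f"got {config.actor_sampling!r}"
        )
    return config


def init_lattice(config: SimulationConfig, rng: np.random.Generator) -> LatticeState:
    """Random initial lattice with each territory seeded by its own genus.

    Each site in the top half is drawn independently from
    ``{A1, B1, C1, E}`` and each site in the bottom half from
    ``{A2, B2, C2, E}``, with the empty state taking probability
    ``empty_fraction`` and the three species sharing the rest equally
    (the default 1/4 each).
    """
    validate_config(config)
    L = config.L
    e = config.empty_fraction
    p = np.array([(1 - e) / 3] * 3 + [e])
    half = L // 2
    top_labels = np.array([SiteState.A1, SiteState.B1, SiteState.C1, SiteState.E],
                          dtype=np.int8)
    bot_labels = np.array([SiteState.A2, SiteState.B2, SiteState.C2, SiteState.E],
                          dtype=np.int8)
    grid = np.empty((L, L), dtype=np.int8)
    # top half first, then bottom: part of the documented draw order
    grid[:half] = top_labels[rng.choice(4, size=(half, L), p=p)]
    grid[half:] = bot_labels[rng.choice(4, size=(L - half, L), p=p)]
    return LatticeState(grid, generation=0)


def event_probabilities(config: SimulationConfig, k: float) -> EventProbabilities:
    """The four normalized pair-event probabilities for actor sensitivity ``k``.

    The common denominator is ``p1 + k*p2 + r + m``; the numerators are
    ``p1`` (interspecific), ``k*p2`` (intraspecific), ``r`` (reproduction)
    and ``m`` (migration).
    """
    if k < 0:
        raise ConfigError(f"k must be non-negative, got {k}")
    den = config.p1 + k * config.p2 + config.r + config.m
    if den <= 0:
        raise ConfigError("event-probability denominator p1 + k*p2 + r + m is zero")
    return EventProbabilities(
        p_inter=config.p1 / den,
        p_intra=k * config.p2 / den,
        p_repro=config.r / den,
        p_migr=config.m / den,
    )
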