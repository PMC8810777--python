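"""Survival-state classification, extinction times and the interface width.

Row/column coordinates in this module are 1-based, rows counted top to
bottom, matching the lattice convention (territory 1 = rows ``1..L/2``,
territory 2 = rows ``L/2+1..L``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dynamics import DensityTrajectory
from .model_core import (
    GENUS1_CODES,
    GENUS2_CODES,
    LABEL_NAMES,
    LatticeState,
    SPECIES_NAMES,
)

__all__ = [
    "SurvivalSummary",
    "ExtinctionRecord",
    "InterfaceWidthResult",
    "summarize",
    "extinction_time",
    "column_penetration",
    "interface_width",
    "interface_width_oracle",
    "default_window",
]


@dataclass(frozen=True)
class SurvivalSummary:
    """Label counts plus a coarse survival-state classification.

    ``state_label`` is one of ``full_coexistence`` (all six labels alive),
    ``reduced_coexistence`` (all three species alive, exactly one genus
    each), ``two_species_extinct`` (one species alive with both genera),
    ``uniform`` (a single label alive), ``all_dead``, or ``other`` for the
    remaining transient compositions.
    """

    counts: dict
    species_alive: frozenset
    genera_alive: frozenset
    state_label: str


@dataclass(frozen=True)
class ExtinctionRecord:
    """An extinction time under one of the two definitions.

    ``status`` is ``observed`` (the first-crossing generation), ``censored``
    (event not reached; ``time`` is the censoring value, entering averages
    as-is), or ``undetermined`` (trajectory too short and no censoring
    value given; ``time`` is None).
    """

    definition: str  # low_mobility | high_mobility
    time: Optional[int]
    status: str  # observed | censored | undetermined
    censored_at: Optional[int] = None


@dataclass
class InterfaceWidthResult:
    """Per-column penetration bounds and the mean interface width.

    ``P1[j-1]``/``P2[j-1]`` are the per-column penetration rows (NaN when no
    individual of that territory class lies in the window), ``I`` the
    per-column non-negative widths and ``W`` their mean over all L columns.
    """

    P1: np.ndarray
    P2: np.ndarray
    I: np.ndarray
    W: float
    window: tuple


def summarize(state: LatticeState) -> SurvivalSummary:
    """Exact label counts and the derived survival-state label."""
    c = state.counts()
    counts = {LABEL_NAMES[i]: int(c[i]) for i in range(7)}
    genera = frozenset(
        LABEL_NAMES[i] for i in range(6) if c[i] > 0
    )
    species = frozenset(
        SPECIES_NAMES[s] for s in range(3) if c[2 * s] + c[2 * s + 1] > 0
    )
    n_species = len(species)
    n_genera = len(genera)
    if n_species == 0:
        label = "all_dead"
    elif n_genera == 1:
        label = "uniform"
    elif n_species == 1:
        label = "two_species_extinct"
    elif n_species == 3 and n_genera == 6:
        label = "full_coexistence"
    elif n_species == 3 and n_genera == 3:
        label = "reduced_coexistence"
    else:
        label = "other"
    return SurvivalSummary(counts, species, genera, label)


def _low_mobility_hit(counts: np.ndarray) -> np.ndarray:
    """Boolean per row: every species has at least one genus extinct."""
    return (
        (np.minimum(counts[:, 0], counts[:, 1]) == 0)
        & (np.minimum(counts[:, 2], counts[:, 3]) == 0)
        & (np.minimum(counts[:, 4], counts[:, 5]) == 0)
    )


def _high_mobility_hit(counts: np.ndarray) -> np.ndarray:
    """Boolean per row: at least two species fully extinct."""
    dead = sum(
        (counts[:, 2 * s] + counts[:, 2 * s + 1] == 0).astype(int) for s in range(3)
    )
    return dead >= 2


def extinction_time(
    trajectory: DensityTrajectory,
    definition: str,
    censor_at: Optional[int] = None,
) -> ExtinctionRecord:
    """First-crossing extinction time under one of the two definitions.

    ``low_mobility``: first generation at which every species has lost at
    least one genus.  ``high_mobility``: first generation at which at least
    two species are completely extinct.  If the event is not reached, the
    record is censored at ``censor_at`` when given, else marked
    undetermined.
    """
    if definition == "low_mobility":
        hit = _low_mobility_hit(trajectory.counts)
    elif definition == "high_mobility":
        hit = _high_mobility_hit(trajectory.counts)
    else:
        raise ValueError(f"unknown definition {definition!r}")
    idx = np.flatnonzero(hit)
    if idx.size:
        t = int(trajectory.generations[idx[0]])
        return ExtinctionRecord(definition, t, "observed", censor_at)
    if censor_at is not None:
        return ExtinctionRecord(definition, int(censor_at), "censored", censor_at)
    return ExtinctionRecord(definition, None, "undetermined", None)


def default_window(L: int) -> tuple:
    """Central third of rows, split evenly about the interface.

    Returns the 1-based inclusive row interval ``(lo, hi)``; for ``L=300``
    this is rows 101..200 (100 rows straddling the row-150/151 boundary).
    """
    width = L // 3
    half = width // 2
    lo = L // 2 - half + 1
    hi = L // 2 + (width - half)
    return lo, hi


def _check_window(L: int, window: tuple) -> tuple:
    lo, hi = int(window[0]), int(window[1])
    if not (1 <= lo <= hi <= L):
        raise ValueError(f"window {window} outside rows 1..{L}")
    return lo, hi


def column_penetration(
    state: LatticeState,
    j: int,
    territory: int,
    window: Optional[tuple] = None,
) -> Optional[int]:
    """Penetration row of a territory class in 1-based column ``j``.

    For territory 1 the individuals scanned are all genus-1 sites
    (``A1, B1, C1`` pooled) in the column within the window; the result is
    the deepest row among invaders of territory 2 when any exist, otherwise
    the row nearest the interface within territory 1 -- which is simply the
    maximum row index.  Territory 2 is the mirror image (minimum row).
    Returns ``None`` when the class is absent from the column's window.
    """
    L = state.L
    if not (1 <= j <= L):
        raise ValueError(f"column {j} outside 1..{L}")
    if territory not in (1, 2):
        raise ValueError("territory must be 1 or 2")
    lo, hi = _check_window(L, window if window is not None else default_window(L))
    col = state.grid[lo - 1 : hi, j - 1]
    codes = GENUS1_CODES if territory == 1 else GENUS2_CODES
    mask = np.isin(col, codes)
    if not mask.any():
        return None
    rows = np.flatnonzero(mask) + lo
    return int(rows.max() if territory == 1 else rows.min())


def interface_width(
    state: LatticeState, window: Optional[tuple] = None
) -> InterfaceWidthResult:
    """Mean interpenetration depth of the two territory classes.

    Per column ``j``, ``I_j = P1_j - P2_j`` when ``P1_j > P2_j`` and 0
    otherwise; columns where either class is absent from the window
    contribute 0.  ``W`` is the mean of ``I_j`` over all L columns.
    """
    L = state.L
    lo, hi = _check_window(L, window if window is not None else default_window(L))
    sub = state.grid[lo - 1 : hi, :]
    rows = np.arange(lo, hi + 1, dtype=np.int64)[:, None]
    g1 = np.isin(sub, GENUS1_CODES)
    g2 = np.isin(sub, GENUS2_CODES)
    p1 = np.where(g1, rows, np.iinfo(np.int64).min).max(axis=0).astype(float)
    p2 = np.where(g2, rows, np.iinfo(np.int64).max).min(axis=0).astype(float)
    p1[~g1.any(axis=0)] = np.nan
    p2[~g2.any(axis=0)] = np.nan
    I = p1 - p2
    I[~(I > 0)] = 0.0  # includes NaN -> 0
    W = float(I.sum() / L)
    return InterfaceWidthResult(P1=p1, P2=p2, I=I, W=W, window=(lo, hi))


def interface_width_oracle(
    state: LatticeState, window: Optional[tuple] = None
) -> InterfaceWidthResult:
    """Naive, obviously-correct twin of :func:`interface_width`.

    Walks every cell with explicit case analysis (invasion vs own-side
    nearest-to-interface); used only in tests as an independent oracle.
    """
    L = state.L
    lo, hi = _check_window(L, window if window is not None else default_window(L))
    half = L // 2
    P1 = np.full(L, np.nan)
    P2 = np.full(L, np.nan)
    I = np.zeros(L)
    for j in range(1, L + 1):
        rows1 = [
            r
            for r in range(lo, hi + 1)
            if int(state.grid[r - 1, j - 1]) in GENUS1_CODES
        ]
        rows2 = [
            r
            for r in range(lo, hi + 1)
            if int(state.grid[r - 1, j - 1]) in GENUS2_CODES
        ]
        if rows1:
            invaders = [r for r in rows1 if r > half]
            if invaders:
                P1[j - 1] = max(invaders)  # deepest invasion of territory 2
            else:
                P1[j - 1] = max(rows1)  # nearest to the interface from above
        if rows2:
            invaders = [r for r in rows2 if r <= half]
            if invaders:
                P2[j - 1] = min(invaders)
            else:
                P2[j - 1] = min(rows2)
        if rows1 and rows2 and P1[j - 1] > P2[j - 1]:
            I[j - 1] = P1[j - 1] - P2[j - 1]
    return InterfaceWidthResult(P1=P1, P2=P2, I=I, W=float(I.sum() / L), window=(lo, hi))
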