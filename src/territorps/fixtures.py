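"""Deterministic hand-checkable lattice states and scripted trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .dynamics import DensityTrajectory
from .model_core import EMPTY, LABEL_NAMES, LatticeState, SiteState

__all__ = ["FixtureSpec", "make_fixture", "make_density_trajectory"]

_LABEL_TO_CODE = {name: i for i, name in enumerate(LABEL_NAMES)}


@dataclass(frozen=True)
class FixtureSpec:
    """A small lattice given by explicit ``(row, column, label)`` placements.

    Rows and columns are 1-based; ``label`` may be a :class:`SiteState`, an
    integer code, or a name like ``"A1"``.  Unlisted cells take ``fill``.
    """

    L: int
    placements: tuple = ()
    fill: Union[SiteState, int, str] = SiteState.E
    window_override: Optional[tuple] = None


def _code(label) -> int:
    if isinstance(label, str):
        try:
            return _LABEL_TO_CODE[label]
        except KeyError:
            raise ValueError(f"unknown label {label!r}") from None
    code = int(label)
    if not (0 <= code <= EMPTY):
        raise ValueError(f"invalid site code {code}")
    return code


def make_fixture(spec: FixtureSpec) -> LatticeState:
    """Exact lattice with the requested placements, generation 0."""
    if spec.L < 2 or spec.L % 2 != 0:
        raise ValueError(f"fixture L must be even and >= 2, got {spec.L}")
    grid = np.full((spec.L, spec.L), _code(spec.fill), dtype=np.int8)
    seen = set()
    for row, col, label in spec.placements:
        if not (1 <= row <= spec.L and 1 <= col <= spec.L):
            raise ValueError(f"placement ({row}, {col}) out of bounds for L={spec.L}")
        if (row, col) in seen:
            raise ValueError(f"duplicate placement at ({row}, {col})")
        seen.add((row, col))
        grid[row - 1, col - 1] = _code(label)
    return LatticeState(grid, generation=0)


def make_density_trajectory(
    script: Sequence[tuple],
) -> DensityTrajectory:
    """Scripted trajectory from ``(generation, counts)`` pairs.

    ``counts`` may be a length-7 sequence in label code order or a mapping
    from label names (missing labels count 0).  Generations must be
    strictly increasing.
    """
    gens = []
    rows = []
    for gen, counts in script:
        gens.append(int(gen))
        if isinstance(counts, dict):
            row = [int(counts.get(name, 0)) for name in LABEL_NAMES]
        else:
            row = [int(x) for x in counts]
            if len(row) != 7:
                raise ValueError("counts sequence must have length 7")
        if any(x < 0 for x in row):
            raise ValueError("counts must be non-negative")
        rows.append(row)
    return DensityTrajectory(np.array(gens), np.array(rows))
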