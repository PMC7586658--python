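"""Abridged age grids: contiguous 5-year age groups ending in an open group.

Every table in the package (rates, population states, mortality surfaces,
life tables) is indexed by such a grid. The grid is immutable; the final
group is always open-ended (width = inf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["AgeGrid"]


@dataclass(frozen=True)
class AgeGrid:
    """Ordered [start, width] age bins, last one open-ended.

    Parameters
    ----------
    starts : tuple of int
        Lower bounds of each age group, strictly increasing.
    widths : tuple of float
        Widths in years; all finite except the last, which is ``inf``.
    """

    starts: tuple = field(default_factory=tuple)
    widths: tuple = field(default_factory=tuple)

    def __post_init__(self):
        starts = tuple(int(s) for s in self.starts)
        widths = tuple(float(w) for w in self.widths)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "widths", widths)
        if len(starts) == 0:
            raise ValueError("empty age grid")
        if len(starts) != len(widths):
            raise ValueError("starts and widths length mismatch")
        if not math.isinf(widths[-1]):
            raise ValueError("last age group must be open-ended (width=inf)")
        if any(math.isinf(w) for w in widths[:-1]):
            raise ValueError("only the last group may be open-ended")
        for i in range(len(starts) - 1):
            if starts[i] + widths[i] != starts[i + 1]:
                raise ValueError(
                    f"age groups must be contiguous: group {i} ends at "
                    f"{starts[i] + widths[i]} but group {i + 1} starts at {starts[i + 1]}"
                )

    @classmethod
    def from_range(cls, start: int, open_start: int, width: int = 5) -> "AgeGrid":
        """Grid of ``width``-year groups from ``start`` up to the open group at ``open_start``."""
        if open_start <= start or (open_start - start) % width != 0:
            raise ValueError("open_start must exceed start by a multiple of width")
        starts = list(range(start, open_start + 1, width))
        widths = [float(width)] * (len(starts) - 1) + [math.inf]
        return cls(tuple(starts), tuple(widths))

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def n_groups(self) -> int:
        return len(self.starts)

    @property
    def labels(self) -> list:
        out = []
        for s, w in zip(self.starts, self.widths):
            out.append(f"{s}+" if math.isinf(w) else f"{s}-{s + int(w) - 1}")
        return out

    @property
    def closed_widths(self) -> np.ndarray:
        """Widths with the open group reported as nan (no finite width)."""
        w = np.array(self.widths, dtype=float)
        w[-1] = np.nan
        return w

    def index_of(self, age) -> np.ndarray:
        """Group index for exact age(s); ages below the grid raise."""
        age = np.asarray(age, dtype=float)
        if np.any(age < self.starts[0]):
            raise ValueError(f"age below grid start {self.starts[0]}")
        edges = np.array(self.starts[1:], dtype=float)
        return np.searchsorted(edges, age, side="right")

    def boundaries(self) -> np.ndarray:
        """Interior boundaries plus a large sentinel for the open group."""
        upper = [s + w for s, w in zip(self.starts[:-1], self.widths[:-1])]
        return np.array([self.starts[0]] + upper + [np.inf])

    def subset(self, min_age: int) -> "AgeGrid":
        """Sub-grid of groups whose start is >= min_age."""
        keep = [i for i, s in enumerate(self.starts) if s >= min_age]
        if not keep:
            raise ValueError("no groups at or above min_age")
        return AgeGrid(tuple(self.starts[i] for i in keep), tuple(self.widths[i] for i in keep))

    def mask_from(self, min_age: int) -> np.ndarray:
        return np.array([s >= min_age for s in self.starts])


# Canonical grids used throughout the analyses.
ADULT_GRID = AgeGrid.from_range(30, 95)     # 30-34 ... 95+ (14 groups)
ELDERLY_GRID = AgeGrid.from_range(60, 95)   # 60-64 ... 95+ (8 groups)
FULL_GRID = AgeGrid.from_range(0, 95)       # 0-4 ... 95+ (20 groups)
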