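"""Space-filling curve traversals of square grids.

A space-filling curve here is an ordered traversal of a ``side x side``
grid that visits every cell exactly once; writing the i-th base of a
sequence to the i-th visited cell folds a linear sequence into two
dimensions. Three curves are provided:

* Hilbert — recursive, locality preserving; consecutive cells are always
  4-neighbours. Defined on power-of-two sides only.
* Morton (Z-order) — the order obtained by interleaving the bits of the
  row and column indices (row bit more significant); not adjacency
  preserving. Power-of-two sides only.
* Snake (boustrophedon) — row-major with alternating direction; even rows
  run left to right. Any side.

All traversals start at cell (0, 0) and are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache


@dataclass(frozen=True)
class CurvePath:
    """An ordered traversal of a square grid visiting every cell once."""

    side: int
    cells: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    def __getitem__(self, i: int) -> tuple[int, int]:
        return self.cells[i]


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


def _hilbert_d2cell(side: int, d: int) -> tuple[int, int]:
    # classic distance-to-coordinate recurrence; first cell (0,0),
    # last cell (side-1, 0)
    row = col = 0
    t = d
    s = 1
    while s < side:
        r_bit = 1 & (t // 2)
        c_bit = 1 & (t ^ r_bit)
        if c_bit == 0:
            if r_bit == 1:
                row = s - 1 - row
                col = s - 1 - col
            row, col = col, row
        row += s * r_bit
        col += s * c_bit
        t //= 4
        s *= 2
    return row, col


def _morton_index(row: int, col: int, bits: int) -> int:
    d = 0
    for b in range(bits):
        d |= ((row >> b) & 1) << (2 * b + 1)
        d |= ((col >> b) & 1) << (2 * b)
    return d


@lru_cache(maxsize=None)
def curve_path(representation: str, side: int) -> CurvePath:
    """The full grid traversal for one curve family at the given side.

    Raises ``ValueError`` for an unknown curve or, for hilbert/morton,
    a side that is not a power of two.
    """
    if side < 1:
        raise ValueError("side must be >= 1")
    if representation in ("hilbert", "morton") and not _is_power_of_two(side):
        raise ValueError(f"{representation} curve requires a power-of-two side, got {side}")

    if representation == "hilbert":
        cells = tuple(_hilbert_d2cell(side, d) for d in range(side * side))
    elif representation == "morton":
        bits = max(1, side.bit_length() - 1)
        order = sorted(
            ((r, c) for r in range(side) for c in range(side)),
            key=lambda rc: _morton_index(rc[0], rc[1], bits),
        )
        cells = tuple(order)
    elif representation == "snake":
        out: list[tuple[int, int]] = []
        for r in range(side):
            cols = range(side) if r % 2 == 0 else range(side - 1, -1, -1)
            out.extend((r, c) for c in cols)
        cells = tuple(out)
    else:
        raise ValueError(f"unknown curve representation {representation!r}")
    return CurvePath(side=side, cells=cells)
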