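"""Hexagonal cell-grid topology.

The segment polarity network operates on a sheet of hexagonal cells.  Each
cell has six membrane sides, numbered 1..6 counterclockwise: side 1 points
along +col (posterior), side 4 along -col (anterior), sides 2/3 are the
upper diagonals and sides 5/6 the lower ones.  Side ``s`` of a cell is
apposed to side ``opposite(s) = ((s + 2) % 6) + 1`` of the neighboring
cell, e.g. side 5 faces a neighbor's side 2.

Rows are "pointy-side" offset rows (odd rows shifted half a cell along the
column axis).  With periodic boundaries (the default) every (cell, side)
slot resolves to a cell of the grid.  A single-row grid wraps vertically
onto itself, so the diagonal sides of a 1 x N row map back onto row cells;
this is what lets a 1 x 4 row stand in for a larger toroidal array.  On a
torus with an odd number of rows the naive offset arithmetic is not an
involution across the wrap seam, so the map is built by pairing slots
greedily and verified afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["GridSpec", "CellGrid", "build_grid", "opposite_side"]

# (drow, dcol) per side 1..6, for even and odd source rows.
_OFFSETS = {
    0: {1: (0, 1), 2: (-1, 0), 3: (-1, -1), 4: (0, -1), 5: (1, -1), 6: (1, 0)},
    1: {1: (0, 1), 2: (-1, 1), 3: (-1, 0), 4: (0, -1), 5: (1, 0), 6: (1, 1)},
}


def opposite_side(s: int) -> int:
    """Return the side of the neighboring cell apposed to side ``s``.

    Opposite sides differ by 3 in the 1..6 counterclockwise numbering, so
    side 5 of a cell faces side 2 of its neighbor.
    """
    if not 1 <= int(s) <= 6:
        raise ValueError(f"side index must be in 1..6, got {s}")
    return ((s + 2) % 6) + 1


@dataclass(frozen=True)
class GridSpec:
    """Shape of the cell sheet.

    ``periodic`` applies per axis (rows, cols); both default to true, giving
    a toroidal sheet.  On a non-periodic axis a side that would leave the
    sheet is a wall: the slot is apposed to itself (documented clamp mode).
    """

    rows: int
    cols: int
    periodic: tuple[bool, bool] = (True, True)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError(
                f"grid dimensions must be positive, got {self.rows}x{self.cols}"
            )


@dataclass(frozen=True)
class CellGrid:
    """A built grid: ordered cells plus the (cell, side) apposition map."""

    spec: GridSpec
    cells: tuple[tuple[int, int], ...]
    #: neighbor_map[(cell, side)] = (neighbor cell, apposed side)
    neighbor_map: dict[tuple[tuple[int, int], int], tuple[tuple[int, int], int]] = field(
        repr=False, default_factory=dict
    )

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_index(self, cell: tuple[int, int]) -> int:
        return self.cells.index(cell)

    def neighbor(self, cell: tuple[int, int], side: int) -> tuple[tuple[int, int], int]:
        """Resolve (cell, side) to (neighboring cell, apposed side)."""
        try:
            return self.neighbor_map[(cell, side)]
        except KeyError:
            raise KeyError(f"unknown (cell, side): ({cell}, {side})") from None


def _target(spec: GridSpec, cell: tuple[int, int], side: int):
    """Geometric target cell of a side, or None if it leaves the sheet."""
    r, c = cell
    dr, dc = _OFFSETS[r % 2][side]
    nr, nc = r + dr, c + dc
    per_r, per_c = spec.periodic
    if per_r:
        nr %= spec.rows
    if per_c:
        nc %= spec.cols
    if 0 <= nr < spec.rows and 0 <= nc < spec.cols:
        return (nr, nc)
    return None


def build_grid(spec: GridSpec) -> CellGrid:
    """Build the hexagonal grid and its apposition map.

    The matching is defined from the forward sides (1, 2, 3) only: for a
    fixed side the map cell -> geometric target is a translation, hence a
    bijection on the torus, so every backward slot (sides 4, 5, 6) is
    covered exactly once as a reverse.  This stays a perfect matching even
    on single-row tori, where the naive per-slot geometry is inconsistent
    across the wrap seam (there some diagonal slots pair within one cell).
    The result is checked to be a total involution.
    """
    cells = tuple((r, c) for r in range(spec.rows) for c in range(spec.cols))
    nmap: dict[tuple[tuple[int, int], int], tuple[tuple[int, int], int]] = {}
    for cell in cells:
        for s in (1, 2, 3):
            ncell = _target(spec, cell, s)
            if ncell is None:
                nmap[(cell, s)] = (cell, s)  # wall (clamp mode)
                continue
            partner = (ncell, opposite_side(s))
            if partner in nmap:
                raise AssertionError(
                    f"cannot pair slot ({cell}, {s}): partner {partner} taken"
                )
            nmap[(cell, s)] = partner
            nmap[partner] = (cell, s)
    for cell in cells:
        for s in (4, 5, 6):
            if (cell, s) not in nmap:
                # uncovered backward slots occur only at clamped boundaries
                nmap[(cell, s)] = (cell, s)
    grid = CellGrid(spec=spec, cells=cells, neighbor_map=nmap)
    _check_involution(grid)
    return grid


def _check_involution(grid: CellGrid) -> None:
    slots = {(cell, s) for cell in grid.cells for s in range(1, 7)}
    if set(grid.neighbor_map) != slots:
        raise AssertionError("apposition map does not cover every (cell, side) slot")
    for slot, partner in grid.neighbor_map.items():
        if grid.neighbor_map[partner] != slot:
            raise AssertionError(
                f"apposition map is not an involution at {slot} -> {partner}"
            )
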