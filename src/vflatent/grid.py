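"""24-2 test-pattern geometry on a 12x12 image frame.

The Humphrey 24-2 pattern samples 54 locations on a 6-degree lattice offset
3 degrees from the meridians: rows of 4/6/8/9/9/8/6/4 points at vertical
eccentricities +-21, +-15, +-9 and +-3 degrees, with the two extra points of
the 9-point rows extending to 27 degrees nasally.  For a right eye (OD) the
nasal extension lies at x = -27 and the physiologic blind spot sits
temporally at (x = +15, y = +-3); removing the two blind-spot locations
leaves 52 informative locations.  Embedding the lattice in a 12x12 frame
(column = (x + 33)/6, row = (33 - y)/6) centres it with zero padding and
makes the left/right-eye mirror the column map c -> 11 - c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FRAME_SHAPE = (12, 12)
N_LOCATIONS = 52

# x-eccentricities present in each OD row, keyed by |y|; blind spot removed.
_ROW_X_OD = {
    21: (-9, -3, 3, 9),
    15: (-15, -9, -3, 3, 9, 15),
    9: (-21, -15, -9, -3, 3, 9, 15, 21),
    3: (-27, -21, -15, -9, -3, 3, 9, 21),  # -27 nasal step point; +15 blind spot
}
_ROW_Y = (21, 15, 9, 3, -3, -9, -15, -21)


def _cell(x: int, y: int) -> tuple[int, int]:
    return (33 - y) // 6, (x + 33) // 6


@dataclass(frozen=True)
class GridMask:
    """Boolean layout of the informative 24-2 locations in the 12x12 frame.

    ``index_order[i]`` is the (row, col) frame cell of location ``i`` (0-based,
    reading order: top row to bottom, left to right within a row).
    """

    shape: tuple[int, int]
    informative: np.ndarray
    index_order: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.shape != FRAME_SHAPE:
            raise ValueError(f"mask frame must be {FRAME_SHAPE}, got {self.shape}")
        if self.informative.shape != self.shape:
            raise ValueError("informative matrix does not match frame shape")
        if int(self.informative.sum()) != len(self.index_order):
            raise ValueError("index_order does not enumerate the informative cells")
        cells = set(self.index_order)
        if len(cells) != len(self.index_order):
            raise ValueError("index_order has repeated cells")
        rows, cols = np.nonzero(self.informative)
        if cells != set(zip(rows.tolist(), cols.tolist())):
            raise ValueError("index_order is not a bijection onto informative cells")

    @property
    def n_locations(self) -> int:
        return len(self.index_order)

    def rows(self) -> np.ndarray:
        return np.array([r for r, _ in self.index_order])

    def cols(self) -> np.ndarray:
        return np.array([c for _, c in self.index_order])


def build_24_2_mask() -> GridMask:
    """Right-eye 24-2 layout: 52 informative cells centred in a 12x12 frame."""
    cells = []
    for y in _ROW_Y:
        for x in _ROW_X_OD[abs(y)]:
            cells.append(_cell(x, y))
    informative = np.zeros(FRAME_SHAPE, dtype=bool)
    for r, c in cells:
        informative[r, c] = True
    return GridMask(FRAME_SHAPE, informative, tuple(cells))


def mirror_mask(mask: GridMask) -> GridMask:
    """Horizontal mirror (c -> 11 - c): the left-eye (OS) layout of ``mask``.

    The returned index order is the reading order of the mirrored chart.
    """
    informative = mask.informative[:, ::-1].copy()
    order = sorted((r, mask.shape[1] - 1 - c) for r, c in mask.index_order)
    return GridMask(mask.shape, informative, tuple(order))


def mirror_permutation(mask: GridMask) -> np.ndarray:
    """Map left-eye location indices onto right-eye location indices.

    Returns the permutation ``p`` such that a TD vector ``td`` recorded in the
    reading order of the mirrored (OS) chart lands in right-eye order via
    ``td_od[p] = td_os``: location ``i`` of the OS chart, at frame cell
    ``(r, c)``, corresponds to the OD location at cell ``(r, 11 - c)``.
    """
    mirrored = mirror_mask(mask)
    lookup = {cell: j for j, cell in enumerate(mask.index_order)}
    ncol = mask.shape[1]
    perm = np.empty(mask.n_locations, dtype=int)
    for i, (r, c) in enumerate(mirrored.index_order):
        perm[i] = lookup[(r, ncol - 1 - c)]
    return perm
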