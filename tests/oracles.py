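"""Independent brute-force reference implementations used only by the tests.

Everything here is deliberately naive — explicit python loops, flood fill,
direct side enumeration — and shares no code with the package so it can serve
as an oracle for the vectorised implementations.
"""

from __future__ import annotations

import math
from collections import deque

QUEEN_STEPS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
ROOK_STEPS = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def flood_fill_patches(grid, nodata=0, connectivity=8):
    """Label equal-class connected components by BFS flood fill.

    Returns (labels, records) with records a list of dicts holding class_code,
    area_cells and perimeter_sides (sides facing a different value, nodata, or
    the grid edge).
    """
    nrows, ncols = len(grid), len(grid[0])
    steps = QUEEN_STEPS if connectivity == 8 else ROOK_STEPS
    labels = [[0] * ncols for _ in range(nrows)]
    records = []
    next_id = 0
    for r0 in range(nrows):
        for c0 in range(ncols):
            if grid[r0][c0] == nodata or labels[r0][c0]:
                continue
            next_id += 1
            code = grid[r0][c0]
            queue = deque([(r0, c0)])
            labels[r0][c0] = next_id
            cells = []
            while queue:
                r, c = queue.popleft()
                cells.append((r, c))
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nrows and 0 <= cc < ncols and not labels[rr][cc] \
                            and grid[rr][cc] == code:
                        labels[rr][cc] = next_id
                        queue.append((rr, cc))
            perimeter = 0
            for r, c in cells:
                for dr, dc in ROOK_STEPS:
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < nrows and 0 <= cc < ncols) or grid[rr][cc] != code:
                        perimeter += 1
            records.append({"patch_id": next_id, "class_code": code,
                            "area_cells": len(cells), "perimeter_sides": perimeter})
    return labels, records


def adjacency_counts(grid, nodata=0):
    """Double-counted rook adjacencies between non-nodata values.

    Returns a dict (code_a, code_b) -> ordered-pair count; a like side
    contributes 2 to (a, a), an unlike side 1 to (a, b) and 1 to (b, a).
    """
    nrows, ncols = len(grid), len(grid[0])
    g: dict[tuple[int, int], int] = {}
    for r in range(nrows):
        for c in range(ncols):
            a = grid[r][c]
            if a == nodata:
                continue
            for dr, dc in ((0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols:
                    b = grid[rr][cc]
                    if b == nodata:
                        continue
                    g[(a, b)] = g.get((a, b), 0) + 1
                    g[(b, a)] = g.get((b, a), 0) + 1
    return g


def min_perimeter_closed_form(z):
    """Minimum polyomino perimeter in sides: 2 * ceil(2 * sqrt(z))."""
    return 2 * math.ceil(2 * math.sqrt(z))


def edge_density_oracle(grid, class_code, cell_size, nodata=0, count_boundary=False):
    """ED by direct side enumeration, in m/ha."""
    nrows, ncols = len(grid), len(grid[0])
    sides = 0
    n_valid = 0
    for r in range(nrows):
        for c in range(ncols):
            if grid[r][c] != nodata:
                n_valid += 1
            if grid[r][c] != class_code:
                continue
            for dr, dc in ROOK_STEPS:
                rr, cc = r + dr, c + dc
                outside = not (0 <= rr < nrows and 0 <= cc < ncols)
                if outside or grid[rr][cc] == nodata:
                    if count_boundary:
                        sides += 1
                elif grid[rr][cc] != class_code:
                    sides += 1
    area_ha = n_valid * cell_size**2 / 1e4
    return sides * cell_size / area_ha


def clumpy_oracle(grid, class_code, nodata=0):
    """CLUMPY from first principles via adjacency_counts; None if undefined."""
    cells = sum(row.count(class_code) for row in grid)
    valid = sum(1 for row in grid for v in row if v != nodata)
    if cells == 0 or cells == valid:
        return None
    P = cells / valid
    g = adjacency_counts(grid, nodata)
    g_ii = g.get((class_code, class_code), 0)
    sum_g = sum(v for (a, _), v in g.items() if a == class_code)
    if sum_g <= 0:
        G = 0.0
    else:
        denom = sum_g - min_perimeter_closed_form(cells)
        G = g_ii / denom if denom > 0 else g_ii / sum_g
    if G < P and P < 0.5:
        value = (G - P) / P
    else:
        value = (G - P) / (1 - P)
    return max(-1.0, min(1.0, value))


def area_am_oracle(grid, class_code, cell_size, nodata=0, connectivity=8):
    _, recs = flood_fill_patches(grid, nodata, connectivity)
    areas = [r["area_cells"] * cell_size**2 / 1e4
             for r in recs if r["class_code"] == class_code]
    if not areas:
        return None
    return sum(a * a for a in areas) / sum(areas)


def shape_am_oracle(grid, class_code, nodata=0, connectivity=8):
    _, recs = flood_fill_patches(grid, nodata, connectivity)
    recs = [r for r in recs if r["class_code"] == class_code]
    if not recs:
        return None
    total = sum(r["area_cells"] for r in recs)
    return sum(
        (r["perimeter_sides"] / min_perimeter_closed_form(r["area_cells"]))
        * r["area_cells"] / total
        for r in recs
    )


def transition_counts_oracle(grid_from, grid_to, mask=None):
    """Per-pixel transition tally dict (code_from, code_to) -> count."""
    nrows, ncols = len(grid_from), len(grid_from[0])
    out: dict[tuple[int, int], int] = {}
    for r in range(nrows):
        for c in range(ncols):
            if mask is not None and not mask[r][c]:
                continue
            key = (grid_from[r][c], grid_to[r][c])
            out[key] = out.get(key, 0) + 1
    return out


def enumerate_polyominoes(n):
    """All fixed polyominoes of n cells, as canonical frozensets of (r, c).

    Grown cell-by-cell with dedup by translation-normalised form; used to
    confirm the minimum-perimeter rule by exhaustion at small n.
    """
    def normalise(cells):
        rmin = min(r for r, _ in cells)
        cmin = min(c for _, c in cells)
        return frozenset((r - rmin, c - cmin) for r, c in cells)

    current = {normalise([(0, 0)])}
    for _ in range(n - 1):
        nxt = set()
        for poly in current:
            for r, c in poly:
                for dr, dc in ROOK_STEPS:
                    cell = (r + dr, c + dc)
                    if cell not in poly:
                        nxt.add(normalise(poly | {cell}))
        current = nxt
    return current


def polyomino_perimeter(cells):
    per = 0
    for r, c in cells:
        for dr, dc in ROOK_STEPS:
            if (r + dr, c + dc) not in cells:
                per += 1
    return per
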