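"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_supercover(x: np.ndarray, y: np.ndarray, side: int) -> set[tuple[int, int]]:
    """Independent raster oracle: exhaustive cell-segment intersection test.

    Cells are half-open ``[c/side, (c+1)/side) x [r/side, (r+1)/side)`` with
    the top/right boundary closed for the last row/column (the point (1, 1)
    belongs to the last cell).  A cell is occupied iff some segment of the
    polyline has a parameter t in [0, 1] whose point lies in the cell — solved
    exactly with half-open interval arithmetic per axis, no rasterization
    involved.
    """
    cells: set[tuple[int, int]] = set()
    px, py = np.asarray(x) * side, np.asarray(y) * side

    def axis_interval(u0: float, du: float, lo_edge: float, hi_edge: float,
                      top_closed: bool):
        """Parameter t-set where ``lo_edge <= u(t) < hi_edge`` (<= if closed)."""
        if du == 0:
            inside = u0 >= lo_edge and (u0 < hi_edge or (top_closed and u0 <= hi_edge))
            return (0.0, False, 1.0, False) if inside else None
        t_lo = (lo_edge - u0) / du
        t_hi = (hi_edge - u0) / du
        if du > 0:
            return (t_lo, False, t_hi, not top_closed)
        return (t_hi, not top_closed, t_lo, False)

    def intersect(a, b):
        # compare (value, strictness): at equal values the strict bound is tighter
        lo_v, lo_strict = max((a[0], a[1]), (b[0], b[1]))
        hi_v, hi_nonstrict = min((a[2], not a[3]), (b[2], not b[3]))
        return lo_v, lo_strict, hi_v, not hi_nonstrict

    for i in range(len(px) - 1):
        x0, y0, x1, y1 = px[i], py[i], px[i + 1], py[i + 1]
        cmin = max(0, int(np.floor(min(x0, x1))) - 1)
        cmax = min(side - 1, int(np.floor(max(x0, x1))) + 1)
        rmin = max(0, int(np.floor(min(y0, y1))) - 1)
        rmax = min(side - 1, int(np.floor(max(y0, y1))) + 1)
        for c in range(cmin, cmax + 1):
            tx = axis_interval(x0, x1 - x0, c, c + 1, c == side - 1)
            if tx is None:
                continue
            for r in range(rmin, rmax + 1):
                ty = axis_interval(y0, y1 - y0, r, r + 1, r == side - 1)
                if ty is None:
                    continue
                lo, lo_strict, hi, hi_strict = intersect(
                    intersect(tx, ty), (0.0, False, 1.0, False))
                nonempty = lo < hi or (lo == hi and not lo_strict and not hi_strict)
                if nonempty:
                    cells.add((r, c))
    return cells
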