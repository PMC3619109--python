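"""Direct geometric planar-extent estimators on the graph of a waveform.

A waveform is treated as a self-avoiding open curve in a bounded plane.  Both
estimators first map it into the unit square by a double linear transformation
of the axes; the Sevcik estimator then works from the Euclidean length of the
normalized polyline, while the box-counting estimator rasterizes the polyline
into a 2N-by-2N binary image and regresses occupied-box counts against box
size on dyadic scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .synthesis import Waveform, MIN_N

__all__ = [
    "NormalizedCurve",
    "DimensionEstimate",
    "BinaryGraphImage",
    "normalize_to_unit_square",
    "sevcik_dimension",
    "rasterize_graph",
    "box_count_dimension",
]


@dataclass(frozen=True)
class NormalizedCurve:
    """A waveform embedded in the unit square.

    ``x`` increases uniformly from 0 to 1 over ``n`` points (``n_prime = n - 1``
    observation intervals); ``y`` is the min-max normalized amplitude; a
    constant series is centred at ``y = 0.5``.  ``length_L`` is the Euclidean
    polyline length (>= 1, the x-extent alone).
    """

    x: np.ndarray
    y: np.ndarray
    length_L: float

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def n_prime(self) -> int:
        return self.n - 1


@dataclass(frozen=True)
class DimensionEstimate:
    """A planar-extent estimate with its method tag and fit diagnostics.

    ``diagnostics`` carries whatever is needed to re-derive ``value`` (curve
    length and interval count for the Sevcik method; per-scale box counts and
    the log-log fit for box counting).
    """

    value: float
    method: str
    diagnostics: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class BinaryGraphImage:
    """Binary raster of the normalized curve on a 2N-by-2N grid.

    ``grid[r, c]`` is True where the polyline intersects the half-open cell
    ``[c/S, (c+1)/S) x [r/S, (r+1)/S)`` with ``S = 2N``; rows index the y-axis
    bottom-up and the boundary points at coordinate 1 belong to the last
    row/column.
    """

    grid: np.ndarray

    @property
    def side(self) -> int:
        return self.grid.shape[0]


def normalize_to_unit_square(w: Waveform | np.ndarray) -> NormalizedCurve:
    """Embed the waveform in the unit square and measure its polyline length."""
    v = w.samples if isinstance(w, Waveform) else np.asarray(w, dtype=float)
    n = v.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    if not np.all(np.isfinite(v)):
        raise ValueError("waveform contains non-finite samples")
    x = np.linspace(0.0, 1.0, n)
    vmin, vmax = v.min(), v.max()
    if vmax > vmin:
        y = (v - vmin) / (vmax - vmin)
    else:
        y = np.full(n, 0.5)  # constant series: centre of the square
    length = float(np.sum(np.hypot(np.diff(x), np.diff(y))))
    return NormalizedCurve(x=x, y=y, length_L=length)


def sevcik_dimension(w: Waveform | np.ndarray) -> DimensionEstimate:
    """Curve-length planar-extent estimate, ``D = 1 + ln(L) / ln(2 N')``.

    ``L`` is the polyline length of the unit-square-normalized waveform and
    ``N' = N - 1`` its number of observation intervals.  A straight horizontal
    line (L = 1) gives exactly D = 1; increasingly plane-filling waveforms
    approach 2.
    """
    curve = w if isinstance(w, NormalizedCurve) else normalize_to_unit_square(w)
    if curve.n < MIN_N:
        raise ValueError(f"need at least {MIN_N} samples, got {curve.n}")
    value = 1.0 + np.log(curve.length_L) / np.log(2.0 * curve.n_prime)
    return DimensionEstimate(
        value=float(value), method="sevcik",
        diagnostics={"length_L": curve.length_L, "n_prime": curve.n_prime},
    )


def _supercover_segment(x0: float, y0: float, x1: float, y1: float,
                        side: int, rows: list[int], cols: list[int]) -> None:
    """Append all grid cells intersected by one segment (pixel coordinates).

    Cells are half-open ``[c, c+1) x [r, r+1)``; coordinates equal to ``side``
    land in the last cell.  Exact corner crossings mark the cell containing
    the corner point as well (the supercover property: no intersected cell is
    skipped).
    """
    def cell(v: float) -> int:
        return min(int(v), side - 1)

    cx, cy = cell(x0), cell(y0)
    ex, ey = cell(x1), cell(y1)
    rows.append(cy); cols.append(cx)
    dx, dy = x1 - x0, y1 - y0
    sx = 1 if dx > 0 else (-1 if dx < 0 else 0)
    sy = 1 if dy > 0 else (-1 if dy < 0 else 0)

    # time to the next boundary of the *current cell* (handles starts exactly
    # on a boundary, including the clamped top/right edge)
    if sx > 0:
        t_max_x = (cx + 1.0 - x0) / dx
        t_dx = 1.0 / dx
    elif sx < 0:
        t_max_x = (x0 - cx) / -dx
        t_dx = -1.0 / dx
    else:
        t_max_x, t_dx = np.inf, np.inf
    if sy > 0:
        t_max_y = (cy + 1.0 - y0) / dy
        t_dy = 1.0 / dy
    elif sy < 0:
        t_max_y = (y0 - cy) / -dy
        t_dy = -1.0 / dy
    else:
        t_max_y, t_dy = np.inf, np.inf

    while (cx, cy) != (ex, ey):
        if cx == ex:
            cy += sy
            t_max_y += t_dy
        elif cy == ey:
            cx += sx
            t_max_x += t_dx
        elif t_max_x < t_max_y:
            cx += sx
            t_max_x += t_dx
        elif t_max_y < t_max_x:
            cy += sy
            t_max_y += t_dy
        else:
            # exact corner crossing: the corner point itself lies in the cell
            # toward positive x/y; mark it so the cover has no gaps
            rows.append(cy + (1 if sy > 0 else 0))
            cols.append(cx + (1 if sx > 0 else 0))
            cx += sx
            cy += sy
            t_max_x += t_dx
            t_max_y += t_dy
        rows.append(cy)
        cols.append(cx)


def rasterize_graph(c: NormalizedCurve | Waveform | np.ndarray) -> BinaryGraphImage:
    """Supercover rasterization of the normalized curve on a 2N-by-2N grid.

    Every grid cell the polyline passes through is marked — consecutive points
    are connected by segments and all intersected cells are set, so the drawn
    curve never skips cells (8-connected along the polyline, every column
    occupied).
    """
    curve = c if isinstance(c, NormalizedCurve) else normalize_to_unit_square(c)
    side = 2 * curve.n
    px = curve.x * side
    py = curve.y * side
    rows: list[int] = []
    cols: list[int] = []
    for i in range(curve.n - 1):
        _supercover_segment(px[i], py[i], px[i + 1], py[i + 1], side, rows, cols)
    grid = np.zeros((side, side), dtype=bool)
    grid[np.asarray(rows), np.asarray(cols)] = True
    return BinaryGraphImage(grid=grid)


def box_count_dimension(img: BinaryGraphImage | np.ndarray,
                        min_box: int = 2, max_box: int | None = None) -> DimensionEstimate:
    """Box-counting planar extent from a binary graph image.

    Counts occupied boxes at dyadic box sizes and returns the OLS slope of
    ``log10 N(eps)`` against ``log10 (1/eps)``.  The default scale range runs
    from 2 px to side/4: the single-pixel scale and the near-full-image scales
    are excluded as saturated.  The grid is zero-padded up to a power-of-two
    side if necessary.
    """
    grid = img.grid if isinstance(img, BinaryGraphImage) else np.asarray(img, dtype=bool)
    if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
        raise ValueError("image must be a square 2D boolean grid")
    if not grid.any():
        raise ValueError("empty image: no occupied cells to count")
    side = grid.shape[0]
    pow2 = 1 << (side - 1).bit_length()
    if pow2 != side:
        padded = np.zeros((pow2, pow2), dtype=bool)
        padded[:side, :side] = grid
        grid, side = padded, pow2
    if max_box is None:
        max_box = side // 4
    sizes = []
    counts = []
    eps = min_box
    while eps <= max_box:
        nb = side // eps
        occupied = grid[:nb * eps, :nb * eps].reshape(nb, eps, nb, eps).any(axis=(1, 3))
        sizes.append(eps)
        counts.append(int(occupied.sum()))
        eps *= 2
    if len(sizes) < 2:
        raise ValueError("fewer than 2 usable box scales; image too small")
    logx = np.log10(1.0 / np.asarray(sizes, dtype=float))
    logy = np.log10(np.asarray(counts, dtype=float))
    slope, intercept = np.polyfit(logx, logy, 1)
    return DimensionEstimate(
        value=float(slope), method="box_count",
        diagnostics={
            "box_sizes": sizes, "box_counts": counts,
            "intercept": float(intercept), "side": side,
        },
    )
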