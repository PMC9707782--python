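"""Site covariates: buffer-weighted raster extraction, point counts,
temporally weighted vegetation index, standardization and collinearity.

Camera-site covariates are extracted from planar gridded layers within a
disc buffer (150 m by default), with each cell's contribution weighted by
the area of its intersection with the disc.  Intersection areas are
estimated by regular sub-cell sampling (32 x 32 points per cell by default),
which converges to the exact geometric weighting well below the tolerances
that matter here.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "Grid",
    "read_ascii_grid",
    "write_ascii_grid",
    "weighted_disc_mean",
    "count_points_in_disc",
    "monthly_evi",
    "standardize",
    "collinearity_screen",
]


@dataclass
class Grid:
    """A rectangular planar raster in metre coordinates.

    ``values[0, 0]`` is the north-west (top-left) cell, matching the ESRI
    ASCII grid layout.  ``origin`` is the lower-left corner of the grid
    (xllcorner, yllcorner).  Missing cells are NaN.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_value(self, row: int, col: int) -> float:
        return float(self.values[row, col])


def read_ascii_grid(path) -> Grid:
    """Read an ESRI ASCII grid (.asc) file."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {"ncols", "nrows", "xllcorner", "yllcorner",
                                    "cellsize", "nodata_value"}:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    values = np.asarray(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape {values.shape} disagrees with header")
    nodata = header.get("nodata_value")
    if nodata is not None:
        values[values == nodata] = np.nan
    return Grid(header["xllcorner"], header["yllcorner"], header["cellsize"], values)


def write_ascii_grid(grid: Grid, path, nodata: float = -9999.0) -> None:
    vals = np.where(np.isnan(grid.values), nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\nnrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.origin_x}\nyllcorner {grid.origin_y}\n")
        fh.write(f"cellsize {grid.cell_size}\nNODATA_value {nodata}\n")
        for row in vals:
            fh.write(" ".join(format(v, ".10g") for v in row) + "\n")


def _cell_weights(grid: Grid, cx: float, cy: float, radius: float,
                  subcells: int) -> tuple[np.ndarray, np.ndarray]:
    """Fractional disc coverage of each grid cell touching the disc.

    Returns (values, weights) over cells with positive coverage; weights are
    intersection areas in cell-area units estimated by sub-cell sampling.
    """
    cs = grid.cell_size
    top = grid.origin_y + grid.nrows * cs
    # candidate cell index window from the disc bounding box
    col_lo = max(0, int(np.floor((cx - radius - grid.origin_x) / cs)))
    col_hi = min(grid.ncols - 1, int(np.floor((cx + radius - grid.origin_x) / cs)))
    row_lo = max(0, int(np.floor((top - (cy + radius)) / cs)))
    row_hi = min(grid.nrows - 1, int(np.floor((top - (cy - radius)) / cs)))
    if col_lo > col_hi or row_lo > row_hi:
        raise ValueError("buffer disc lies entirely outside the grid")

    cols = np.arange(col_lo, col_hi + 1)
    rows = np.arange(row_lo, row_hi + 1)
    # sub-cell sample offsets (midpoints of a subcells x subcells partition)
    off = (np.arange(subcells) + 0.5) / subcells * cs
    x_cells = grid.origin_x + cols * cs                      # west edges
    y_cells = top - (rows + 1) * cs                          # south edges
    sx = x_cells[:, None] + off[None, :]                     # (ncol, s)
    sy = y_cells[:, None] + off[None, :]                     # (nrow, s)
    dx2 = (sx - cx) ** 2                                     # (ncol, s)
    dy2 = (sy - cy) ** 2                                     # (nrow, s)
    inside = dy2[:, None, :, None] + dx2[None, :, None, :] <= radius ** 2
    frac = inside.mean(axis=(2, 3))                          # (nrow, ncol)
    vals = grid.values[np.ix_(rows, cols)]
    mask = frac > 0
    return vals[mask], frac[mask]


def weighted_disc_mean(grid: Grid, center: tuple[float, float], radius: float = 150.0,
                       subcells: int = 32) -> float:
    """Area-weighted mean of grid cells over a disc buffer.

    Each intersected cell contributes its value weighted by the area of its
    intersection with the disc; missing (NaN) cells are excluded from both
    numerator and denominator.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    vals, wts = _cell_weights(grid, center[0], center[1], radius, subcells)
    ok = ~np.isnan(vals)
    if not ok.any() or wts[ok].sum() == 0:
        raise ValueError("buffer disc covers only missing cells")
    return float(np.average(vals[ok], weights=wts[ok]))


def count_points_in_disc(points: np.ndarray, center: tuple[float, float],
                         radius: float = 500.0) -> int:
    """Number of points within Euclidean distance <= radius of center."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return 0
    d2 = (pts[:, 0] - center[0]) ** 2 + (pts[:, 1] - center[1]) ** 2
    return int(np.sum(d2 <= radius ** 2))


def _overlap_days(start: date, length_days: int, year: int, month: int) -> int:
    """Days of overlap between [start, start+length) and a calendar month."""
    m_start = date(year, month, 1)
    m_end = (date(year + 1, 1, 1) if month == 12 else date(year, month + 1, 1))
    w_end = start + timedelta(days=length_days)
    lo = max(start, m_start)
    hi = min(w_end, m_end)
    return max(0, (hi - lo).days)


def monthly_evi(windows, year: int, month: int, center: tuple[float, float],
                radius: float = 150.0, subcells: int = 32) -> float:
    """Monthly vegetation index from 16-day composite windows.

    ``windows`` is an iterable of ``(start_date, length_days, grid)``.  The
    monthly value is the overlap-day-weighted average of each window's
    buffer mean: sum_w d_w * e_w / sum_w d_w, where d_w is the number of
    days window w shares with the month.  Returns NaN when no window
    overlaps the month.
    """
    num = 0.0
    den = 0.0
    for start, length, grid in windows:
        d = _overlap_days(start, length, year, month)
        if d > 0:
            num += d * weighted_disc_mean(grid, center, radius, subcells)
            den += d
    if den == 0:
        return float("nan")
    return num / den


def standardize(table: pd.DataFrame, columns=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center and scale continuous columns to mean 0, sd 1 (sample sd, n-1).

    Returns the transformed table and a parameter table (mean, sd per
    column) for back-transformation.  Binary/factor columns should not be
    passed; a constant column is an error.
    """
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    out = table.copy()
    params = {}
    for col in columns:
        x = table[col].astype(float)
        mu, sd = x.mean(), x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} is constant; cannot standardize")
        out[col] = (x - mu) / sd
        params[col] = {"mean": mu, "sd": sd}
    return out, pd.DataFrame(params).T


def collinearity_screen(table: pd.DataFrame, threshold: float = 0.7,
                        columns=None) -> pd.DataFrame:
    """Pairs of continuous covariates with |Pearson r| >= threshold.

    An empty result means the covariate set passes the screen.
    """
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    if len(columns) < 2:
        raise ValueError("need at least two continuous columns")
    corr = table[columns].corr(method="pearson")
    rows = []
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            r = corr.loc[a, b]
            if abs(r) >= threshold:
                rows.append({"var_a": a, "var_b": b, "r": float(r)})
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r"])
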