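"""Canopy height models, gap detection and transect-buffer gap fractions.

A canopy surface model (per-cell maximum of first-return heights) minus a
digital terrain model (per-cell minimum of ground heights) yields the canopy
height model (CHM).  Gaps are CHM cells strictly below a height threshold
(2, 5 and 11 m are the conventional choices); the gap fraction inside a
buffer zone around the field transects is the canopy-openness statistic
validated against the short-lived-pioneer frequency.

Grids are planar-metric, origin at the lower-left corner, row 0 at the
northern edge (north-up, row-major).  Rasters round-trip through ESRI ASCII
grid text files.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from scipy import stats

__all__ = [
    "HeightRaster",
    "rasterize",
    "compute_chm",
    "buffer_mask",
    "gap_fraction",
    "indicator_gap_correlation",
    "write_ascii_grid",
    "read_ascii_grid",
]

DEFAULT_THRESHOLDS = (2.0, 5.0, 11.0)


@dataclasses.dataclass
class HeightRaster:
    """Gridded height surface.

    ``data[0, :]`` is the northernmost row; cell (row, col) has center
    ``(x0 + (col + 0.5) * cell, y0 + (nrows - row - 0.5) * cell)``.
    """

    origin: tuple  # (x0, y0) of the lower-left corner, m
    cell_size: float
    data: np.ndarray
    nodata: float = -9999.0
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D grid")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def aligned_with(self, other: "HeightRaster") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.origin, other.origin)
                and np.isclose(self.cell_size, other.cell_size))

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) center coordinate grids matching ``data``."""
        nrows, ncols = self.data.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_size
        ys = y0 + (nrows - np.arange(nrows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


def rasterize(points: pd.DataFrame, cls: str, cell_size: float,
              extent: Sequence[float]) -> HeightRaster:
    """Grid a point list by per-cell extremum and fill holes by
    inverse-distance interpolation.

    ``points`` needs columns ``x, y, z, cls``.  First returns take the
    per-cell maximum (canopy surface); ground points take the minimum
    (terrain).  Cells without points are filled by inverse-distance-squared
    weighting of the 8 nearest filled cell centers, so no nodata remains.
    """
    if cls not in ("first", "ground"):
        raise ValueError("cls must be 'first' or 'ground'")
    xmin, ymin, xmax, ymax = (float(v) for v in extent)
    sub = points[points["cls"] == cls]
    x = sub["x"].to_numpy()
    y = sub["y"].to_numpy()
    z = sub["z"].to_numpy()
    inside = (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)
    if not inside.any():
        raise ValueError(f"no '{cls}' points inside the extent")
    x, y, z = x[inside], y[inside], z[inside]

    ncols = int(np.ceil((xmax - xmin) / cell_size))
    nrows = int(np.ceil((ymax - ymin) / cell_size))
    col = np.clip(((x - xmin) / cell_size).astype(int), 0, ncols - 1)
    row = nrows - 1 - np.clip(((y - ymin) / cell_size).astype(int),
                              0, nrows - 1)

    fill = -np.inf if cls == "first" else np.inf
    grid = np.full((nrows, ncols), fill)
    flat = row * ncols + col
    if cls == "first":
        np.maximum.at(grid.ravel(), flat, z)
    else:
        np.minimum.at(grid.ravel(), flat, z)
    filled = np.isfinite(grid)

    if not filled.all():
        ras = HeightRaster(origin=(xmin, ymin), cell_size=cell_size,
                           data=grid)
        cx, cy = ras.cell_centers()
        src = np.column_stack([cx[filled], cy[filled]])
        dst = np.column_stack([cx[~filled], cy[~filled]])
        tree = cKDTree(src)
        k = min(8, len(src))
        d, idx = tree.query(dst, k=k)
        d = np.atleast_2d(d.T).T
        idx = np.atleast_2d(idx.T).T
        w = 1.0 / np.maximum(d, 1e-12) ** 2
        vals = grid[filled][idx]
        grid[~filled] = (w * vals).sum(axis=1) / w.sum(axis=1)

    return HeightRaster(origin=(xmin, ymin), cell_size=cell_size, data=grid,
                        meta={"class": cls, "n_points": int(len(z))})


def compute_chm(csm: HeightRaster, dtm: HeightRaster) -> HeightRaster:
    """CHM = canopy surface model - digital terrain model.

    Negative cells (terrain above canopy, an interpolation artefact) are
    clamped to 0; the clamp count is recorded in ``meta['n_clamped']``.
    """
    if not csm.aligned_with(dtm):
        raise ValueError("CSM and DTM grids are not aligned")
    diff = csm.data - dtm.data
    n_clamped = int((diff < 0).sum())
    return HeightRaster(origin=csm.origin, cell_size=csm.cell_size,
                        data=np.maximum(diff, 0.0),
                        meta={"n_clamped": n_clamped})


def buffer_mask(transect: np.ndarray, radius_m: float,
                grid: HeightRaster) -> np.ndarray:
    """Boolean grid: cell center within ``radius_m`` of the transect polyline.

    ``transect`` is an (n, 2) vertex array in planar meters; a degenerate
    (single-vertex or zero-length) polyline yields a disk.
    """
    transect = np.asarray(transect, dtype=float)
    if transect.ndim != 2 or transect.shape[0] < 1 or transect.shape[1] != 2:
        raise ValueError("transect must be an (n, 2) vertex array")
    if radius_m < 0:
        raise ValueError("radius_m must be >= 0")
    uniq = np.unique(transect, axis=0)
    if len(uniq) == 1:
        geom = shapely.Point(uniq[0])
    else:
        geom = shapely.LineString(transect)
    if radius_m > 0:
        geom = geom.buffer(radius_m, quad_segs=128)
    shapely.prepare(geom)
    cx, cy = grid.cell_centers()
    return shapely.intersects_xy(geom, cx.ravel(), cy.ravel()).reshape(cx.shape)


def gap_fraction(chm: HeightRaster, threshold_m: float,
                 buffer: np.ndarray) -> float:
    """Share of in-buffer cells whose canopy height is strictly below the
    threshold."""
    buffer = np.asarray(buffer, dtype=bool)
    if buffer.shape != chm.data.shape:
        raise ValueError("buffer grid and CHM are not aligned")
    n = int(buffer.sum())
    if n == 0:
        raise ValueError("empty buffer: no cells to evaluate")
    return float((chm.data[buffer] < threshold_m).sum() / n)


@dataclasses.dataclass
class CorrelationReport:
    r: float
    t: float
    df: int
    p: float


def indicator_gap_correlation(
        sectors: Sequence[tuple]) -> CorrelationReport:
    """Pearson correlation between per-sector gap fraction and short-lived
    pioneer frequency, with the t statistic on n - 2 degrees of freedom."""
    arr = np.asarray(sectors, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (gap_fraction, urti_freq) sectors")
    gap, urti = arr[:, 0], arr[:, 1]
    if np.ptp(gap) == 0 or np.ptp(urti) == 0:
        raise ValueError("zero variance in gap fraction or indicator")
    n = len(arr)
    r = float(np.corrcoef(gap, urti)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationReport(r=r, t=float(t), df=df, p=float(p))


def write_ascii_grid(path, raster: HeightRaster) -> None:
    """ESRI ASCII grid writer (full float precision, exact round-trip)."""
    nrows, ncols = raster.data.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.origin[0]!r}\n")
        fh.write(f"yllcorner {raster.origin[1]!r}\n")
        fh.write(f"cellsize {raster.cell_size!r}\n")
        fh.write(f"NODATA_value {raster.nodata!r}\n")
        data = np.where(np.isnan(raster.data), raster.nodata, raster.data)
        for row in data:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path) -> HeightRaster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", -9999.0)
    data = np.where(data == nodata, np.nan, data)
    assert data.shape == (int(header["nrows"]), int(header["ncols"]))
    return HeightRaster(origin=(header["xllcorner"], header["yllcorner"]),
                        cell_size=header["cellsize"], data=data,
                        nodata=nodata)
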