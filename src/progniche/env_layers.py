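"""Environmental raster stacks: loading, alignment, extraction, background, PCA.

An :class:`EnvStack` is an ordered set of continuous environmental variables
(ENVIREM-like) on a shared regular lon/lat grid (EPSG:4326) with a common
nodata mask. Layers are stored on disk as plain-text ESRI ASCII grids
(``.asc``), one band per file on a shared grid. Point values are extracted
nearest-cell by default (bilinear optional); background samples are drawn
cell-uniform over the unmasked cells of an accessible area.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .occurrence_prep import AccessibleArea

ASC_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid: lower-left corner, cell size, shape (EPSG:4326)."""

    west: float
    south: float
    resolution: float
    nrows: int
    ncols: int

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def north(self) -> float:
        return self.south + self.nrows * self.resolution

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.resolution

    def lon_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.ncols) + 0.5) * self.resolution

    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, north to south (row-major raster order)."""
        return self.north - (np.arange(self.nrows) + 0.5) * self.resolution

    def cell_index(self, lon, lat):
        """Row/col of the cell containing each point; -1 where outside."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.west) / self.resolution).astype(int)
        row = np.floor((self.north - lat) / self.resolution).astype(int)
        # points exactly on the north/east edge belong to the edge cell
        col = np.where((lon == self.east), self.ncols - 1, col)
        row = np.where((lat == self.south + self.nrows * self.resolution), 0, row)
        inside = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        return np.where(inside, row, -1), np.where(inside, col, -1)

    def approx_equal(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.nrows == other.nrows
            and self.ncols == other.ncols
            and abs(self.west - other.west) <= tol
            and abs(self.south - other.south) <= tol
            and abs(self.resolution - other.resolution) <= tol
        )


class EnvStack:
    """Aligned multi-variable raster grid with a shared nodata mask.

    ``data`` has shape (n_vars, nrows, ncols) with NaN on masked cells;
    ``mask`` is True on valid cells. All layers share the grid exactly and
    unmasked cells are finite in every layer.
    """

    def __init__(self, variables, grid: GridSpec, data: np.ndarray, mask: np.ndarray | None = None):
        data = np.asarray(data, dtype=float)
        if data.ndim != 3 or data.shape[0] != len(variables):
            raise ValueError("data must have shape (n_vars, nrows, ncols)")
        if data.shape[1:] != (grid.nrows, grid.ncols):
            raise ValueError("data shape does not match grid")
        if mask is None:
            mask = np.all(np.isfinite(data), axis=0)
        mask = np.asarray(mask, dtype=bool)
        data = data.copy()
        data[:, ~mask] = np.nan
        if not np.all(np.isfinite(data[:, mask])):
            raise ValueError("unmasked cells must be finite in every layer")
        self.variables = list(variables)
        self.grid = grid
        self.data = data
        self.mask = mask

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    def layer(self, name: str) -> np.ndarray:
        return self.data[self.variables.index(name)]

    def valid_cell_vectors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(rows, cols, values) of all unmasked cells; values is (n_cells, n_vars)."""
        rows, cols = np.nonzero(self.mask)
        return rows, cols, self.data[:, rows, cols].T

    def cell_lonlat(self, rows, cols) -> tuple[np.ndarray, np.ndarray]:
        return self.grid.lon_centers()[cols], self.grid.lat_centers()[rows]

    def cells_in_area(self, m: AccessibleArea) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of unmasked cells whose centers fall in M (boundary in)."""
        rows, cols = np.nonzero(self.mask)
        lon, lat = self.cell_lonlat(rows, cols)
        keep = m.covers_xy(lon, lat)
        return rows[keep], cols[keep]

    def area_mask(self, m: AccessibleArea) -> np.ndarray:
        out = np.zeros_like(self.mask)
        rows, cols = self.cells_in_area(m)
        out[rows, cols] = True
        return out

    # -- I/O ---------------------------------------------------------------

    def write_ascii(self, directory) -> list[Path]:
        """Write one .asc file per variable on the shared grid."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, name in enumerate(self.variables):
            path = directory / f"{name}.asc"
            write_ascii_grid(path, self.data[i], self.grid)
            paths.append(path)
        return paths


def write_ascii_grid(path, array: np.ndarray, grid: GridSpec) -> None:
    arr = np.where(np.isfinite(array), array, ASC_NODATA)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.west!r}\n"
        f"yllcorner {grid.south!r}\n"
        f"cellsize {grid.resolution!r}\n"
        f"NODATA_value {ASC_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt="%.10g")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec]:
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    grid = GridSpec(
        west=header["xllcorner"], south=header["yllcorner"],
        resolution=header["cellsize"], nrows=int(header["nrows"]), ncols=int(header["ncols"]),
    )
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    nodata = header.get("nodata_value", ASC_NODATA)
    arr[arr == nodata] = np.nan
    if arr.shape != (grid.nrows, grid.ncols):
        raise ValueError(f"{path}: data shape {arr.shape} does not match header")
    return arr, grid


def load_stack(paths, resample: bool = False) -> EnvStack:
    """Load .asc layers into an aligned stack with the union nodata mask.

    All layers must share the grid exactly; with ``resample=True`` layers are
    instead nearest-neighbour resampled onto the first layer's grid.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no raster paths given")
    layers, grids = zip(*(read_ascii_grid(p) for p in paths))
    ref = grids[0]
    aligned = [layers[0]]
    for arr, grid, path in zip(layers[1:], grids[1:], paths[1:]):
        if grid.approx_equal(ref):
            aligned.append(arr)
        elif resample:
            r, c = grid.cell_index(
                np.repeat(ref.lon_centers()[None, :], ref.nrows, 0),
                np.repeat(ref.lat_centers()[:, None], ref.ncols, 1),
            )
            out = np.full((ref.nrows, ref.ncols), np.nan)
            ok = (r >= 0)
            out[ok] = arr[r[ok], c[ok]]
            aligned.append(out)
        else:
            raise ValueError(
                f"{path}: grid does not match {paths[0]} (use resample=True to force)"
            )
    names = [p.stem for p in paths]
    return EnvStack(names, ref, np.stack(aligned))


def select_variables(stack: EnvStack, names) -> EnvStack:
    """Restrict the stack to ``names`` in the order given."""
    names = list(names)
    if not names:
        raise ValueError("no variables selected")
    unknown = [n for n in names if n not in stack.variables]
    if unknown:
        raise KeyError(f"unknown variables {unknown}; available: {stack.variables}")
    idx = [stack.variables.index(n) for n in names]
    return EnvStack(names, stack.grid, stack.data[idx], stack.mask.copy())


def extract(stack: EnvStack, lons, lats, ids=None, bilinear: bool = False
            ) -> tuple[pd.DataFrame, list]:
    """Environmental vectors at point locations.

    Returns (EnvMatrix, dropped ids): a DataFrame of variable columns indexed
    by record id, with points falling outside the grid or on nodata cells
    dropped and reported. Nearest-cell lookup by default; ``bilinear``
    interpolates from the four surrounding cell centers (requires all four
    valid).
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if ids is None:
        ids = np.arange(len(lons))
    ids = np.asarray(ids)
    if bilinear:
        values, ok = _bilinear(stack, lons, lats)
    else:
        rows, cols = stack.grid.cell_index(lons, lats)
        ok = rows >= 0
        ok[ok] = stack.mask[rows[ok], cols[ok]]
        values = np.full((len(lons), stack.n_vars), np.nan)
        values[ok] = stack.data[:, rows[ok], cols[ok]].T
    if not ok.any():
        raise ValueError("all points fall outside the grid or on nodata cells")
    matrix = pd.DataFrame(values[ok], columns=stack.variables, index=pd.Index(ids[ok], name="id"))
    return matrix, list(ids[~ok])


def _bilinear(stack: EnvStack, lons, lats):
    grid = stack.grid
    # fractional position in units of cells, relative to cell-center lattice
    fx = (lons - grid.west) / grid.resolution - 0.5
    fy = (grid.north - lats) / grid.resolution - 0.5
    x0 = np.floor(fx).astype(int)
    y0 = np.floor(fy).astype(int)
    wx = fx - x0
    wy = fy - y0
    values = np.full((len(lons), stack.n_vars), np.nan)
    ok = (x0 >= 0) & (x0 + 1 < grid.ncols) & (y0 >= 0) & (y0 + 1 < grid.nrows)
    if ok.any():
        corners_ok = (
            stack.mask[y0[ok], x0[ok]] & stack.mask[y0[ok], x0[ok] + 1]
            & stack.mask[y0[ok] + 1, x0[ok]] & stack.mask[y0[ok] + 1, x0[ok] + 1]
        )
        idx = np.nonzero(ok)[0][corners_ok]
        ok = np.zeros_like(ok)
        ok[idx] = True
        w00 = (1 - wx[idx]) * (1 - wy[idx])
        w10 = wx[idx] * (1 - wy[idx])
        w01 = (1 - wx[idx]) * wy[idx]
        w11 = wx[idx] * wy[idx]
        values[idx] = (
            stack.data[:, y0[idx], x0[idx]].T * w00[:, None]
            + stack.data[:, y0[idx], x0[idx] + 1].T * w10[:, None]
            + stack.data[:, y0[idx] + 1, x0[idx]].T * w01[:, None]
            + stack.data[:, y0[idx] + 1, x0[idx] + 1].T * w11[:, None]
        )
    return values, ok


def sample_background(stack: EnvStack, m: AccessibleArea, n: int, seed) -> pd.DataFrame:
    """n cell-uniform background points from the unmasked cells of M.

    Cells are sampled uniformly with replacement; each point takes its cell's
    environmental vector. Returns an EnvMatrix with lon/lat stored in the
    ``attrs`` for traceability.
    """
    rows, cols = stack.cells_in_area(m)
    if len(rows) == 0:
        raise ValueError(f"M for {m.taxon!r} contains no unmasked cell")
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, len(rows), size=n)
    values = stack.data[:, rows[pick], cols[pick]].T
    matrix = pd.DataFrame(values, columns=stack.variables, index=pd.RangeIndex(n, name="id"))
    lon, lat = stack.cell_lonlat(rows[pick], cols[pick])
    matrix.attrs["lon"] = lon
    matrix.attrs["lat"] = lat
    return matrix


@dataclass
class PcaResult:
    """PCA of an EnvMatrix with per-variable variance attribution.

    ``contribution`` gives each variable's share of each component as a
    percent (squared loading share x 100, summing to 100 per component).
    """

    loadings: pd.DataFrame        # variable x component
    scores: pd.DataFrame          # point x component
    var_explained: np.ndarray     # fraction per component, non-increasing
    contribution: pd.DataFrame    # variable x component, percent

    def to_frame(self) -> pd.DataFrame:
        out = self.contribution.copy()
        out.loc["__var_explained__"] = self.var_explained
        return out


def pca(matrix: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """Centered (and scaled, by default) PCA of an EnvMatrix.

    ENVIREM-style variables carry incommensurate units, so unit-variance
    scaling is the default; a zero-variance variable under scaling is an
    error. Variance attribution per component is the squared loading as a
    share of the component's squared loading norm, in percent.
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("PCA requires at least 2 variables")
    if n < 3:
        raise ValueError("PCA requires at least 3 points")
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        zero = sd <= 0
        if zero.any():
            bad = [v for v, z in zip(matrix.columns, zero) if z]
            raise ValueError(f"zero-variance variables under standardize: {bad}")
        X = X / sd
    # economy SVD: columns of V are the principal axes
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n - 1, p)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    var = S**2 / (n - 1)
    total = X.var(axis=0, ddof=1).sum()
    comp_names = [f"PC{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(Vt.T, index=matrix.columns, columns=comp_names)
    scores = pd.DataFrame(U * S, index=matrix.index, columns=comp_names)
    contrib = pd.DataFrame(
        100.0 * Vt.T**2 / (Vt**2).sum(axis=1), index=matrix.columns, columns=comp_names
    )
    return PcaResult(loadings, scores, var / total, contrib)
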