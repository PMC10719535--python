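"""DEM rasters, triangle surface meshes, slope/aspect, and synthetic surfaces.

Grid convention (fixed for the whole package): metric coordinates, square
cells, row 0 of the elevation array is the northernmost row, and
``(origin_x, origin_y)`` is the lower-left corner of the lower-left cell.
Mesh vertices sit at cell centres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "DEMGrid",
    "TriangleMesh",
    "SlopeAspectGrid",
    "read_dem",
    "write_dem",
    "dem_to_mesh",
    "slope_aspect",
    "synthetic_dem",
    "resample",
]

DEFAULT_NODATA = -9999.0


@dataclass
class DEMGrid:
    """Georeferenced elevation raster with square cells."""

    elevation: np.ndarray  # (n_rows, n_cols), row 0 = north
    origin_x: float
    origin_y: float
    cell_size: float
    nodata: float = DEFAULT_NODATA
    crs_label: str = ""

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.ndim != 2:
            raise ValueError("elevation must be a 2-D array")
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("DEM must be at least 2x2 cells")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.elevation.shape[0]

    @property
    def n_cols(self) -> int:
        return self.elevation.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """True where the cell holds valid data."""
        return self.elevation != self.nodata

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        """Northing of each row (row 0 first, i.e. descending)."""
        return self.origin_y + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cell_size

    def cell_centers(self):
        """Meshgrid (X, Y) of cell-centre coordinates, shape (n_rows, n_cols)."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer grid edge."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)

    def bilinear(self, x, y) -> np.ndarray:
        """Bilinear interpolation of elevation at map coordinates.

        Coordinates outside the cell-centre hull are clamped to the edge
        (constant extrapolation within the outer half-cell rim).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cs = self.cell_size
        fx = np.clip((x - self.origin_x) / cs - 0.5, 0.0, self.n_cols - 1.0)
        # row coordinate grows southward
        fy = np.clip((self.origin_y + self.n_rows * cs - y) / cs - 0.5, 0.0, self.n_rows - 1.0)
        c0 = np.floor(fx).astype(int)
        r0 = np.floor(fy).astype(int)
        c1 = np.minimum(c0 + 1, self.n_cols - 1)
        r1 = np.minimum(r0 + 1, self.n_rows - 1)
        wx = fx - c0
        wy = fy - r0
        z = self.elevation
        return (
            z[r0, c0] * (1 - wx) * (1 - wy)
            + z[r0, c1] * wx * (1 - wy)
            + z[r1, c0] * (1 - wx) * wy
            + z[r1, c1] * wx * wy
        )


@dataclass
class TriangleMesh:
    """Surface triangulation of a DEM: vertices at cell centres, two faces per
    2x2 vertex block split along the fixed SW-NE diagonal."""

    vertices: np.ndarray  # (n, 3)
    faces: np.ndarray  # (m, 3) int indices, CCW seen from above
    cell_of_face: np.ndarray  # (m, 2) (row, col) of the NW cell of the block

    def face_normals(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        n = np.cross(b - a, c - a)
        return n / np.linalg.norm(n, axis=1, keepdims=True)


@dataclass
class SlopeAspectGrid:
    """Per-cell slope (degrees) and downslope aspect (degrees clockwise from
    north); aspect is NaN where the cell is flat or nodata."""

    slope_deg: np.ndarray
    aspect_deg: np.ndarray


# ---------------------------------------------------------------------------
# I/O


def _format_float(v: float) -> str:
    # repr round-trips doubles exactly; integers render without exponent
    return repr(float(v))


def write_dem(grid: DEMGrid, path: str | Path, format: str | None = None) -> None:
    """Write a DEM as ESRI ASCII grid or single-band GeoTIFF.

    The format is inferred from the suffix when not given.  ASCII output
    round-trips bit-exactly (floats are written with ``repr``).
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "esri_ascii":
        lines = [
            f"ncols {grid.n_cols}",
            f"nrows {grid.n_rows}",
            f"xllcorner {_format_float(grid.origin_x)}",
            f"yllcorner {_format_float(grid.origin_y)}",
            f"cellsize {_format_float(grid.cell_size)}",
            f"NODATA_value {_format_float(grid.nodata)}",
        ]
        for row in grid.elevation:
            lines.append(" ".join(_format_float(v) for v in row))
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "geotiff":
        import tifffile

        top_y = grid.origin_y + grid.n_rows * grid.cell_size
        extratags = [
            (33550, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),  # ModelPixelScale
            (33922, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, top_y, 0.0)),  # ModelTiepoint
            (42113, "s", 0, _format_float(grid.nodata)),  # GDAL_NODATA
        ]
        tifffile.imwrite(path, grid.elevation.astype(np.float64), extratags=extratags)
    else:
        raise ValueError(f"unknown DEM format: {fmt!r}")


def read_dem(path: str | Path, format: str | None = None) -> DEMGrid:
    """Read a DEM from ESRI ASCII grid or single-band GeoTIFF."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "esri_ascii":
        return _read_ascii(path)
    if fmt == "geotiff":
        return _read_geotiff(path)
    raise ValueError(f"unknown DEM format: {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".asc", ".txt", ".grd"}:
        return "esri_ascii"
    if suffix in {".tif", ".tiff"}:
        return "geotiff"
    raise ValueError(f"cannot infer DEM format from suffix {suffix!r}")

def _read_ascii(path: Path) -> DEMGrid:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"ESRI ASCII header missing {req!r} in {path}")
    data = np.array(rows, dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.size != nrows * ncols:
        raise ValueError(f"grid body has {data.size} values, header promises {nrows * ncols}")
    return DEMGrid(
        elevation=data.reshape(nrows, ncols),
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata=header.get("nodata_value", DEFAULT_NODATA),
    )


def _read_geotiff(path: Path) -> DEMGrid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        tags = {t.code: t.value for t in page.tags.values()}
    if 33550 not in tags or 33922 not in tags:
        raise ValueError(f"{path} lacks GeoTIFF georeferencing tags")
    sx, sy = float(tags[33550][0]), float(tags[33550][1])
    if not math.isclose(sx, sy, rel_tol=1e-9):
        raise ValueError(f"non-square pixels ({sx} x {sy}) are not supported")
    tie = tags[33922]
    top_x, top_y = float(tie[3]), float(tie[4])
    nodata = float(tags[42113]) if 42113 in tags else DEFAULT_NODATA
    if data.ndim != 2:
        raise ValueError("only single-band rasters are supported")
    return DEMGrid(
        elevation=data,
        origin_x=top_x,
        origin_y=top_y - data.shape[0] * sx,
        cell_size=sx,
        nodata=nodata,
    )


# ---------------------------------------------------------------------------
# Mesh


def dem_to_mesh(grid: DEMGrid) -> TriangleMesh:
    """Triangulate the DEM surface.

    One vertex per cell centre; each 2x2 vertex block is split along the
    SW-NE diagonal into two counter-clockwise triangles (seen from above).
    Blocks touching a nodata cell are dropped; an all-nodata grid is an error.
    """
    if not grid.mask.any():
        raise ValueError("cannot mesh an all-nodata grid")
    X, Y = grid.cell_centers()
    Z = grid.elevation
    nr, nc = grid.n_rows, grid.n_cols
    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    idx = np.arange(nr * nc).reshape(nr, nc)
    nw = idx[:-1, :-1]
    ne = idx[:-1, 1:]
    sw = idx[1:, :-1]
    se = idx[1:, 1:]
    ok = (
        grid.mask[:-1, :-1] & grid.mask[:-1, 1:] & grid.mask[1:, :-1] & grid.mask[1:, 1:]
    ).ravel()
    tri1 = np.column_stack([sw.ravel(), se.ravel(), ne.ravel()])[ok]
    tri2 = np.column_stack([sw.ravel(), ne.ravel(), nw.ravel()])[ok]
    faces = np.empty((2 * tri1.shape[0], 3), dtype=int)
    faces[0::2] = tri1
    faces[1::2] = tri2
    rr, cc = np.meshgrid(np.arange(nr - 1), np.arange(nc - 1), indexing="ij")
    block = np.column_stack([rr.ravel(), cc.ravel()])[ok]
    cell_of_face = np.repeat(block, 2, axis=0)
    if faces.shape[0] == 0:
        raise ValueError("no valid 2x2 block to mesh")
    return TriangleMesh(vertices=vertices, faces=faces, cell_of_face=cell_of_face)


# ---------------------------------------------------------------------------
# Slope / aspect


def slope_aspect(grid: DEMGrid) -> SlopeAspectGrid:
    """Horn 3x3 finite-difference slope and downslope aspect.

    The grid is padded by linear extrapolation so edge cells effectively use
    one-sided differences (exact on planar surfaces everywhere).
    """
    if grid.n_rows < 3 or grid.n_cols < 3:
        raise ValueError("slope_aspect needs at least a 3x3 grid")
    z = np.where(grid.mask, grid.elevation, np.nan)
    zp = np.pad(z, 1, mode="reflect", reflect_type="odd")
    cs = grid.cell_size
    # east derivative: column index grows eastward
    dzdx = (
        (zp[:-2, 2:] + 2 * zp[1:-1, 2:] + zp[2:, 2:])
        - (zp[:-2, :-2] + 2 * zp[1:-1, :-2] + zp[2:, :-2])
    ) / (8.0 * cs)
    # north derivative: row index grows southward, so north is row-1
    dzdy = (
        (zp[:-2, :-2] + 2 * zp[:-2, 1:-1] + zp[:-2, 2:])
        - (zp[2:, :-2] + 2 * zp[2:, 1:-1] + zp[2:, 2:])
    ) / (8.0 * cs)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    with np.errstate(invalid="ignore"):
        aspect = np.mod(np.degrees(np.arctan2(-dzdx, -dzdy)), 360.0)
    aspect = np.where(slope > 0.0, aspect, np.nan)
    return SlopeAspectGrid(slope_deg=slope, aspect_deg=aspect)


def surface_normals(sa: SlopeAspectGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit surface normals (e, n, u components) from slope/aspect.

    The horizontal component of the normal points in the downslope direction.
    Flat or nodata cells get the vertical normal.
    """
    s = np.radians(np.nan_to_num(sa.slope_deg, nan=0.0))
    a = np.radians(np.nan_to_num(sa.aspect_deg, nan=0.0))
    flat = ~(sa.slope_deg > 0) | np.isnan(sa.aspect_deg)
    ne_ = np.where(flat, 0.0, np.sin(s) * np.sin(a))
    nn = np.where(flat, 0.0, np.sin(s) * np.cos(a))
    nu = np.where(flat, 1.0, np.cos(s))
    return ne_, nn, nu


# ---------------------------------------------------------------------------
# Synthetic surfaces


def synthetic_dem(
    kind: str,
    n_rows: int,
    n_cols: int,
    cell_size: float = 1.0,
    origin_x: float = 0.0,
    origin_y: float = 0.0,
    base: float = 0.0,
    grade: float = 0.02,
    downslope_azimuth_deg: float = 270.0,
    amplitude: float = 7.3,
    sigma: float = 60.0,
) -> DEMGrid:
    """Deterministic synthetic DEM fixtures.

    kind ``flat``: constant ``base``.  kind ``plane``: inclined plane with the
    given grade (rise/run) falling toward ``downslope_azimuth_deg``.  kind
    ``gaussian_hill``: ``base`` plus a Gaussian bump of height ``amplitude``
    and width ``sigma`` centred on the grid.
    """
    if n_rows < 2 or n_cols < 2 or cell_size <= 0:
        raise ValueError("grid dimensions and cell size must be positive (>= 2x2)")
    shell = DEMGrid(np.zeros((n_rows, n_cols)), origin_x, origin_y, cell_size)
    X, Y = shell.cell_centers()
    if kind == "flat":
        z = np.full((n_rows, n_cols), float(base))
    elif kind == "plane":
        az = math.radians(downslope_azimuth_deg)
        # elevation rises opposite the downslope direction
        z = base - grade * ((X - X.mean()) * math.sin(az) + (Y - Y.mean()) * math.cos(az))
    elif kind == "gaussian_hill":
        r2 = (X - X.mean()) ** 2 + (Y - Y.mean()) ** 2
        z = base + amplitude * np.exp(-r2 / (2.0 * sigma**2))
    else:
        raise ValueError(f"unknown synthetic DEM kind: {kind!r}")
    return DEMGrid(z, origin_x, origin_y, cell_size, crs_label="synthetic metric")


def resample(grid: DEMGrid, factor: int) -> DEMGrid:
    """Block-mean coarsening by an integer factor (trailing partial blocks dropped).

    Nodata cells poison their block (a block with any nodata becomes nodata).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return replace(grid, elevation=grid.elevation.copy())
    nr = (grid.n_rows // factor) * factor
    nc = (grid.n_cols // factor) * factor
    z = np.where(grid.mask, grid.elevation, np.nan)[:nr, :nc]
    blocks = z.reshape(nr // factor, factor, nc // factor, factor)
    out = blocks.mean(axis=(1, 3))
    out = np.where(np.isnan(out), grid.nodata, out)
    # keep the top-left (north-west) corner anchored
    new_origin_y = grid.origin_y + (grid.n_rows - nr) * grid.cell_size
    return DEMGrid(
        elevation=out,
        origin_x=grid.origin_x,
        origin_y=new_origin_y,
        cell_size=grid.cell_size * factor,
        nodata=grid.nodata,
        crs_label=grid.crs_label,
    )
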