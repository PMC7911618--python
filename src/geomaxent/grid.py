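"""Raster grids and occurrence tables.

Gridded environmental fields are held as :class:`RasterLayer` objects (row 0 =
northernmost row, cell-center registration, geographic degrees) sharing a
:class:`GridSpec`; aligned collections form a :class:`RasterStack`.  Species
presence coordinates are held in an :class:`OccurrenceSet`.

The canonical on-disk format is the ESRI ASCII grid (``.asc``): a 6-line
header (ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed
by row-major values north to south.  Occurrences are CSV in the
samples-with-data dialect: header ``species,longitude,latitude``.

Nodata is represented internally as NaN; a sampled point is invalid if *any*
layer is nodata at its cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "RasterLayer",
    "RasterStack",
    "OccurrenceSet",
    "read_esri_ascii",
    "write_esri_ascii",
    "read_occurrences",
    "write_occurrences",
    "extract_values",
]


class GridParseError(ValueError):
    """Malformed ESRI ASCII grid file."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry shared by all layers of a stack.

    Extent is half-open: ``[x_ll, x_ll + n_cols*cell_size)`` in longitude and
    ``[y_ll, y_ll + n_rows*cell_size)`` in latitude, with square cells of
    ``cell_size`` degrees.
    """

    n_rows: int
    n_cols: int
    x_ll: float
    y_ll: float
    cell_size: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def x_ur(self) -> float:
        return self.x_ll + self.n_cols * self.cell_size

    @property
    def y_ur(self) -> float:
        return self.y_ll + self.n_rows * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        """Cell-center longitudes, west to east (length n_cols)."""
        return self.x_ll + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, north to south (length n_rows, row order)."""
        return self.y_ur - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.x_ll + (col + 0.5) * self.cell_size,
            self.y_ur - (row + 0.5) * self.cell_size,
        )

    def locate(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map points to (row, col); third return flags points inside the extent.

        Cells are half-open; a point on a shared boundary belongs to the cell
        east/south of it, except that the southern/western extent edges are
        included (they are the closed side of the half-open extent).
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        col = np.floor((lon - self.x_ll) / self.cell_size).astype(int)
        # floor puts boundary latitudes into the cell south of the boundary;
        # the southern extent edge (closed side of the half-open extent)
        # belongs to the last row
        row = np.floor((self.y_ur - lat) / self.cell_size).astype(int)
        row[lat == self.y_ll] = self.n_rows - 1
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return row, col, inside


@dataclass
class RasterLayer:
    """One named gridded variable; nodata cells are NaN in ``values``."""

    name: str
    spec: GridSpec
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"!= grid shape {self.spec.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return np.isfinite(self.values)

    def with_values(self, values: np.ndarray, name: str | None = None) -> "RasterLayer":
        return RasterLayer(name or self.name, self.spec, values, self.units)


@dataclass
class RasterStack:
    """Ordered, aligned collection of layers with unique names."""

    layers: list[RasterLayer] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [lay.name for lay in self.layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names: {names}")
        if self.layers:
            spec0 = self.layers[0].spec
            for lay in self.layers[1:]:
                if lay.spec != spec0:
                    raise ValueError(
                        f"layer {lay.name!r} is misaligned with {self.layers[0].name!r}: "
                        f"{lay.spec} != {spec0}"
                    )

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, name: str) -> RasterLayer:
        for lay in self.layers:
            if lay.name == name:
                return lay
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [lay.name for lay in self.layers]

    @property
    def spec(self) -> GridSpec:
        if not self.layers:
            raise ValueError("empty stack has no grid spec")
        return self.layers[0].spec

    def array(self) -> np.ndarray:
        """(n_layers, n_rows, n_cols) array."""
        return np.stack([lay.values for lay in self.layers])

    def valid_mask(self) -> np.ndarray:
        """True where every layer holds data."""
        m = np.ones(self.spec.shape, dtype=bool)
        for lay in self.layers:
            m &= lay.mask
        return m

    def subset(self, names: list[str]) -> "RasterStack":
        return RasterStack([self[n] for n in names])

    def cell_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flatten valid cells to a sample matrix.

        Returns (X, rows, cols) where X is (n_valid, n_layers).
        """
        m = self.valid_mask()
        rows, cols = np.nonzero(m)
        X = np.column_stack([lay.values[rows, cols] for lay in self.layers])
        return X, rows, cols


@dataclass
class OccurrenceSet:
    """Presence coordinates for one species."""

    species: str
    points: np.ndarray  # (n, 2) columns lon, lat

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 2)
        if self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2) lon/lat pairs")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("occurrence coordinates must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def lon(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def lat(self) -> np.ndarray:
        return self.points[:, 1]

    def take(self, idx: np.ndarray) -> "OccurrenceSet":
        return OccurrenceSet(self.species, self.points[np.asarray(idx)])


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_esri_ascii(path, name: str | None = None, units: str = "") -> RasterLayer:
    """Read an ESRI ASCII grid file into a :class:`RasterLayer`.

    The layer name defaults to the file stem.  Cells equal to the header's
    NODATA_value become NaN.
    """
    import os

    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    for i in range(6):
        if i >= len(lines):
            raise GridParseError(f"{path}: truncated header at line {i + 1}")
        parts = lines[i].split()
        if len(parts) != 2:
            raise GridParseError(f"{path}: malformed header line {i + 1}: {lines[i]!r}")
        key = parts[0].lower()
        if key != _HEADER_KEYS[i]:
            raise GridParseError(
                f"{path}: header line {i + 1} expected {_HEADER_KEYS[i]!r}, got {parts[0]!r}"
            )
        try:
            header[key] = float(parts[1])
        except ValueError as exc:
            raise GridParseError(f"{path}: non-numeric header value on line {i + 1}") from exc

    spec = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        x_ll=header["xllcorner"],
        y_ll=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata=header["nodata_value"],
    )
    body = "\n".join(lines[6:])
    try:
        flat = np.array(body.split(), dtype=float)
    except ValueError as exc:
        raise GridParseError(f"{path}: non-numeric cell value in body") from exc
    if flat.size != spec.n_rows * spec.n_cols:
        raise GridParseError(
            f"{path}: expected {spec.n_rows}x{spec.n_cols}={spec.n_rows * spec.n_cols} "
            f"values, found {flat.size}"
        )
    values = flat.reshape(spec.n_rows, spec.n_cols)
    values[values == spec.nodata] = np.nan
    if name is None:
        name = os.path.splitext(os.path.basename(str(path)))[0]
    return RasterLayer(name=name, spec=spec, values=values, units=units)


def write_esri_ascii(layer: RasterLayer, path) -> None:
    """Write a layer as an ESRI ASCII grid; NaN cells become the nodata sentinel.

    Values and header are printed with round-trip precision so that
    write -> read reproduces the layer exactly.
    """
    spec = layer.spec
    out = np.where(np.isfinite(layer.values), layer.values, spec.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.x_ll:.17g}\n")
        fh.write(f"yllcorner {spec.y_ll:.17g}\n")
        fh.write(f"cellsize {spec.cell_size:.17g}\n")
        fh.write(f"NODATA_value {spec.nodata:.17g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.17g}" for v in row))
            fh.write("\n")


def read_stack(paths, names=None) -> RasterStack:
    """Read several .asc files into an aligned stack."""
    layers = []
    for i, p in enumerate(paths):
        nm = None if names is None else names[i]
        layers.append(read_esri_ascii(p, name=nm))
    return RasterStack(layers)


# ---------------------------------------------------------------------------
# Occurrence I/O

def read_occurrences(path, species: str | None = None) -> OccurrenceSet:
    """Read a samples-with-data CSV (columns species, longitude, latitude).

    Column order is irrelevant and extra columns are ignored; column names are
    matched case-insensitively.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("longitude", "latitude") if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    lon = pd.to_numeric(df[cols["longitude"]], errors="raise")
    lat = pd.to_numeric(df[cols["latitude"]], errors="raise")
    if species is None:
        species = str(df[cols["species"]].iloc[0]) if "species" in cols and len(df) else "species"
    return OccurrenceSet(species=species, points=np.column_stack([lon, lat]))


def write_occurrences(occ: OccurrenceSet, path) -> None:
    pd.DataFrame(
        {"species": occ.species, "longitude": occ.lon, "latitude": occ.lat}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Point extraction

def extract_values(stack: RasterStack, points) -> tuple[np.ndarray, np.ndarray]:
    """Sample every stack layer at each point.

    Returns ``(X, valid)`` where X is (n_points, n_layers) and ``valid`` is
    False for points outside the extent or on a cell where any layer is
    nodata (invalid rows hold NaN).
    """
    if len(stack) == 0:
        raise ValueError("cannot extract from an empty stack")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    row, col, inside = stack.spec.locate(pts[:, 0], pts[:, 1])
    X = np.full((pts.shape[0], len(stack)), np.nan)
    r = row[inside]
    c = col[inside]
    for j, lay in enumerate(stack.layers):
        X[inside, j] = lay.values[r, c]
    valid = inside & np.all(np.isfinite(X), axis=1)
    return X, valid
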