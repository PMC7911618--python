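"""Reporting layer: suitability classes, areas, range change, centroids, MESS.

Suitability maps are cut into four habitat classes (unsuitable < 0.1,
0.1 <= poorly < 0.3, 0.3 <= moderately < 0.6, highly >= 0.6); class areas are
summed from spherical cell areas and reported in 1e4 km^2.  Binary maps of
two periods are compared cell-wise into gain / loss / unchanged masks, the
suitable range's area-weighted centroid is tracked between periods, and the
multivariate environmental similarity surface (MESS) flags cells of a
projection stack whose climate falls outside (negative S) or near the edge
of the reference sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec, RasterLayer, RasterStack
from .model import SuitabilityMap

__all__ = [
    "EARTH_RADIUS_KM",
    "DEFAULT_THRESHOLDS",
    "ClassifiedMap",
    "AreaSummary",
    "RangeChange",
    "CentroidShift",
    "MESSMap",
    "classify",
    "cell_area_km2",
    "area_summary",
    "percent_change",
    "binarize",
    "range_change",
    "centroid",
    "centroid_shift",
    "haversine_km",
    "mess",
    "mean_mess_at_points",
]

EARTH_RADIUS_KM = 6371.0
DEFAULT_THRESHOLDS = (0.1, 0.3, 0.6)
CLASS_NAMES = {0: "unsuitable", 1: "poorly", 2: "moderately", 3: "highly"}


@dataclass
class ClassifiedMap:
    """Raster of habitat class codes 0-3 (NaN on nodata)."""

    layer: RasterLayer
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
    label: str = ""


@dataclass
class AreaSummary:
    """Per-class suitable area in 1e4 km^2 for one period/scenario."""

    label: str
    highly: float
    moderately: float
    poorly: float

    @property
    def total(self) -> float:
        return self.highly + self.moderately + self.poorly

    def as_row(self, decimals: int = 2) -> dict:
        return {
            "period": self.label,
            "highly": round(self.highly, decimals),
            "moderately": round(self.moderately, decimals),
            "poorly": round(self.poorly, decimals),
            "total": round(self.total, decimals),
        }

    def class_shares(self, decimals: int = 2) -> dict:
        """Each class's share of the total suitable area, in percent."""
        if self.total <= 0:
            return {"highly": 0.0, "moderately": 0.0, "poorly": 0.0}
        return {
            k: round(100.0 * v / self.total, decimals)
            for k, v in (("highly", self.highly), ("moderately", self.moderately), ("poorly", self.poorly))
        }

    def share_of_region(self, region_area_1e4km2: float, decimals: int = 2) -> float:
        """Total suitable area as a percent of a reference region's area."""
        return round(100.0 * self.total / region_area_1e4km2, decimals)


@dataclass
class RangeChange:
    """Cell-wise gain/loss/unchanged between two binary suitability maps."""

    gain_area: float  # 1e4 km^2
    loss_area: float
    unchanged_area: float
    gain_mask: np.ndarray = field(repr=False, default=None)
    loss_mask: np.ndarray = field(repr=False, default=None)
    unchanged_mask: np.ndarray = field(repr=False, default=None)

    @property
    def current_area(self) -> float:
        return self.unchanged_area + self.loss_area

    @property
    def future_area(self) -> float:
        return self.unchanged_area + self.gain_area


@dataclass
class CentroidShift:
    lon_from: float
    lat_from: float
    lon_to: float
    lat_to: float

    @property
    def delta_lat(self) -> float:
        return self.lat_to - self.lat_from

    @property
    def distance_km(self) -> float:
        return haversine_km(self.lon_from, self.lat_from, self.lon_to, self.lat_to)


@dataclass
class MESSMap:
    """Per-cell minimum similarity S and the most dissimilar variable."""

    similarity: RasterLayer
    most_dissimilar: np.ndarray  # object array of variable names (None on nodata)


# ---------------------------------------------------------------------------
# Classification and areas

def classify(
    suitability: SuitabilityMap | RasterLayer,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    label: str = "",
) -> ClassifiedMap:
    """Cut a [0,1] suitability raster into classes 0-3 (lower-closed bins)."""
    layer = suitability.layer if isinstance(suitability, SuitabilityMap) else suitability
    t1, t2, t3 = thresholds
    if not (0 <= t1 < t2 < t3 <= 1):
        raise ValueError("thresholds must satisfy 0 <= t1 < t2 < t3 <= 1")
    v = layer.values
    finite = np.isfinite(v)
    if finite.any() and (np.nanmin(v) < 0 or np.nanmax(v) > 1):
        raise ValueError("suitability values must lie in [0, 1]")
    cls = np.full(v.shape, np.nan)
    cls[finite] = (
        (v[finite] >= t1).astype(float)
        + (v[finite] >= t2)
        + (v[finite] >= t3)
    )
    return ClassifiedMap(
        layer=layer.with_values(cls, name="habitat_class"), thresholds=thresholds, label=label
    )


def cell_area_km2(spec: GridSpec, row: int | np.ndarray) -> np.ndarray | float:
    """Spherical area of the cell(s) in grid row(s): R^2 * dlam * (sin top - sin bot)."""
    lat_top = spec.y_ur - np.asarray(row) * spec.cell_size
    lat_bot = lat_top - spec.cell_size
    dlam = np.deg2rad(spec.cell_size)
    area = (
        EARTH_RADIUS_KM**2
        * dlam
        * (np.sin(np.deg2rad(lat_top)) - np.sin(np.deg2rad(lat_bot)))
    )
    return area


def _row_areas(spec: GridSpec) -> np.ndarray:
    return np.asarray(cell_area_km2(spec, np.arange(spec.n_rows)), dtype=float)


def _mask_area_1e4km2(mask: np.ndarray, spec: GridSpec) -> float:
    per_row = _row_areas(spec)
    return float((mask.sum(axis=1) * per_row).sum() / 1e4)


def area_summary(classified: ClassifiedMap, label: str | None = None) -> AreaSummary:
    """Sum spherical cell areas per suitable class, in 1e4 km^2."""
    cls = classified.layer.values
    spec = classified.layer.spec
    areas = {
        code: _mask_area_1e4km2(cls == code, spec) for code in (1, 2, 3)
    }
    return AreaSummary(
        label=label if label is not None else classified.label,
        highly=areas[3],
        moderately=areas[2],
        poorly=areas[1],
    )


def percent_change(current: AreaSummary, future: AreaSummary, decimals: int = 2) -> pd.DataFrame:
    """Per-class and total change: absolute, percent, and fold.

    percent = 100*(future-current)/current; fold = (future-current)/current,
    conventionally quoted as "x times" when >= 1.  Classes with zero current
    area report only the absolute change (percent/fold are NaN).
    """
    rows = []
    pairs = [
        ("highly", current.highly, future.highly),
        ("moderately", current.moderately, future.moderately),
        ("poorly", current.poorly, future.poorly),
        ("total", current.total, future.total),
    ]
    for name, cur, fut in pairs:
        absolute = round(fut - cur, decimals)
        if cur > 0:
            ratio = (fut - cur) / cur
            pct = round(100.0 * ratio, decimals)
            fold = round(ratio, decimals)
        else:
            pct = np.nan
            fold = np.nan
        rows.append(
            {
                "class": name,
                "current": cur,
                "future": fut,
                "absolute_change": absolute,
                "percent_change": pct,
                "fold_change": fold,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Binary range change

def binarize(classified: ClassifiedMap, min_class: int = 1) -> np.ndarray:
    """Boolean suitable/unsuitable mask: True where class >= min_class."""
    cls = classified.layer.values
    return np.isfinite(cls) & (cls >= min_class)


def range_change(current_mask: np.ndarray, future_mask: np.ndarray, spec: GridSpec) -> RangeChange:
    """Gain/loss/unchanged masks and areas between two aligned binary maps."""
    cur = np.asarray(current_mask, dtype=bool)
    fut = np.asarray(future_mask, dtype=bool)
    if cur.shape != fut.shape or cur.shape != spec.shape:
        raise ValueError("masks must share the grid's shape")
    gain = fut & ~cur
    loss = cur & ~fut
    unchanged = cur & fut
    return RangeChange(
        gain_area=_mask_area_1e4km2(gain, spec),
        loss_area=_mask_area_1e4km2(loss, spec),
        unchanged_area=_mask_area_1e4km2(unchanged, spec),
        gain_mask=gain,
        loss_mask=loss,
        unchanged_mask=unchanged,
    )


# ---------------------------------------------------------------------------
# Centroids

def haversine_km(lon1, lat1, lon2, lat2) -> float:
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dp = p2 - p1
    dl = np.deg2rad(lon2) - np.deg2rad(lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def centroid(mask: np.ndarray, spec: GridSpec) -> tuple[float, float]:
    """Area-weighted mean cell-center coordinate of a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot take the centroid of an empty mask")
    rows, cols = np.nonzero(mask)
    w = np.asarray(cell_area_km2(spec, rows), dtype=float)
    lon = spec.x_ll + (cols + 0.5) * spec.cell_size
    lat = spec.y_ur - (rows + 0.5) * spec.cell_size
    return float(np.average(lon, weights=w)), float(np.average(lat, weights=w))


def centroid_shift(c_from: tuple[float, float], c_to: tuple[float, float]) -> CentroidShift:
    return CentroidShift(c_from[0], c_from[1], c_to[0], c_to[1])


# ---------------------------------------------------------------------------
# MESS

def _mess_variable(ref: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Similarity of values v to the reference sample of one variable.

    f = percent of reference values strictly below v;
    S = 100*(v-min)/(max-min) if f = 0; 2f if f <= 50; 2(100-f) if f < 100;
    100*(max-v)/(max-min) if f = 100.
    """
    ref = np.sort(np.asarray(ref, dtype=float))
    rmin, rmax = ref[0], ref[-1]
    if not rmax > rmin:
        raise ValueError("reference variable is constant; MESS is undefined")
    n = ref.size
    f = 100.0 * np.searchsorted(ref, v, side="left") / n
    span = rmax - rmin
    s = np.where(
        f == 0.0,
        100.0 * (v - rmin) / span,
        np.where(
            f <= 50.0,
            2.0 * f,
            np.where(f < 100.0, 2.0 * (100.0 - f), 100.0 * (rmax - v) / span),
        ),
    )
    return s


def mess(reference: dict[str, np.ndarray] | pd.DataFrame, stack: RasterStack) -> MESSMap:
    """Multivariate environmental similarity of a projection stack to a reference sample.

    ``reference`` maps variable names (a subset of the stack's layers) to 1-D
    reference samples — typically the training-period values at the presence
    points or background cells.  The cell similarity is the minimum over
    variables; negative S means at least one variable is outside its
    reference range (extrapolation).
    """
    if isinstance(reference, pd.DataFrame):
        reference = {c: reference[c].to_numpy() for c in reference.columns}
    names = list(reference)
    if not names:
        raise ValueError("reference sample has no variables")
    for nm, ref in reference.items():
        if np.asarray(ref).size < 2:
            raise ValueError(f"reference for {nm!r} needs at least 2 values")
    sub = stack.subset(names)
    X, rows, cols = sub.cell_table()
    per_var = np.column_stack(
        [_mess_variable(np.asarray(reference[nm], dtype=float), X[:, j]) for j, nm in enumerate(names)]
    )
    jmin = np.argmin(per_var, axis=1)
    s = per_var[np.arange(per_var.shape[0]), jmin]
    vals = np.full(sub.spec.shape, np.nan)
    vals[rows, cols] = s
    most = np.full(sub.spec.shape, None, dtype=object)
    most[rows, cols] = np.array(names, dtype=object)[jmin]
    return MESSMap(
        similarity=RasterLayer(name="mess_similarity", spec=sub.spec, values=vals),
        most_dissimilar=most,
    )


def mean_mess_at_points(messmap: MESSMap, points: np.ndarray) -> float:
    """Arithmetic mean similarity at the cells containing the given points."""
    layer = messmap.similarity
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    row, col, inside = layer.spec.locate(pts[:, 0], pts[:, 1])
    vals = np.full(pts.shape[0], np.nan)
    vals[inside] = layer.values[row[inside], col[inside]]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no point falls on a valid cell")
    return float(vals.mean())
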