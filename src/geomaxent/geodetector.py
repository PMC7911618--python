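"""Factor detector for spatial stratified heterogeneity (the geodetector q-statistic).

The factor detector asks how much of the spatial variance of a response *y*
is explained by stratifying the study area on an explanatory variable *x*:

    q = 1 - SSW / SST,   SSW = sum_h N_h * sigma_h^2,   SST = N * sigma^2

where h = 1..L indexes the strata of x, N_h and sigma_h^2 are the stratum
sample count and (population) variance, and N, sigma^2 the overall ones.
q lies in [0, 1]: q = 1 when y is constant within every stratum, q = 0 when
the stratification explains nothing.

Strata are formed by Jenks natural breaks (Fisher's optimal contiguous
partition of the sorted values, minimising within-class squared deviation).
The response is presence/absence of the species on a regular fishnet of
sampling points laid over the study area; significance is assessed by a
permutation test.  Variables whose q exceeds a threshold (default 0.1,
strict) are retained for the suitability model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec, OccurrenceSet, RasterStack, extract_values

__all__ = [
    "KM_PER_DEGREE",
    "StrataMap",
    "FactorDetectionResult",
    "jenks_breaks",
    "stratify",
    "factor_q",
    "q_significance",
    "build_fishnet",
    "presence_response",
    "screen_variables",
]

#: Kilometres per degree of latitude (and of longitude at the equator).
KM_PER_DEGREE = 111.32


class DegenerateVarianceError(ValueError):
    """Raised when the response is constant (SST = 0), so q is undefined."""


@dataclass
class StrataMap:
    """Assignment of samples to ordered strata of one variable."""

    variable: str
    breaks: np.ndarray  # L-1 ascending cut values
    assignment: np.ndarray  # stratum index h in {1..L} per sample

    def __post_init__(self) -> None:
        self.breaks = np.asarray(self.breaks, dtype=float)
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.breaks.size > 1 and not np.all(np.diff(self.breaks) > 0):
            raise ValueError("breaks must be strictly ascending")

    @property
    def L(self) -> int:
        return len(self.breaks) + 1


@dataclass
class FactorDetectionResult:
    """q-statistic and its variance decomposition for one variable."""

    variable: str
    q: float
    N: int
    n_h: np.ndarray
    var_h: np.ndarray
    var_total: float
    ssw: float
    sst: float
    p_value: float | None = None

    def __repr__(self) -> str:  # compact: the q table is the usual view
        p = "n/a" if self.p_value is None else f"{self.p_value:.4g}"
        return (
            f"FactorDetectionResult({self.variable!r}, q={self.q:.4f}, "
            f"p={p}, N={self.N}, L={len(self.n_h)})"
        )


# ---------------------------------------------------------------------------
# Jenks natural breaks (Fisher optimal partition)

def _class_cost(s1: np.ndarray, s2: np.ndarray, sw: np.ndarray, i: np.ndarray, j: int):
    """Weighted within-class sum of squares of unique values i..j (inclusive)."""
    w = sw[j + 1] - sw[i]
    t1 = s1[j + 1] - s1[i]
    t2 = s2[j + 1] - s2[i]
    return t2 - t1 * t1 / w


def jenks_breaks(values, L: int) -> np.ndarray:
    """Optimal natural-breaks cut values for L classes.

    Runs Fisher's dynamic program on the distinct sorted values (weighted by
    multiplicity), so tied values always land in the same class.  Returns
    L-1 ascending break values, each equal to the minimum value of one of
    classes 2..L (class lower bounds); :func:`stratify`'s lower-closed
    semantics then reproduce the optimal classes exactly.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if L < 1:
        raise ValueError("L must be >= 1")
    uniq, counts = np.unique(vals, return_counts=True)
    n = uniq.size
    if n < L:
        raise ValueError(f"need at least L={L} distinct finite values, got {n}")
    if L == 1:
        return np.empty(0)

    w = counts.astype(float)
    sw = np.concatenate([[0.0], np.cumsum(w)])
    s1 = np.concatenate([[0.0], np.cumsum(w * uniq)])
    s2 = np.concatenate([[0.0], np.cumsum(w * uniq * uniq)])

    # D[l, j]: cost of optimally splitting uniq[0..j] into l+1 classes
    D = np.empty((L, n))
    back = np.zeros((L, n), dtype=int)
    idx_all = np.arange(n)
    D[0] = [_class_cost(s1, s2, sw, np.array([0]), j)[0] for j in range(n)]
    for l in range(1, L):
        D[l, :l] = np.inf
        for j in range(l, n):
            i = idx_all[l : j + 1]  # first index of the last class
            cand = D[l - 1, i - 1] + _class_cost(s1, s2, sw, i, j)
            k = int(np.argmin(cand))
            D[l, j] = cand[k]
            back[l, j] = i[k]

    # backtrack class boundaries
    breaks = []
    j = n - 1
    for l in range(L - 1, 0, -1):
        i = back[l, j]
        breaks.append(uniq[i])  # minimum value of the last class
        j = i - 1
    return np.array(breaks[::-1])


def stratify(values, breaks, variable: str = "") -> StrataMap:
    """Assign each value to stratum ``1 + #{breaks <= v}``.

    Classes are lower-closed, upper-open: a value equal to a break belongs
    to the class the break opens.
    """
    vals = np.asarray(values, dtype=float)
    br = np.asarray(breaks, dtype=float)
    assignment = 1 + np.searchsorted(br, vals, side="right")
    return StrataMap(variable=variable, breaks=br, assignment=assignment)


# ---------------------------------------------------------------------------
# The q statistic

def _ssw_sst(y: np.ndarray, h: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Within/total sums of squares with population (divisor-N) variances."""
    labels, inv = np.unique(h, return_inverse=True)
    n_h = np.bincount(inv).astype(float)
    sum_h = np.bincount(inv, weights=y)
    sumsq_h = np.bincount(inv, weights=y * y)
    var_h = sumsq_h / n_h - (sum_h / n_h) ** 2
    var_h = np.maximum(var_h, 0.0)
    ssw = float(np.sum(n_h * var_h))
    sst = float(y.size * np.var(y))
    return ssw, sst, n_h, var_h


def factor_q(y, strata: StrataMap | np.ndarray, variable: str | None = None) -> FactorDetectionResult:
    """Compute q = 1 - SSW/SST for a response over a stratification.

    Uses population variances (divisor N), so q is exactly 1 when every
    stratum is internally constant.  Raises
    :class:`DegenerateVarianceError` when y is constant (SST = 0).
    """
    y = np.asarray(y, dtype=float)
    if isinstance(strata, StrataMap):
        h = strata.assignment
        var_name = variable if variable is not None else strata.variable
    else:
        h = np.asarray(strata)
        var_name = variable or ""
    if y.shape != h.shape:
        raise ValueError("y and strata must have the same length")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    ssw, sst, n_h, var_h = _ssw_sst(y, h)
    if sst <= 0:
        raise DegenerateVarianceError("response variance is zero; q is undefined")
    q = 1.0 - ssw / sst
    q = float(min(max(q, 0.0), 1.0))
    return FactorDetectionResult(
        variable=var_name,
        q=q,
        N=y.size,
        n_h=n_h,
        var_h=var_h,
        var_total=sst / y.size,
        ssw=ssw,
        sst=sst,
    )


def q_significance(y, strata: StrataMap | np.ndarray, n_permutations: int = 999, seed=None) -> float:
    """Permutation p-value for the observed q.

    Permutes y against the stratum labels; p = (1 + #{q_perm >= q_obs}) /
    (n_permutations + 1).  Invariant to any relabelling of strata.
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    y = np.asarray(y, dtype=float)
    h = strata.assignment if isinstance(strata, StrataMap) else np.asarray(strata)
    obs = factor_q(y, h).q
    rng = np.random.default_rng(seed)

    # q comparison only needs SSW (SST is permutation-invariant)
    labels, inv = np.unique(h, return_inverse=True)
    n_h = np.bincount(inv).astype(float)
    sst = y.size * np.var(y)
    count = 0
    for _ in range(n_permutations):
        yp = rng.permutation(y)
        sum_h = np.bincount(inv, weights=yp)
        sumsq_h = np.bincount(inv, weights=yp * yp)
        ssw = np.sum(sumsq_h - sum_h**2 / n_h)
        qp = 1.0 - ssw / sst
        if qp >= obs - 1e-12:
            count += 1
    return (1 + count) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# Fishnet sampling

def _fishnet_steps(spec: GridSpec, spacing_km: float) -> tuple[float, float]:
    """Lattice steps in degrees for a spacing in km, at the grid's mean latitude."""
    mean_lat = 0.5 * (spec.y_ll + spec.y_ur)
    dlat = spacing_km / KM_PER_DEGREE
    dlon = spacing_km / (KM_PER_DEGREE * np.cos(np.deg2rad(mean_lat)))
    return dlon, dlat


def build_fishnet(spec: GridSpec, spacing_km: float, valid_mask: np.ndarray | None = None) -> np.ndarray:
    """Regular lattice of sampling points at the given spacing, clipped to valid cells.

    Points are cell-centred in lattice cells of side ``spacing_km``
    (converted to degrees with 111.32 km/deg, longitude scaled by the cosine
    of the grid's mean latitude).  Returns an (n, 2) lon/lat array.
    """
    if spacing_km <= 0:
        raise ValueError("spacing_km must be positive")
    dlon, dlat = _fishnet_steps(spec, spacing_km)
    width = spec.n_cols * spec.cell_size
    height = spec.n_rows * spec.cell_size
    nx = int(width / dlon + 1e-9)
    ny = int(height / dlat + 1e-9)
    if nx < 1 or ny < 1:
        raise ValueError("fishnet spacing exceeds the grid extent (no points)")
    lon = spec.x_ll + (np.arange(nx) + 0.5) * dlon
    lat = spec.y_ll + (np.arange(ny) + 0.5) * dlat
    gl, gt = np.meshgrid(lon, lat)
    pts = np.column_stack([gl.ravel(), gt.ravel()])
    if valid_mask is not None:
        row, col, inside = spec.locate(pts[:, 0], pts[:, 1])
        keep = inside.copy()
        keep[inside] = valid_mask[row[inside], col[inside]]
        pts = pts[keep]
    return pts


def presence_response(
    fishnet_points: np.ndarray,
    occurrences: OccurrenceSet,
    spec: GridSpec,
    spacing_km: float,
    counts: bool = False,
) -> np.ndarray:
    """Binary response: 1 where at least one occurrence falls in a fishnet cell.

    A fishnet cell is the half-open square of side ``spacing_km`` centred on
    the point.  With ``counts=True`` the occurrence count per cell is
    returned instead.
    """
    pts = np.atleast_2d(np.asarray(fishnet_points, dtype=float))
    y = np.zeros(pts.shape[0], dtype=float)
    if len(occurrences) == 0:
        return y
    dlon, dlat = _fishnet_steps(spec, spacing_km)
    for j in range(pts.shape[0]):
        dx = occurrences.lon - pts[j, 0]
        dy = occurrences.lat - pts[j, 1]
        hit = (dx >= -dlon / 2) & (dx < dlon / 2) & (dy >= -dlat / 2) & (dy < dlat / 2)
        y[j] = hit.sum() if counts else float(hit.any())
    return y


# ---------------------------------------------------------------------------
# Variable screening

def screen_variables(
    stack: RasterStack,
    occurrences: OccurrenceSet,
    L: int = 5,
    q_threshold: float = 0.1,
    spacing_km: float = 10.0,
    n_permutations: int = 999,
    seed=None,
) -> tuple[list[str], pd.DataFrame]:
    """Factor-detector screening of every stack variable.

    Lays a fishnet over the valid cells, builds the binary presence response,
    stratifies each variable into L natural-breaks classes and computes q and
    its permutation p-value.  Variables with q strictly greater than
    ``q_threshold`` are retained.

    Returns ``(selected_names, table)``; the table has one row per variable
    with columns variable, q, p_value, L, retained.
    """
    if len(stack) < 1:
        raise ValueError("stack has no variables")
    pts = build_fishnet(stack.spec, spacing_km, valid_mask=stack.valid_mask())
    y = presence_response(pts, occurrences, stack.spec, spacing_km)
    X, valid = extract_values(stack, pts)
    y = y[valid]
    X = X[valid]
    rng = np.random.default_rng(seed)
    rows = []
    for j, name in enumerate(stack.names):
        breaks = jenks_breaks(X[:, j], L)
        sm = stratify(X[:, j], breaks, variable=name)
        res = factor_q(y, sm)
        if n_permutations:  # 0 skips the permutation test (p_value = NaN)
            res.p_value = q_significance(
                y, sm, n_permutations=n_permutations, seed=rng.integers(2**31 - 1)
            )
        else:
            res.p_value = np.nan
        rows.append(
            {
                "variable": name,
                "q": res.q,
                "p_value": res.p_value,
                "L": sm.L,
                "retained": res.q > q_threshold,
            }
        )
    table = pd.DataFrame(rows)
    selected = table.loc[table["retained"], "variable"].tolist()
    if not selected:
        import warnings

        warnings.warn("no variable exceeded the q threshold; selection is empty")
    return selected, table
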