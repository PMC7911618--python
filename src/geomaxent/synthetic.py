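"""Virtual-species test bed: synthetic rasters, known truth, sampled occurrences.

The generator emulates the ingredients of a climate-envelope study without
any download: spatially autocorrelated environmental fields (kernel-smoothed
white noise, temperature-like layers carrying a latitudinal gradient), a
known log-linear/quadratic suitability surface over a subset of "signal"
variables (the remaining "noise" layers get zero weight), occurrence points
drawn without replacement with probability proportional to true suitability,
and "future" stacks built by an additive warming shift on temperature layers
and a multiplicative factor on precipitation layers.

Everything is deterministic under the scenario seed.  Layer roles are
carried by name prefix: ``temp*`` (gradient + warming), ``precip*``
(precipitation factor), ``noise*`` (no role in the truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grid import GridSpec, OccurrenceSet, RasterLayer, RasterStack

__all__ = [
    "SyntheticScenario",
    "default_scenario",
    "make_environment",
    "make_true_suitability",
    "sample_occurrences",
    "make_future_environment",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Full description of one simulated study; the seed fixes every output.

    ``true_coefficients`` maps a variable name to ``(beta, gamma)`` — its
    linear and quadratic weight in the log-suitability.  Variables absent
    from the mapping are noise.  Fields are standardized, so coefficients
    are per standard deviation and ``warming_offset`` is in field standard
    deviations (a degree-like unit for the standardized temperature layers).
    """

    spec: GridSpec
    signal_vars: tuple[str, ...]
    noise_vars: tuple[str, ...]
    true_coefficients: dict = field(default_factory=dict)
    intercept: float = 0.0
    link: str = "logistic"
    n_presences: int = 200
    warming_offset: float = 0.5
    precip_factor: float = 0.9
    smoothing_sigma: float = 3.0
    gradient_weight: float = 1.0
    precip_gradient_weight: float = 0.7
    latent_loading: float = 0.85
    noise_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.signal_vars:
            raise ValueError("need at least one signal variable")
        if self.n_presences < 1:
            raise ValueError("n_presences must be positive")
        if self.link not in ("logistic", "cloglog"):
            raise ValueError(f"unknown link {self.link!r}")

    @property
    def var_names(self) -> tuple[str, ...]:
        return self.signal_vars + self.noise_vars


def default_scenario(seed: int = 0, **overrides) -> SyntheticScenario:
    """The standard test scenario: 60x80 grid, 4 signal + 3 noise variables,
    200 presences, logistic truth quadratic in temp1 (interior optimum)."""
    base = dict(
        spec=GridSpec(n_rows=60, n_cols=80, x_ll=100.0, y_ll=20.0, cell_size=0.05),
        signal_vars=("temp1", "temp2", "precip1", "precip2"),
        noise_vars=("noise1", "noise2", "noise3"),
        true_coefficients={
            "temp1": (6.0, -8.0),  # band niche, optimum at -beta/(2*gamma) = 0.375 sd
            "temp2": (5.0, 0.0),
            "precip1": (4.0, 0.0),
            "precip2": (-4.0, 0.0),
        },
        intercept=-7.0,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticScenario(**base)


# ---------------------------------------------------------------------------

def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Standardized white noise convolved with an isotropic Gaussian kernel."""
    z = rng.standard_normal(shape)
    if sigma > 0:
        z = gaussian_filter(z, sigma, mode="reflect")
    return _standardize(z)


def make_environment(scenario: SyntheticScenario) -> RasterStack:
    """Generate the environmental stack for a scenario.

    Two latent climate axes organise the signal variables, mimicking the
    strong mutual correlation of real bioclim covariates: a temperature axis
    T = gradient + smoothed noise (poleward = colder) and a precipitation
    axis P = ``precip_gradient_weight`` * gradient + smoothed noise (the
    warm south is also the wet south).  Each ``temp*`` layer loads on T and
    each ``precip*`` layer on P with loading ``latent_loading`` (the last
    precip layer with negative sign, emulating wet-season/dry-season
    anticorrelation), plus an idiosyncratic smoothed-noise component of
    complementary variance; ``noise*`` layers are independent smoothed
    fields.  All layers are standardized to mean 0, sd 1 and the whole stack
    is deterministic under the scenario seed.
    """
    spec = scenario.spec
    if spec.n_rows < 2 or spec.n_cols < 2:
        raise ValueError("grid must be at least 2x2")
    rng = np.random.default_rng(scenario.seed)
    lat = spec.lat_centers()  # north to south
    grad = _standardize(-lat)[:, None] * np.ones((1, spec.n_cols))  # colder poleward
    sigma = scenario.smoothing_sigma
    nw = scenario.noise_weight

    def std_or_raise(field_, name):
        sd = field_.std()
        if sd == 0:
            raise ValueError(f"layer/axis {name!r} is degenerate (zero variance)")
        return (field_ - field_.mean()) / sd

    axis_t = std_or_raise(
        scenario.gradient_weight * grad + nw * _smooth_field(rng, spec.shape, sigma),
        "temperature axis",
    )
    axis_p = std_or_raise(
        scenario.precip_gradient_weight * grad + nw * _smooth_field(rng, spec.shape, sigma),
        "precipitation axis",
    )
    rho = scenario.latent_loading
    precip_names = [n for n in scenario.var_names if n.startswith("precip")]
    layers = []
    for name in scenario.var_names:
        own = nw * _smooth_field(rng, spec.shape, sigma)
        if name.startswith("temp"):
            field_ = rho * axis_t + np.sqrt(max(1 - rho * rho, 0.0)) * own
        elif name.startswith("precip"):
            sign = -1.0 if (precip_names and name == precip_names[-1]) else 1.0
            field_ = sign * rho * axis_p + np.sqrt(max(1 - rho * rho, 0.0)) * own
        else:
            field_ = own
        layers.append(RasterLayer(name=name, spec=spec, values=std_or_raise(field_, name)))
    return RasterStack(layers)


def make_true_suitability(stack: RasterStack, scenario: SyntheticScenario) -> RasterLayer:
    """True suitability = link(intercept + sum beta_i x_i + sum gamma_i x_i^2)."""
    eta = np.full(stack.spec.shape, scenario.intercept, dtype=float)
    for name, (beta, gamma) in scenario.true_coefficients.items():
        x = stack[name].values  # KeyError if the stack lacks a signal variable
        eta = eta + beta * x + gamma * x * x
    if scenario.link == "logistic":
        suit = expit(eta)
    else:
        suit = 1.0 - np.exp(-np.exp(eta))
    return RasterLayer(name="true_suitability", spec=stack.spec, values=suit)


def sample_occurrences(
    true_suitability: RasterLayer, n: int, seed=None, species: str = "virtual"
) -> OccurrenceSet:
    """Draw n distinct cells with probability proportional to suitability;
    each occurrence sits at its cell's center."""
    suit = true_suitability.values
    spec = true_suitability.spec
    mask = np.isfinite(suit) & (suit > 0)
    if not mask.any():
        raise ValueError("suitability is identically zero; nothing to sample")
    rows, cols = np.nonzero(mask)
    p = suit[rows, cols]
    if n > rows.size:
        raise ValueError(f"cannot draw {n} distinct cells from {rows.size} positive cells")
    rng = np.random.default_rng(seed)
    idx = rng.choice(rows.size, size=n, replace=False, p=p / p.sum())
    lon = spec.x_ll + (cols[idx] + 0.5) * spec.cell_size
    lat = spec.y_ur - (rows[idx] + 0.5) * spec.cell_size
    return OccurrenceSet(species=species, points=np.column_stack([lon, lat]))


def make_future_environment(
    stack: RasterStack,
    scenario: SyntheticScenario,
    warming_offset: float | None = None,
    precip_factor: float | None = None,
) -> RasterStack:
    """Climate-shifted copy: temp* layers + offset, precip* layers * factor.

    Geometry and the remaining layers are unchanged.  The offsets default to
    the scenario's; pass explicit values to build several emission pathways
    from one baseline.
    """
    off = scenario.warming_offset if warming_offset is None else warming_offset
    fac = scenario.precip_factor if precip_factor is None else precip_factor
    layers = []
    for lay in stack:
        v = lay.values
        if lay.name.startswith("temp"):
            v = v + off
        elif lay.name.startswith("precip"):
            v = v * fac
        layers.append(RasterLayer(name=lay.name, spec=lay.spec, values=v.copy(), units=lay.units))
    return RasterStack(layers)
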