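"""Virtual-species landscapes for end-to-end testing of the pipeline.

The generator builds a self-contained test world with the statistical
structure the analysis assumes about real data:

* spatially autocorrelated continuous covariate layers (smoothed Gaussian
  random fields plus a latitudinal trend) on a regular lat-lon grid, with a
  shared "ocean" nodata mask;
* a known true suitability surface — a logistic over additive response
  functions, dominated by one window-shaped effect of a temperature-range-like
  variable (high suitability only below an upper breakpoint), mimicking the
  strongly temperature-limited niche of a tropical crop;
* occurrence points sampled proportionally to true suitability, jittered
  within their cell, with duplicate cells allowed (duplicate records);
* categorical land-cover and region partitions as contiguous patches;
* climate scenarios as additive shifts applied to climate layers only.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .errors import ValidationError
from .grid import GridSpec, make_grid
from .raster import (CovariateStack, LandCoverMap, Raster, RegionMap,
                     SuitabilityMap)
from .terrain import slope_from_elevation

_CLIMATE_NAMES = ("temp_range", "temp_seasonality", "temp_coldest_q",
                  "min_temp_coldest", "precip_wettest_q", "annual_precip")
#: (location, scale) of each canonical climate layer, in layer units
_CLIMATE_SCALES = {
    "temp_range": (34.0, 8.0),          # deg C
    "temp_seasonality": (400.0, 150.0),  # SD x 100
    "temp_coldest_q": (18.0, 6.0),       # deg C
    "min_temp_coldest": (12.0, 6.0),     # deg C
    "precip_wettest_q": (500.0, 250.0),  # mm
    "annual_precip": (1200.0, 600.0),    # mm
}

_IGBP_NAMES = {1: "evergreen needleleaf forest", 2: "evergreen broadleaf forest",
               3: "deciduous needleleaf forest", 4: "deciduous broadleaf forest",
               5: "mixed forest", 6: "closed shrubland", 7: "open shrubland",
               8: "woody savanna", 9: "savanna", 10: "grassland",
               11: "wetland", 12: "cropland", 13: "urban", 16: "barren"}

#: land-cover classes counted as marginal land (shrublands, savannas, grassland)
MARGINAL_CLASSES = frozenset({6, 7, 8, 9, 10})

DEFAULT_CLASS_PROPS = {2: 0.25, 7: 0.05, 8: 0.10, 9: 0.15, 10: 0.20,
                       12: 0.20, 13: 0.05}


@dataclass(frozen=True)
class Response:
    """One additive response on the logit scale: weight * shape(x).

    kinds:
      ``linear``      shape = (x - lo) / (hi - lo)
      ``saturating``  shape = sigmoid((x - x0) / scale), rising 0 -> 1
      ``window``      shape = sigmoid((x - lo)/scale) - sigmoid((x - hi)/scale),
                      approximately 1 inside [lo, hi] and 0 outside
    """

    kind: str
    weight: float
    lo: float = 0.0
    hi: float = 1.0
    x0: float = 0.0
    scale: float = 1.0

    def shape(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "linear":
            return (x - self.lo) / (self.hi - self.lo)
        if self.kind == "saturating":
            return _sigmoid((x - self.x0) / self.scale)
        if self.kind == "window":
            return (_sigmoid((x - self.lo) / self.scale)
                    - _sigmoid((x - self.hi) / self.scale))
        raise ValidationError(f"unknown response kind {self.kind!r}")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.weight * self.shape(x)


@dataclass(frozen=True)
class TruthParams:
    """Generative truth: logistic link over additive responses."""

    intercept: float
    responses: dict[str, Response] = field(default_factory=dict)
    dominant: str = ""

    def __post_init__(self) -> None:
        if self.dominant and self.dominant not in self.responses:
            raise ValidationError(
                f"dominant variable {self.dominant!r} has no response")


@dataclass(frozen=True)
class ScenarioShift:
    """Additive per-layer climate offsets for one scenario x horizon."""

    scenario: str
    horizon: str
    offsets: dict[str, float] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return f"{self.scenario}_{self.horizon}"


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Standardized smoothed Gaussian random field (positive autocorrelation)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def generate_covariates(grid: GridSpec, n_climate: int = 8, seed: int = 0,
                        sigma: float | None = None,
                        ocean_fraction: float = 0.1) -> CovariateStack:
    """Build a covariate stack of climate, topography, and soil layers.

    Continuous layers are smoothed random fields mixed with a north-south
    trend; a shared "ocean" nodata mask (a thresholded smooth field) covers
    roughly ``ocean_fraction`` of the grid. Elevation is generated, slope
    derived from it, and a single categorical soil-class layer added.
    Deterministic given ``seed``.
    """
    if n_climate < 2:
        raise ValidationError("need at least 2 climate layers")
    if min(grid.n_rows, grid.n_cols) < 20:
        raise ValidationError("grid too small to smooth (min dimension 20)")
    if sigma is None:
        sigma = max(2.0, min(grid.n_rows, grid.n_cols) / 33.0)
    rng = np.random.default_rng(seed)
    trend = np.linspace(1.0, -1.0, grid.n_rows)[:, None] * np.ones(grid.n_cols)

    ocean = _smooth_field(rng, grid.shape, sigma)
    thr = np.quantile(ocean, 1.0 - ocean_fraction)
    mask = ocean > thr  # True = nodata

    names = list(_CLIMATE_NAMES[:n_climate])
    names += [f"bio_{k:02d}" for k in range(len(names) + 1, n_climate + 1)]

    layers: dict[str, Raster] = {}
    for name in names:
        loc, scale = _CLIMATE_SCALES.get(name, (0.0, 1.0))
        alpha = rng.uniform(0.2, 0.6)
        z = _smooth_field(rng, grid.shape, sigma)
        vals = loc + scale * (alpha * trend + math.sqrt(1 - alpha ** 2) * z)
        layers[name] = Raster(grid, vals, mask.copy())

    elev_vals = np.clip(800.0 + 600.0 * _smooth_field(rng, grid.shape, sigma),
                        0.0, None)
    elev = Raster(grid, elev_vals, mask.copy())
    layers["elevation"] = elev
    layers["slope"] = slope_from_elevation(elev)

    soil_field = _smooth_field(rng, grid.shape, sigma)
    edges = np.quantile(soil_field, np.linspace(0, 1, 7)[1:-1])
    soil = np.digitize(soil_field, edges) + 1  # codes 1..6
    layers["soil_class"] = Raster(grid, soil.astype(np.int32), mask.copy())

    return CovariateStack(grid, layers, climate_layers=tuple(names),
                          categorical_layers=("soil_class",))


def default_truth() -> TruthParams:
    """Default generative niche, dominated by the temperature-range window.

    The dominant window response (weight 9 of a total effect magnitude 12,
    i.e. 75%) makes suitability collapse once the temperature annual range
    exceeds its upper breakpoint of 30, with minor saturating effects of
    wettest-quarter precipitation and coldest-quarter temperature.
    """
    responses = {
        "temp_range": Response("window", weight=9.0, lo=8.0, hi=30.0, scale=1.5),
        "precip_wettest_q": Response("saturating", weight=1.5, x0=450.0, scale=150.0),
        "temp_coldest_q": Response("saturating", weight=1.5, x0=16.0, scale=3.0),
    }
    return TruthParams(intercept=-7.0, responses=responses, dominant="temp_range")


def true_suitability(stack: CovariateStack, params: TruthParams) -> SuitabilityMap:
    """Evaluate the generative truth on a stack (logistic of summed responses)."""
    missing = set(params.responses) - set(stack.layers)
    if missing:
        raise ValidationError(f"truth references missing layers: {sorted(missing)}")
    logit = np.full(stack.grid.shape, params.intercept, dtype=float)
    for name, resp in params.responses.items():
        logit += resp(stack.layers[name].values)
    suit = _sigmoid(logit)
    valid = stack.joint_valid()
    suit[~valid] = 0.0
    return SuitabilityMap(Raster(stack.grid, suit, ~valid))


def sample_occurrences(truth: SuitabilityMap, n: int, seed: int = 0) -> np.ndarray:
    """Sample occurrence points with probability proportional to suitability.

    Cells are drawn with replacement (duplicate records are realistic); each
    point is jittered uniformly within its cell. Returns an (n, 2) array of
    (lat, lon).
    """
    if n <= 0:
        raise ValidationError("number of occurrences must be positive")
    suit = truth.mean.values.astype(float).copy()
    suit[~truth.valid] = 0.0
    flat = suit.ravel()
    n_positive = int((flat > 0).sum())
    if n_positive < n:
        raise ValidationError(
            f"only {n_positive} cells with positive suitability; need >= {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat.size, size=n, replace=True, p=flat / flat.sum())
    rows, cols = np.unravel_index(idx, suit.shape)
    grid = truth.grid
    lat = grid.origin_lat - (rows + rng.random(n)) * grid.res
    lon = grid.origin_lon + (cols + rng.random(n)) * grid.res
    return np.column_stack([lat, lon])


def perturb_scenario(stack: CovariateStack, shift: ScenarioShift) -> CovariateStack:
    """Apply additive offsets to climate layers; all other layers unchanged."""
    bad = set(shift.offsets) - set(stack.climate_layers)
    if bad:
        raise ValidationError(
            f"scenario shifts non-climate or unknown layers: {sorted(bad)}")
    layers = dict(stack.layers)
    for name, off in shift.offsets.items():
        base = stack.layers[name]
        layers[name] = Raster(base.grid, base.values + float(off),
                              base.mask.copy())
    return CovariateStack(stack.grid, layers, stack.climate_layers,
                          stack.categorical_layers)


def generate_landcover(grid: GridSpec, class_props: dict[int, float] | None = None,
                       seed: int = 0, sigma: float | None = None,
                       legend: dict[int, str] | None = None) -> LandCoverMap:
    """Contiguous land-cover patches via smoothed-field quantile thresholding."""
    props = dict(class_props or DEFAULT_CLASS_PROPS)
    total = sum(props.values())
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(f"class proportions sum to {total}, not 1")
    if sigma is None:
        sigma = max(2.0, min(grid.n_rows, grid.n_cols) / 33.0)
    rng = np.random.default_rng(seed)
    f = _smooth_field(rng, grid.shape, sigma)
    codes = sorted(props)
    cum = np.cumsum([props[c] for c in codes])[:-1]
    edges = np.quantile(f, cum)
    lc = np.asarray(codes, dtype=np.int32)[np.digitize(f, edges)]
    leg = legend or {c: _IGBP_NAMES.get(c, f"class_{c}") for c in codes}
    return LandCoverMap(Raster(grid, lc, np.zeros(grid.shape, bool)), leg)


def generate_regions(grid: GridSpec, k: int, seed: int = 0,
                     level: str = "continent") -> RegionMap:
    """Partition the grid into k contiguous regions (nearest-seed-point)."""
    if k < 1:
        raise ValidationError("need at least one region")
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, grid.n_rows, size=k)
    cols = rng.integers(0, grid.n_cols, size=k)
    seeds = np.column_stack([rows, cols]).astype(float)
    ii, jj = np.mgrid[0:grid.n_rows, 0:grid.n_cols]
    pts = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
    _, nearest = cKDTree(seeds).query(pts)
    ids = (nearest + 1).astype(np.int32).reshape(grid.shape)
    table = pd.DataFrame({"region_id": np.arange(1, k + 1),
                          "name": [f"region_{i:02d}" for i in range(1, k + 1)],
                          "level": level})
    return RegionMap(Raster(grid, ids, np.zeros(grid.shape, bool)), table)


def default_scenarios() -> list[ScenarioShift]:
    """Three emission pathways x three horizons as additive climate shifts.

    Warming raises the annual temperature range and coldest-quarter
    temperature and perturbs precipitation; magnitudes grow with pathway
    forcing and horizon, loosely mirroring mid-century bioclim deltas.
    """
    pathways = {"rcp45": 1.0, "rcp60": 1.5, "rcp85": 2.5}
    horizons = {"2030": 0.5, "2050": 1.0, "2080": 1.8}
    shifts = []
    for scen, ps in pathways.items():
        for hor, hs in horizons.items():
            m = ps * hs
            shifts.append(ScenarioShift(scen, hor, {
                "temp_range": 0.8 * m,
                "temp_coldest_q": 1.0 * m,
                "min_temp_coldest": 1.0 * m,
                "precip_wettest_q": -30.0 * m,
            }))
    return shifts


def save_scenarios(shifts: list[ScenarioShift], path) -> None:
    doc = [{"scenario": s.scenario, "horizon": s.horizon,
            "offsets": {k: float(v) for k, v in s.offsets.items()}}
           for s in shifts]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_scenarios(path) -> list[ScenarioShift]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [ScenarioShift(str(d["scenario"]), str(d["horizon"]),
                          {str(k): float(v) for k, v in d["offsets"].items()})
            for d in doc]


def default_world(seed: int = 0, n_rows: int = 200, n_cols: int = 200,
                  n_points: int = 1600, n_climate: int = 8,
                  res: float = 0.05, n_regions: int = 6) -> dict:
    """The default synthetic study system: a tropical 200 x 200 world.

    Returns a dict with the grid, covariate stack, truth parameters and map,
    occurrence points, land cover, regions, and scenario shifts. Sub-seeds for
    the independent generators are derived from ``seed``.
    """
    grid = make_grid(5.0, 20.0, n_rows, n_cols, res)
    ss = np.random.SeedSequence(seed).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    stack = generate_covariates(grid, n_climate=n_climate, seed=sub[0])
    params = default_truth()
    truth = true_suitability(stack, params)
    points = sample_occurrences(truth, n_points, seed=sub[1])
    landcover = generate_landcover(grid, seed=sub[2])
    regions = generate_regions(grid, n_regions, seed=sub[3])
    return {"grid": grid, "stack": stack, "truth_params": params,
            "truth": truth, "points": points, "landcover": landcover,
            "regions": regions, "scenarios": default_scenarios()}
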