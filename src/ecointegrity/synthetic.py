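"""Seeded synthetic landscapes for end-to-end testing.

Generates threat features, smooth environmental rasters, river sites,
raw field parameters, and response values drawn from the linear model
``y = b0 + X b + e`` with Gaussian noise, so that every downstream stage
(threat rasterization, integrity scoring, model selection, cross
validation) can be exercised and validated without external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import LineString, Point, box

from .grids import GridSpec
from .integrity import ReferenceValues, SiteSample, ToleranceTable
from .threats import (
    THREAT_NAMES,
    ImpactSurface,
    ThreatFeature,
    ThreatRegistry,
    default_registry,
    rasterize_threat,
    sample_surface,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticLandscape",
    "SimulatedSites",
    "default_tolerance_table",
    "default_references",
    "default_feature_counts",
    "generate_env_rasters",
    "slope_from_elevation",
    "generate_threat_features",
    "simulate_eii",
    "sigma_for_r2",
    "simulate_site_parameters",
    "make_landscape",
]

ENV_NAMES = ("elevation", "slope")

#: Coefficients mirroring the fitted local-scale model with threat and
#: environmental predictors: settlements, roads and oil depress the
#: response; slope raises it and elevation lowers it.
DEFAULT_BETA = {
    "human_settlements": -0.165,
    "roads": -0.121,
    "oil_activities": -0.136,
    "elevation": -0.176,
    "slope": 0.199,
}


@dataclass
class SyntheticConfig:
    """Everything needed to generate one landscape, reproducibly."""

    extent_km: tuple[float, float] = (50.0, 50.0)
    pixel_size_m: float = 500.0
    n_sites: int = 140
    feature_counts: dict | None = None
    beta0: float = 0.738
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    sigma: float | None = None  # None => calibrate to target_r2
    target_r2: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_m <= 0:
            raise ValueError("pixel size must be > 0")
        if self.n_sites < 2:
            raise ValueError("need at least 2 sites")
        if self.sigma is not None and self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0 < self.target_r2 < 1):
            raise ValueError("target_r2 must be in (0, 1)")

    def grid(self) -> GridSpec:
        return GridSpec(
            origin_x=0.0,
            origin_y=0.0,
            pixel_size=self.pixel_size_m,
            ncols=max(1, round(self.extent_km[0] * 1000 / self.pixel_size_m)),
            nrows=max(1, round(self.extent_km[1] * 1000 / self.pixel_size_m)),
        )


@dataclass
class SyntheticLandscape:
    """A generated landscape bundle (see :func:`make_landscape`)."""

    config: SyntheticConfig
    grid: GridSpec
    elevation: np.ndarray
    slope: np.ndarray
    features: list[ThreatFeature]
    surfaces: dict[str, ImpactSurface]
    sites: pd.DataFrame  # site_id, x, y, elevation
    predictors: pd.DataFrame  # nine threats + scaled elevation/slope, in [0,1]
    eii: np.ndarray
    sigma: float
    n_clamped: int
    env_ranges: dict[str, tuple[float, float]]


@dataclass
class SimulatedSites:
    """Raw site parameters engineered to reproduce target component scores."""

    samples: list[SiteSample]
    fixed_bounds: dict[str, tuple[float, float]]
    references: ReferenceValues
    targets: np.ndarray


# ---------------------------------------------------------------------------
# defaults


def default_tolerance_table(families_per_score: int = 10) -> ToleranceTable:
    """Synthetic family-tolerance table: integer scores 1..10."""
    scores = {}
    for s in range(1, 11):
        for i in range(families_per_score):
            scores[f"fam_s{s:02d}_{i:02d}"] = float(s)
    return ToleranceTable(scores)


def default_references() -> ReferenceValues:
    """Plausible reference condition and deviation scaling bounds."""
    return ReferenceValues(
        references={
            "ph": 7.2,
            "conductivity": 120.0,
            "dissolved_oxygen": 8.0,
            "temperature": 18.0,
        },
        deviation_bounds={
            "ph": 3.0,
            "conductivity": 500.0,
            "dissolved_oxygen": 6.0,
            "temperature": 12.0,
        },
    )


def default_feature_counts() -> dict:
    """Per-(threat, category) feature counts and geometry kinds."""
    return {
        ("human_settlements", "urban_area"): {"count": 3, "kind": "polygon"},
        ("human_settlements", "village"): {"count": 15, "kind": "point"},
        ("mining", "construction_material"): {"count": 3, "kind": "point"},
        ("mining", "metal"): {"count": 3, "kind": "point"},
        ("agricultural_land_use", "crops"): {"count": 5, "kind": "polygon"},
        ("agricultural_land_use", "mosaic_pastureland"): {"count": 5, "kind": "polygon"},
        ("hydroelectric_plants", "operating_large"): {"count": 1, "kind": "point"},
        ("hydroelectric_plants", "operating_small"): {"count": 2, "kind": "point"},
        ("thermoelectric_plants", "default"): {"count": 2, "kind": "point"},
        ("oil_activities", "well_operating"): {"count": 10, "kind": "point"},
        ("oil_activities", "spill_recent_high_volume"): {"count": 3, "kind": "point"},
        ("oil_activities", "pipeline_risky_area"): {"count": 2, "kind": "line"},
        ("water_withdrawals", "default"): {
            "count": 6,
            "kind": "point",
            "attribute_range": (100.0, 10000.0),
        },
        ("aquaculture_farms", "default"): {
            "count": 5,
            "kind": "point",
            "attribute_range": (50.0, 5000.0),
        },
        ("roads", "primary"): {"count": 3, "kind": "line"},
        ("roads", "secondary"): {"count": 5, "kind": "line"},
    }


# ---------------------------------------------------------------------------
# environmental rasters


def slope_from_elevation(elevation: np.ndarray, pixel_size: float) -> np.ndarray:
    """Slope (degrees) from central finite differences of elevation."""
    dz_dy, dz_dx = np.gradient(np.asarray(elevation, dtype=float), pixel_size)
    return np.degrees(np.arctan(np.hypot(dz_dx, dz_dy)))


def generate_env_rasters(
    grid: GridSpec,
    seed: int,
    relief: float = 3300.0,
    base_elevation: float = 300.0,
    noise_sd: float = 120.0,
    smoothing_pixels: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth monotone-plus-noise elevation gradient and derived slope.

    Elevation falls linearly from west (Andes) to east (lowlands) with a
    seeded, Gaussian-smoothed noise field on top; slope is the central
    finite-difference gradient magnitude in degrees.
    """
    if grid.ncols <= 1 or grid.nrows <= 1:
        raise ValueError("degenerate grid: need > 1 pixel per axis")
    rng = np.random.default_rng(seed)
    X, _ = grid.center_mesh()
    frac = (X - grid.origin_x) / grid.width
    elevation = base_elevation + relief * (1.0 - frac)
    if noise_sd > 0:
        noise = rng.normal(0.0, 1.0, size=grid.shape)
        noise = ndimage.gaussian_filter(noise, sigma=smoothing_pixels)
        sd = noise.std()
        if sd > 0:
            elevation = elevation + noise * (noise_sd / sd)
    slope = slope_from_elevation(elevation, grid.pixel_size)
    assert np.all(np.isfinite(elevation)) and np.all(np.isfinite(slope))
    return elevation, slope


# ---------------------------------------------------------------------------
# threat features


def _random_point(rng, grid: GridSpec) -> Point:
    return Point(
        rng.uniform(grid.origin_x, grid.xmax),
        rng.uniform(grid.origin_y, grid.ymax),
    )


def _random_line(rng, grid: GridSpec) -> LineString:
    cx = rng.uniform(grid.origin_x, grid.xmax)
    cy = rng.uniform(grid.origin_y, grid.ymax)
    angle = rng.uniform(0, np.pi)
    half = rng.uniform(1000.0, min(grid.width, grid.height) / 2.0) / 2.0
    dx, dy = half * np.cos(angle), half * np.sin(angle)
    line = LineString([(cx - dx, cy - dy), (cx + dx, cy + dy)])
    clipped = line.intersection(box(grid.origin_x, grid.origin_y, grid.xmax, grid.ymax))
    return clipped if not clipped.is_empty else LineString([(cx, cy), (cx, cy + 1.0)])


def _random_polygon(rng, grid: GridSpec):
    cx = rng.uniform(grid.origin_x, grid.xmax)
    cy = rng.uniform(grid.origin_y, grid.ymax)
    hw = rng.uniform(500.0, 3000.0)
    hh = rng.uniform(500.0, 3000.0)
    poly = box(cx - hw, cy - hh, cx + hw, cy + hh)
    return poly.intersection(box(grid.origin_x, grid.origin_y, grid.xmax, grid.ymax))


def generate_threat_features(
    grid: GridSpec,
    counts: Mapping | None = None,
    registry: ThreatRegistry | None = None,
    seed: int = 0,
) -> list[ThreatFeature]:
    """Seeded random features per (threat, category) count table.

    Geometries always lie within the grid extent; attribute-scaled
    categories draw their attribute uniformly from ``attribute_range``.
    """
    registry = registry or default_registry()
    counts = default_feature_counts() if counts is None else counts
    rng = np.random.default_rng(seed)
    makers = {"point": _random_point, "line": _random_line, "polygon": _random_polygon}
    features: list[ThreatFeature] = []
    for (threat, category), spec in counts.items():
        if (threat, category) not in registry:
            raise KeyError(f"({threat!r}, {category!r}) not in threat registry")
        n = int(spec["count"])
        if n < 0:
            raise ValueError("feature count must be >= 0")
        kind = spec.get("kind", "point")
        if kind not in makers:
            raise ValueError(f"unknown geometry kind {kind!r}")
        arange = spec.get("attribute_range")
        for _ in range(n):
            geom = makers[kind](rng, grid)
            attr = float(rng.uniform(*arange)) if arange is not None else None
            features.append(
                ThreatFeature(geometry=geom, threat=threat, category=category, attribute=attr)
            )
    return features


# ---------------------------------------------------------------------------
# response simulation


def simulate_eii(X, beta0: float, beta, sigma: float, seed=None) -> tuple[np.ndarray, int]:
    """Draw ``y = b0 + X b + Normal(0, sigma^2)``, clamped to [0, 1].

    Returns ``(y, n_clamped)``.  ``seed`` may be an int or a Generator.
    """
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.ndim != 2 or X.shape[1] != beta.size:
        raise ValueError(
            f"predictor matrix has {X.shape[1] if X.ndim == 2 else '?'} columns "
            f"but beta has {beta.size} entries"
        )
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if np.any(X < -1e-9) or np.any(X > 1 + 1e-9):
        warnings.warn("predictor values outside [0, 1]", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eta = beta0 + X @ beta
    y = eta + rng.normal(0.0, sigma, size=eta.shape) if sigma > 0 else eta.copy()
    clamped = (y < 0) | (y > 1)
    return np.clip(y, 0.0, 1.0), int(clamped.sum())


def sigma_for_r2(linear_predictor, r2: float) -> float:
    """Noise SD giving analytic ``R^2 = var(eta) / (var(eta) + sigma^2)``."""
    if not (0 < r2 <= 1):
        raise ValueError("r2 must be in (0, 1]")
    v = float(np.var(np.asarray(linear_predictor, dtype=float)))
    if v == 0:
        raise ValueError("linear predictor is constant; R^2 undefined")
    return float(np.sqrt(v * (1.0 - r2) / r2))


# ---------------------------------------------------------------------------
# raw site parameters hitting target component scores


def _pick_taxa(target: float, table: ToleranceTable, n_fam: int, rng) -> list[str]:
    """Choose ``n_fam`` distinct families whose mean tolerance score maps to
    ``target`` on the (min_score, max_score) scale."""
    lo, hi = table.min_score, table.max_score
    if hi == lo:
        raise ValueError("tolerance table has a single score level: infeasible")
    target_mean = lo + target * (hi - lo)
    by_family = list(table.items())
    rng.shuffle(by_family)
    chosen: list[str] = []
    total = 0.0
    remaining = list(by_family)
    for picks_left in range(n_fam, 0, -1):
        want = (target_mean * n_fam - total) / picks_left
        idx = min(range(len(remaining)), key=lambda j: abs(remaining[j][1] - want))
        fam, score = remaining.pop(idx)
        chosen.append(fam)
        total += score
    achieved = (total / n_fam - lo) / (hi - lo)
    if abs(achieved - target) > 0.02:
        raise ValueError(
            f"cannot reach biotic target {target:.3f} with this tolerance table "
            f"(best {achieved:.3f})"
        )
    return chosen


def simulate_site_parameters(
    targets,
    table: ToleranceTable | None = None,
    seed: int = 0,
    references: ReferenceValues | None = None,
    n_families: int = 10,
    coords=None,
    elevations=None,
) -> SimulatedSites:
    """Raw field parameters that the integrity pipeline maps back onto
    ``targets`` (rows of biotic, habitat, physchem scores) within 0.02.

    The returned ``fixed_bounds`` must be handed to
    :func:`ecointegrity.integrity.score_sites` so normalization uses the
    construction's scale rather than empirical site ranges.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if targets.shape[1] != 3:
        raise ValueError("targets must have three columns (biotic, habitat, physchem)")
    if np.any(targets < 0) or np.any(targets > 1):
        raise ValueError("target component scores must lie in [0, 1]")
    table = table or default_tolerance_table()
    references = references or default_references()
    if not references.deviation_bounds:
        raise ValueError("references must declare deviation_bounds")
    rng = np.random.default_rng(seed)
    n = targets.shape[0]
    coords = np.asarray(coords) if coords is not None else np.column_stack(
        [np.arange(n, dtype=float), np.zeros(n)]
    )
    elevations = (
        np.asarray(elevations, dtype=float)
        if elevations is not None
        else np.full(n, 1000.0)
    )

    samples = []
    for i, (t_bio, t_hab, t_phys) in enumerate(targets):
        taxa = _pick_taxa(t_bio, table, n_families, rng)
        habitat_raw = {"qbr": t_hab * 100.0, "ihf": t_hab * 100.0}
        phys = {}
        for param, bound in references.deviation_bounds.items():
            ref = references.reference_for(param, elevations[i])
            sign = 1.0 if rng.random() < 0.5 else -1.0
            phys[param] = ref + sign * (1.0 - t_phys) * bound
        samples.append(
            SiteSample(
                site_id=f"site_{i:03d}",
                x=float(coords[i, 0]),
                y=float(coords[i, 1]),
                elevation=float(elevations[i]),
                taxa=taxa,
                habitat_raw=habitat_raw,
                physchem=phys,
            )
        )
    lo, hi = table.min_score, table.max_score
    fixed_bounds = {
        "ambi": (n_families * lo, n_families * hi),
        "aspt": (lo, hi),
    }
    return SimulatedSites(
        samples=samples, fixed_bounds=fixed_bounds, references=references,
        targets=targets,
    )


# ---------------------------------------------------------------------------
# full landscape


def make_landscape(
    config: SyntheticConfig | None = None,
    registry: ThreatRegistry | None = None,
) -> SyntheticLandscape:
    """Generate the full synthetic bundle for one seeded configuration."""
    config = config or SyntheticConfig()
    registry = registry or default_registry()
    grid = config.grid()
    ss = np.random.SeedSequence(config.seed)
    seed_env, seed_feat, seed_sites, seed_noise = ss.spawn(4)

    elevation, slope = generate_env_rasters(grid, seed_env)
    features = generate_threat_features(
        grid, config.feature_counts, registry, seed_feat
    )

    by_threat: dict[str, list[ThreatFeature]] = {t: [] for t in THREAT_NAMES}
    for f in features:
        by_threat[f.threat].append(f)
    surfaces = {
        t: rasterize_threat(fs, registry, grid, threat=t)
        for t, fs in by_threat.items()
    }

    rng_sites = np.random.default_rng(seed_sites)
    xs = rng_sites.uniform(grid.origin_x, grid.xmax, size=config.n_sites)
    ys = rng_sites.uniform(grid.origin_y, grid.ymax, size=config.n_sites)
    coords = np.column_stack([xs, ys])

    env_ranges = {
        "elevation": (float(elevation.min()), float(elevation.max())),
        "slope": (float(slope.min()), float(slope.max())),
    }
    cols: dict[str, np.ndarray] = {}
    for t in THREAT_NAMES:
        cols[t] = sample_surface(surfaces[t], coords)
    row, col = grid.cell_of(xs, ys)
    for name, raster in (("elevation", elevation), ("slope", slope)):
        lo, hi = env_ranges[name]
        vals = raster[row, col]
        cols[name] = (vals - lo) / (hi - lo) if hi > lo else np.zeros_like(vals)
    predictors = pd.DataFrame(cols)

    missing = [p for p in config.beta if p not in predictors.columns]
    if missing:
        raise KeyError(f"beta names not among predictors: {missing}")
    names = list(config.beta)
    X = predictors[names].to_numpy()
    beta = np.array([config.beta[p] for p in names])
    eta = config.beta0 + X @ beta
    sigma = config.sigma if config.sigma is not None else sigma_for_r2(eta, config.target_r2)
    eii, n_clamped = simulate_eii(
        X, config.beta0, beta, sigma, np.random.default_rng(seed_noise)
    )

    sites = pd.DataFrame(
        {
            "site_id": [f"site_{i:03d}" for i in range(config.n_sites)],
            "x": xs,
            "y": ys,
            "elevation": elevation[row, col],
        }
    )
    return SyntheticLandscape(
        config=config,
        grid=grid,
        elevation=elevation,
        slope=slope,
        features=features,
        surfaces=surfaces,
        sites=sites,
        predictors=predictors,
        eii=eii,
        sigma=float(sigma),
        n_clamped=n_clamped,
        env_ranges=env_ranges,
    )
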