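"""Anthropogenic threat surfaces.

Each human-activity feature (point, polyline or polygon) carries a
per-category magnitude of impact ``m`` in (0, 1] and a maximum impact
distance ``D`` in meters.  Impact decays linearly from ``m`` at the
feature to zero at ``D``; overlapping buffers add, and the per-threat
surface is summarized on a 0-1 scale.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import shapely
import yaml
from shapely.geometry.base import BaseGeometry

from .grids import GridSpec

__all__ = [
    "THREAT_NAMES",
    "ThreatCategorySpec",
    "ThreatRegistry",
    "ThreatFeature",
    "ImpactSurface",
    "default_registry",
    "resolve_magnitude",
    "resolve_distance",
    "decayed_impact",
    "rasterize_threat",
    "sample_surface",
    "surface_extent_fraction",
]

#: The nine threats, in canonical order.
THREAT_NAMES = (
    "human_settlements",
    "mining",
    "agricultural_land_use",
    "hydroelectric_plants",
    "thermoelectric_plants",
    "oil_activities",
    "water_withdrawals",
    "aquaculture_farms",
    "roads",
)


@dataclass(frozen=True)
class ThreatCategorySpec:
    """Impact parameters of one category within one threat."""

    threat: str
    category: str
    magnitude: float
    impact_distance_m: float
    magnitude_rule: str = "fixed"  # fixed | attribute_scaled
    attribute: str | None = None
    magnitude_range: tuple[float, float] = (0.1, 1.0)
    distance_rule: str = "fixed"  # fixed | plant_size_scaled
    distance_scale_reference: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.magnitude <= 1):
            raise ValueError(
                f"{self.threat}/{self.category}: magnitude must be in (0, 1], "
                f"got {self.magnitude}"
            )
        if self.impact_distance_m <= 0:
            raise ValueError(
                f"{self.threat}/{self.category}: impact distance must be > 0"
            )
        if self.magnitude_rule not in ("fixed", "attribute_scaled"):
            raise ValueError(f"unknown magnitude_rule {self.magnitude_rule!r}")
        if self.distance_rule not in ("fixed", "plant_size_scaled"):
            raise ValueError(f"unknown distance_rule {self.distance_rule!r}")
        if self.magnitude_rule == "attribute_scaled" and self.attribute is None:
            raise ValueError(
                f"{self.threat}/{self.category}: attribute_scaled rule needs "
                "an attribute name"
            )


class ThreatRegistry:
    """Lookup of :class:`ThreatCategorySpec` keyed by ``(threat, category)``."""

    def __init__(self, specs: Iterable[ThreatCategorySpec], version: str = "custom"):
        self.version = version
        self._specs: dict[tuple[str, str], ThreatCategorySpec] = {}
        for spec in specs:
            key = (spec.threat, spec.category)
            if key in self._specs:
                raise ValueError(f"duplicate registry key {key}")
            self._specs[key] = spec

    def __len__(self) -> int:
        return len(self._specs)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._specs

    def __iter__(self):
        return iter(self._specs.values())

    def __getitem__(self, key: tuple[str, str]) -> ThreatCategorySpec:
        try:
            return self._specs[key]
        except KeyError:
            raise KeyError(
                f"threat/category {key} not in registry "
                f"(version {self.version})"
            ) from None

    @property
    def threats(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(t for t, _ in self._specs))

    def categories(self, threat: str) -> tuple[str, ...]:
        return tuple(c for t, c in self._specs if t == threat)

    # -- serialization ----------------------------------------------------

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ThreatRegistry":
        specs = []
        for threat, cats in raw["threats"].items():
            for category, row in cats.items():
                specs.append(
                    ThreatCategorySpec(
                        threat=threat,
                        category=category,
                        magnitude=float(row["magnitude"]),
                        impact_distance_m=float(row["impact_distance_m"]),
                        magnitude_rule=row.get("magnitude_rule", "fixed"),
                        attribute=row.get("attribute"),
                        magnitude_range=tuple(row.get("magnitude_range", (0.1, 1.0))),
                        distance_rule=row.get("distance_rule", "fixed"),
                        distance_scale_reference=row.get("distance_scale_reference"),
                    )
                )
        return cls(specs, version=str(raw.get("version", "custom")))

    def to_dict(self) -> dict:
        threats: dict[str, dict] = {}
        for spec in self:
            row: dict = {
                "magnitude": spec.magnitude,
                "impact_distance_m": spec.impact_distance_m,
            }
            if spec.magnitude_rule != "fixed":
                row["magnitude_rule"] = spec.magnitude_rule
                row["attribute"] = spec.attribute
                row["magnitude_range"] = list(spec.magnitude_range)
            if spec.distance_rule != "fixed":
                row["distance_rule"] = spec.distance_rule
                row["distance_scale_reference"] = spec.distance_scale_reference
            threats.setdefault(spec.threat, {})[spec.category] = row
        return {"version": self.version, "threats": threats}

    @classmethod
    def from_yaml(cls, path) -> "ThreatRegistry":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def default_registry() -> ThreatRegistry:
    """The shipped registry covering all nine threats and their categories."""
    ref = importlib.resources.files("ecointegrity.data") / "threat_registry.yaml"
    return ThreatRegistry.from_dict(yaml.safe_load(ref.read_text()))


@dataclass
class ThreatFeature:
    """A georeferenced human-activity feature (planar meters)."""

    geometry: BaseGeometry
    threat: str
    category: str
    attribute: float | None = None

    def __post_init__(self) -> None:
        if self.geometry is None or self.geometry.is_empty:
            raise ValueError("feature geometry must be non-empty")
        if not shapely.is_valid(self.geometry):
            raise ValueError(f"invalid geometry for {self.threat}/{self.category}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.threat, self.category)


@dataclass
class ImpactSurface:
    """Per-pixel impact values in [0, 1] for one threat on a grid."""

    grid: GridSpec
    values: np.ndarray
    threat: str
    policy: str = "cap"
    registry_version: str = "custom"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if np.any(self.values < 0) or np.any(self.values > 1 + 1e-12):
            raise ValueError("impact values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# magnitude / distance resolution


def attribute_bounds(features: Iterable[ThreatFeature], registry: ThreatRegistry):
    """Observed (min, max) of the scaling attribute per threat.

    Computed across all features of each threat whose category uses the
    attribute_scaled magnitude rule.
    """
    bounds: dict[str, tuple[float, float]] = {}
    pools: dict[str, list[float]] = {}
    for f in features:
        spec = registry[f.key]
        if spec.magnitude_rule == "attribute_scaled":
            if f.attribute is None:
                raise ValueError(
                    f"feature {f.key} requires attribute "
                    f"{spec.attribute!r} for magnitude scaling"
                )
            pools.setdefault(f.threat, []).append(float(f.attribute))
    for threat, vals in pools.items():
        bounds[threat] = (min(vals), max(vals))
    return bounds


def resolve_magnitude(
    feature: ThreatFeature,
    spec: ThreatCategorySpec,
    bounds: tuple[float, float] | None = None,
) -> float:
    """Magnitude of impact for one feature under its category rule.

    Under the attribute_scaled rule the feature's attribute is mapped
    linearly from the observed (min, max) across the feature set onto the
    declared output interval; a lone feature (min == max) maps to the top.
    """
    if spec.magnitude_rule == "fixed":
        return spec.magnitude
    if feature.attribute is None:
        raise ValueError(
            f"feature {feature.key} lacks attribute {spec.attribute!r}"
        )
    lo, hi = spec.magnitude_range
    if bounds is None:
        return hi
    amin, amax = bounds
    if amax == amin:
        return hi
    frac = (float(feature.attribute) - amin) / (amax - amin)
    return lo + frac * (hi - lo)


def resolve_distance(spec: ThreatCategorySpec) -> float:
    """Maximum impact distance, applying the plant-size scaling rule."""
    if spec.distance_rule == "fixed":
        return spec.impact_distance_m
    ref = spec.distance_scale_reference
    if ref is None or ref <= 0:
        raise ValueError(
            f"{spec.threat}/{spec.category}: plant_size_scaled rule needs a "
            "positive distance_scale_reference"
        )
    return min(spec.impact_distance_m, spec.impact_distance_m * spec.magnitude / ref)


def decayed_impact(magnitude, distance, max_distance):
    """Linear decay: ``m * (1 - d/D)`` for ``d < D``, else 0."""
    if np.any(np.asarray(max_distance) <= 0):
        raise ValueError("max_distance must be > 0")
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    return magnitude * np.clip(1.0 - d / max_distance, 0.0, None)


# ---------------------------------------------------------------------------
# rasterization


def rasterize_threat(
    features,
    registry: ThreatRegistry,
    grid: GridSpec,
    policy: str = "cap",
    threat: str | None = None,
) -> ImpactSurface:
    """Sum linearly decayed impacts of all features of one threat on a grid.

    Pixels are evaluated at their centers; distance is Euclidean to the
    nearest point of each geometry (0 inside polygons).  Overlapping
    impacts add and the surface is brought back to [0, 1] by ``policy``:
    ``"cap"`` clips at 1.0, ``"rescale"`` divides by the global maximum
    when it exceeds 1.
    """
    features = list(features)
    if policy not in ("cap", "rescale"):
        raise ValueError(f"unknown overlap policy {policy!r}")
    threats = {f.threat for f in features}
    if len(threats) > 1:
        raise ValueError(f"features span multiple threats: {sorted(threats)}")
    if threat is None:
        if not threats:
            raise ValueError("empty feature list: pass threat= explicitly")
        threat = threats.pop()
    elif threats and threats != {threat}:
        raise ValueError("threat= does not match the features")

    for f in features:
        registry[f.key]  # raises KeyError for unregistered categories
    bounds = attribute_bounds(features, registry)

    xs = grid.x_centers()
    ys = grid.y_centers()
    values = np.zeros(grid.shape)

    for f in features:
        spec = registry[f.key]
        m = resolve_magnitude(f, spec, bounds.get(f.threat))
        dmax = resolve_distance(spec)

        # restrict to pixels whose centers can be within reach
        gxmin, gymin, gxmax, gymax = f.geometry.bounds
        ci = np.flatnonzero((xs >= gxmin - dmax) & (xs <= gxmax + dmax))
        ri = np.flatnonzero((ys >= gymin - dmax) & (ys <= gymax + dmax))
        if ci.size == 0 or ri.size == 0:
            continue
        X, Y = np.meshgrid(xs[ci], ys[ri])
        pts = shapely.points(X.ravel(), Y.ravel())
        d = shapely.distance(pts, f.geometry).reshape(X.shape)
        block = decayed_impact(m, d, dmax)
        values[np.ix_(ri, ci)] += block

    if policy == "cap":
        values = np.clip(values, 0.0, 1.0)
    else:
        peak = values.max()
        if peak > 1.0:
            values = values / peak
    return ImpactSurface(
        grid=grid,
        values=values,
        threat=threat,
        policy=policy,
        registry_version=registry.version,
    )


def sample_surface(surface: ImpactSurface, coords) -> np.ndarray:
    """Value of the pixel containing each (x, y) site."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    row, col = surface.grid.cell_of(coords[:, 0], coords[:, 1])
    return surface.values[row, col]


def sample_grid_values(grid: GridSpec, values: np.ndarray, coords) -> np.ndarray:
    """Like :func:`sample_surface` but for a bare (grid, array) raster."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    row, col = grid.cell_of(coords[:, 0], coords[:, 1])
    return np.asarray(values)[row, col]


def surface_extent_fraction(surface: ImpactSurface, threshold: float = 0.0) -> float:
    """Fraction of grid pixels with impact strictly above ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return float(np.mean(surface.values > threshold))
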