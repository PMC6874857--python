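"""Ecological Integrity Index (EII).

Three site-level components — biotic (family-tolerance biotic index and
its per-taxon average), habitat (riparian-quality and fluvial-habitat raw
scores), and physical-chemical deviations from reference condition — are
each scaled to [0, 1] so that 1 is the least-impacted state, averaged
within component, and combined by an arithmetic or a 2:1:1
biotic-weighted mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ToleranceTable",
    "SiteSample",
    "ReferenceValues",
    "ComponentScores",
    "EIIRecord",
    "PHYSCHEM_PARAMS",
    "WEIGHTS_ARITHMETIC",
    "WEIGHTS_BIOTIC",
    "compute_ambi",
    "compute_aspt",
    "physchem_deviation",
    "normalize_parameter",
    "component_score",
    "compute_eii",
    "score_sites",
]

PHYSCHEM_PARAMS = ("ph", "conductivity", "dissolved_oxygen", "temperature")
WEIGHTS_ARITHMETIC = (1.0, 1.0, 1.0)
WEIGHTS_BIOTIC = (2.0, 1.0, 1.0)  # biotic : habitat : physchem


class ToleranceTable(Mapping):
    """Family name -> physiological tolerance score (> 0; higher = more
    sensitive, hence indicative of better condition)."""

    def __init__(self, scores: Mapping[str, float]):
        bad = {k: v for k, v in scores.items() if not v > 0}
        if bad:
            raise ValueError(f"tolerance scores must be > 0: {bad}")
        self._scores = {str(k): float(v) for k, v in scores.items()}
        if not self._scores:
            raise ValueError("tolerance table is empty")

    def __getitem__(self, family: str) -> float:
        return self._scores[family]

    def __iter__(self):
        return iter(self._scores)

    def __len__(self) -> int:
        return len(self._scores)

    @property
    def min_score(self) -> float:
        return min(self._scores.values())

    @property
    def max_score(self) -> float:
        return max(self._scores.values())

    @classmethod
    def from_yaml(cls, path) -> "ToleranceTable":
        return cls(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self._scores, sort_keys=True))


@dataclass
class SiteSample:
    """Raw field measurements for one river site."""

    site_id: str
    x: float
    y: float
    elevation: float
    taxa: list[str]
    habitat_raw: dict[str, float]  # e.g. {"qbr": 72, "ihf": 60}
    habitat_max: dict[str, float] = field(
        default_factory=lambda: {"qbr": 100.0, "ihf": 100.0}
    )
    physchem: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, raw in self.habitat_raw.items():
            top = self.habitat_max.get(name)
            if top is None or top <= 0:
                raise ValueError(f"site {self.site_id}: no maximum for {name!r}")
            if not (0 <= raw <= top):
                raise ValueError(
                    f"site {self.site_id}: habitat score {name}={raw} outside "
                    f"[0, {top}]"
                )


@dataclass
class ReferenceValues:
    """Reference physical-chemical values, optionally per elevation band.

    ``bands`` maps (low, high) elevation intervals (meters, low-inclusive)
    to overrides of the global references.
    """

    references: dict[str, float]
    deviation_bounds: dict[str, float] | None = None
    bands: Sequence[tuple[float, float, dict[str, float]]] = ()

    def __post_init__(self) -> None:
        if self.deviation_bounds:
            bad = {k: v for k, v in self.deviation_bounds.items() if not v > 0}
            if bad:
                raise ValueError(f"deviation bounds must be > 0: {bad}")

    def reference_for(self, param: str, elevation: float | None = None) -> float:
        if elevation is not None:
            for low, high, overrides in self.bands:
                if low <= elevation < high and param in overrides:
                    return overrides[param]
        if param not in self.references:
            raise KeyError(f"no reference value for parameter {param!r}")
        return self.references[param]

    @classmethod
    def from_yaml(cls, path) -> "ReferenceValues":
        raw = yaml.safe_load(Path(path).read_text())
        bands = [
            (float(b["low"]), float(b["high"]), dict(b["references"]))
            for b in raw.get("bands", [])
        ]
        return cls(
            references=dict(raw["references"]),
            deviation_bounds=raw.get("deviation_bounds"),
            bands=bands,
        )


@dataclass(frozen=True)
class ComponentScores:
    biotic: float
    habitat: float
    physchem: float

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if not (0 <= v <= 1):
                raise ValueError(f"component {name}={v} outside [0, 1]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.biotic, self.habitat, self.physchem)

    def as_dict(self) -> dict[str, float]:
        return {"biotic": self.biotic, "habitat": self.habitat, "physchem": self.physchem}


@dataclass(frozen=True)
class EIIRecord:
    site_id: str
    eii_arithmetic: float
    eii_weighted: float


# ---------------------------------------------------------------------------
# elementary operations


def resolve_taxa(
    taxa: Iterable[str],
    table: ToleranceTable,
    unknown: str = "warn",
) -> list[str]:
    """Distinct families present that resolve in the tolerance table.

    ``unknown='warn'`` drops unresolvable names with a warning;
    ``'strict'`` raises; ``'ignore'`` drops silently.
    """
    seen = list(dict.fromkeys(taxa))
    known = [t for t in seen if t in table]
    missing = [t for t in seen if t not in table]
    if missing:
        if unknown == "strict":
            raise KeyError(f"taxa not in tolerance table: {missing}")
        if unknown == "warn":
            warnings.warn(f"skipping unrecognized taxa: {missing}", stacklevel=2)
    return known


def compute_ambi(taxa: Iterable[str], table: ToleranceTable, unknown: str = "warn") -> float:
    """Biotic index: sum of tolerance scores over distinct families present."""
    families = resolve_taxa(taxa, table, unknown=unknown)
    if not families:
        raise ValueError("no resolvable taxa: biotic index undefined")
    return float(sum(table[f] for f in families))


def compute_aspt(ambi_score: float, n_families: int) -> float:
    """Average score per taxon: biotic index / number of families."""
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    return ambi_score / n_families


def physchem_deviation(observed: float, reference: float) -> float:
    """Absolute deviation of an observation from its reference value."""
    if not (np.isfinite(observed) and np.isfinite(reference)):
        raise ValueError("observed and reference must be finite")
    return abs(observed - reference)


def normalize_parameter(
    values,
    invert: bool = False,
    bounds: tuple[float, float] | None = None,
) -> np.ndarray:
    """Min-max scale a parameter across sites to [0, 1], 1 = best.

    Empirical (min, max) across the sites is used unless fixed ``bounds``
    are given.  ``invert=True`` flips the scale (for deviations, where a
    larger value means worse condition).  A constant column scores 1.0
    everywhere — no evidence of impairment — with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0 or not np.any(np.isfinite(v)):
        raise ValueError("need at least one finite value")
    lo, hi = bounds if bounds is not None else (np.nanmin(v), np.nanmax(v))
    if hi == lo:
        warnings.warn(
            "constant parameter column: scoring 1.0 everywhere", stacklevel=2
        )
        return np.ones_like(v)
    scaled = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
    return 1.0 - scaled if invert else scaled


def component_score(parameter_scores) -> float:
    """Arithmetic mean of parameter scores, all already in [0, 1]."""
    s = np.asarray(parameter_scores, dtype=float)
    if s.size == 0:
        raise ValueError("component needs at least one parameter score")
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("parameter scores must lie in [0, 1]")
    return float(np.mean(s))


def compute_eii(components, weights=WEIGHTS_ARITHMETIC) -> float:
    """Weighted mean of (biotic, habitat, physchem) component scores."""
    if isinstance(components, ComponentScores):
        components = components.as_tuple()
    c = np.asarray(components, dtype=float)
    w = np.asarray(weights, dtype=float)
    if c.shape != (3,) or w.shape != (3,):
        raise ValueError("expected three components and three weights")
    if np.any(c < 0) or np.any(c > 1):
        raise ValueError(f"components outside [0, 1]: {c}")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return float(np.dot(w, c) / w.sum())


# ---------------------------------------------------------------------------
# site-table pipeline


def score_sites(
    samples: Sequence[SiteSample],
    table: ToleranceTable,
    references: ReferenceValues,
    fixed_bounds: Mapping[str, tuple[float, float]] | None = None,
    unknown_taxa: str = "warn",
) -> pd.DataFrame:
    """Score a set of sites: components plus both EII variants.

    ``fixed_bounds`` optionally pins the normalization interval per
    parameter (keys ``"ambi"``, ``"aspt"`` and, for deviation scales,
    the physical-chemical parameter names); otherwise bounds are
    empirical across the site set.  Deviation bounds declared on
    ``references.deviation_bounds`` act as fixed (0, bound) intervals.
    """
    if not samples:
        raise ValueError("no sites to score")
    fixed_bounds = dict(fixed_bounds or {})
    if references.deviation_bounds:
        for param, bound in references.deviation_bounds.items():
            fixed_bounds.setdefault(param, (0.0, float(bound)))

    ambi = np.empty(len(samples))
    nfam = np.empty(len(samples), dtype=int)
    for i, s in enumerate(samples):
        families = resolve_taxa(s.taxa, table, unknown=unknown_taxa)
        if not families:
            raise ValueError(f"site {s.site_id}: no resolvable taxa")
        ambi[i] = sum(table[f] for f in families)
        nfam[i] = len(families)
    aspt = ambi / nfam

    # biotic: higher index values indicate more sensitive communities
    ambi_score = normalize_parameter(ambi, bounds=fixed_bounds.get("ambi"))
    aspt_score = normalize_parameter(aspt, bounds=fixed_bounds.get("aspt"))
    biotic = (ambi_score + aspt_score) / 2.0

    # habitat: raw index scores against their declared maxima
    habitat_names = sorted({n for s in samples for n in s.habitat_raw})
    habitat_cols = []
    for name in habitat_names:
        raw = np.array([s.habitat_raw[name] for s in samples], dtype=float)
        top = np.array([s.habitat_max[name] for s in samples], dtype=float)
        habitat_cols.append(raw / top)
    habitat = np.mean(habitat_cols, axis=0)

    # physical-chemical: deviation from reference, inverted so 1 = best
    phys_cols = []
    params = sorted({p for s in samples for p in s.physchem})
    for param in params:
        devs = np.array(
            [
                physchem_deviation(
                    s.physchem[param], references.reference_for(param, s.elevation)
                )
                for s in samples
            ]
        )
        phys_cols.append(
            normalize_parameter(devs, invert=True, bounds=fixed_bounds.get(param))
        )
    if not phys_cols:
        raise ValueError("no physical-chemical parameters measured")
    physchem = np.mean(phys_cols, axis=0)

    arith = np.array(
        [compute_eii(c, WEIGHTS_ARITHMETIC) for c in zip(biotic, habitat, physchem)]
    )
    weighted = np.array(
        [compute_eii(c, WEIGHTS_BIOTIC) for c in zip(biotic, habitat, physchem)]
    )
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in samples],
            "x": [s.x for s in samples],
            "y": [s.y for s in samples],
            "elevation": [s.elevation for s in samples],
            "ambi": ambi,
            "aspt": aspt,
            "n_families": nfam,
            "biotic": biotic,
            "habitat": habitat,
            "physchem": physchem,
            "eii_arithmetic": arith,
            "eii_weighted": weighted,
        }
    )
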