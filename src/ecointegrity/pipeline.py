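"""Pipeline orchestration: config validation, scenario runs, run manifests.

Four scenarios link threat surfaces to the integrity response:
``a`` local scale, threat predictors only; ``b`` local scale, threats
plus environment (elevation, slope); ``c`` microbasin scale, threats
only; ``d`` microbasin scale, threats plus environment.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geoio import write_ascii_grid, write_feature_collection, write_polygon_collection
from .grids import GridSpec
from .modeling import (
    SelectionConfig,
    cross_validate,
    predict_surface,
    predict_table,
    scale_predictors,
    select_best,
)
from .spatial import (
    SpatialWeightSpec,
    aggregate_microbasins,
    assign_sites_to_microbasins,
    make_rect_microbasins,
    morans_i,
)
from .synthetic import ENV_NAMES, SyntheticConfig, make_landscape
from .threats import THREAT_NAMES, ThreatRegistry, default_registry

__all__ = [
    "PipelineConfig",
    "load_config",
    "validate_config",
    "run_scenario",
    "write_manifest",
]

SCENARIOS = ("a", "b", "c", "d")
LOCAL_SCENARIOS = ("a", "b")
ENV_SCENARIOS = ("b", "d")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see data/default_config.yaml)."""

    seed: int = 0
    output_dir: str = "out"
    scenario: str = "b"
    grid: GridSpec = field(default_factory=GridSpec)
    simulation: dict = field(default_factory=dict)
    selection: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)
    moran: dict = field(default_factory=dict)
    microbasins: dict = field(default_factory=lambda: {"nx": 7, "ny": 7})
    registry_path: str | None = None

    def max_terms(self) -> int:
        explicit = self.selection.get("max_terms")
        if explicit is not None:
            return int(explicit)
        return 7 if self.scenario in LOCAL_SCENARIOS else 2

    def selection_config(self) -> SelectionConfig:
        return SelectionConfig(
            max_terms=self.max_terms(),
            collinearity_threshold=float(
                self.selection.get("collinearity_threshold", 0.7)
            ),
        )

    def synthetic_config(self) -> SyntheticConfig:
        sim = self.simulation
        kwargs = dict(
            extent_km=(self.grid.width / 1000.0, self.grid.height / 1000.0),
            pixel_size_m=self.grid.pixel_size,
            n_sites=int(sim.get("n_sites", 140)),
            beta0=float(sim.get("beta0", 0.738)),
            sigma=sim.get("sigma"),
            target_r2=float(sim.get("target_r2", 0.25)),
            seed=int(sim.get("seed", self.seed)),
        )
        if sim.get("beta"):
            kwargs["beta"] = {k: float(v) for k, v in sim["beta"].items()}
        return SyntheticConfig(**kwargs)

    def weight_spec(self) -> SpatialWeightSpec:
        return SpatialWeightSpec(
            scheme=self.moran.get("scheme", "inverse_distance"),
            band=self.moran.get("band"),
            row_standardize=bool(self.moran.get("row_standardize", False)),
        )


def default_config_text() -> str:
    ref = importlib.resources.files("ecointegrity.data") / "default_config.yaml"
    return ref.read_text()


def load_config(path=None) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text() if path else default_config_text())
    errors = validate_config(raw)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(f"- {e}" for e in errors))
    grid = GridSpec(**{k: raw["grid"][k] for k in raw.get("grid", {})})
    return PipelineConfig(
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "out")),
        scenario=str(raw.get("scenario", "b")),
        grid=grid,
        simulation=dict(raw.get("simulation") or {}),
        selection=dict(raw.get("selection") or {}),
        cv=dict(raw.get("cv") or {}),
        moran=dict(raw.get("moran") or {}),
        microbasins=dict(raw.get("microbasins") or {"nx": 7, "ny": 7}),
        registry_path=raw.get("registry_path"),
    )


def validate_config(raw: dict) -> list[str]:
    """Aggregate every config problem rather than failing fast."""
    errors: list[str] = []
    if not isinstance(raw, dict):
        return ["config root must be a mapping"]
    scenario = raw.get("scenario", "b")
    if scenario not in SCENARIOS:
        errors.append(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    grid = raw.get("grid") or {}
    if grid.get("pixel_size", 500.0) <= 0:
        errors.append("grid.pixel_size must be > 0")
    for axis in ("ncols", "nrows"):
        if grid.get(axis, 100) < 2:
            errors.append(f"grid.{axis} must be >= 2")
    for key in ("seed",):
        if key in raw and not isinstance(raw[key], int):
            errors.append(f"{key} must be an integer")
    sim = raw.get("simulation") or {}
    if sim.get("n_sites", 140) < 2:
        errors.append("simulation.n_sites must be >= 2")
    if sim.get("sigma") is not None and sim["sigma"] < 0:
        errors.append("simulation.sigma must be >= 0")
    sel = raw.get("selection") or {}
    if sel.get("max_terms") is not None and sel["max_terms"] < 0:
        errors.append("selection.max_terms must be >= 0")
    thr = sel.get("collinearity_threshold", 0.7)
    if not (0 < thr <= 1):
        errors.append("selection.collinearity_threshold must be in (0, 1]")
    cv = raw.get("cv") or {}
    if cv.get("k", 7) < 2:
        errors.append("cv.k must be >= 2")
    if cv.get("repeats", 20) < 1:
        errors.append("cv.repeats must be >= 1")
    if "seed" in cv and not isinstance(cv["seed"], int):
        errors.append("cv.seed must be an integer")
    moran = raw.get("moran") or {}
    if moran.get("scheme", "inverse_distance") not in (
        "inverse_distance",
        "distance_band",
        "rook",
    ):
        errors.append(f"moran.scheme unknown: {moran.get('scheme')!r}")
    registry_path = raw.get("registry_path")
    if registry_path is not None and not Path(registry_path).exists():
        errors.append(f"registry_path does not exist: {registry_path}")
    else:
        try:
            registry = (
                default_registry()
                if registry_path is None
                else ThreatRegistry.from_yaml(registry_path)
            )
            unknown = set(registry.threats) - set(THREAT_NAMES)
            if unknown:
                errors.append(f"registry contains unknown threats: {sorted(unknown)}")
        except Exception as exc:  # aggregated, not fail-fast
            errors.append(f"registry unreadable: {exc}")
    return errors


# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(outdir: Path, config_snapshot: dict, warnings_log: list[str]) -> Path:
    files = sorted(
        p for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package_version": __version__,
        "config": config_snapshot,
        "outputs": {p.name: _sha256(p) for p in files},
        "warnings": warnings_log,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def write_landscape(landscape, outdir: Path) -> None:
    """Persist a synthetic landscape as GeoJSON/ASCII-grid/CSV fixtures."""
    outdir.mkdir(parents=True, exist_ok=True)
    write_feature_collection(outdir / "features.geojson", landscape.features)
    write_ascii_grid(outdir / "elevation.asc", landscape.grid, landscape.elevation)
    write_ascii_grid(outdir / "slope.asc", landscape.grid, landscape.slope)
    for name, surface in landscape.surfaces.items():
        write_ascii_grid(outdir / f"threat_{name}.asc", landscape.grid, surface.values)
    sites = landscape.sites.copy()
    for colname in landscape.predictors.columns:
        sites[f"pred_{colname}"] = landscape.predictors[colname].to_numpy()
    sites["eii"] = landscape.eii
    sites.to_csv(outdir / "sites.csv", index=False)
    truth = {
        "beta0": landscape.config.beta0,
        "beta": landscape.config.beta,
        "sigma": landscape.sigma,
        "n_clamped": landscape.n_clamped,
        "env_ranges": {k: list(v) for k, v in landscape.env_ranges.items()},
    }
    (outdir / "true_model.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


def run_scenario(config: PipelineConfig, scenario: str | None = None) -> dict:
    """Run one modeling scenario end-to-end on a synthetic landscape.

    Stages: threat mapping -> response -> (optional microbasin
    aggregation) -> predictor scaling -> all-subsets selection -> repeated
    k-fold CV -> projection.  Writes all artifacts plus a manifest under
    ``config.output_dir`` and returns the scenario report.
    """
    scenario = scenario or config.scenario
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    warn_log: list[str] = []

    def _stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        landscape = _stage("simulate")(make_landscape, config.synthetic_config())
        _stage("write-landscape")(write_landscape, landscape, outdir)
        if landscape.n_clamped:
            warn_log.append(f"{landscape.n_clamped} simulated response values clamped")

        coords = landscape.sites[["x", "y"]].to_numpy()
        moran = _stage("moran")(
            morans_i, landscape.eii, coords, config.weight_spec()
        )

        predictor_names = list(THREAT_NAMES)
        if scenario in ENV_SCENARIOS:
            predictor_names += list(ENV_NAMES)

        if scenario in LOCAL_SCENARIOS:
            table = landscape.predictors[predictor_names].copy()
            response = landscape.eii
            unit = "pixel"
            n_units = len(table)
        else:
            nx, ny = int(config.microbasins["nx"]), int(config.microbasins["ny"])
            ids, polys = make_rect_microbasins(landscape.grid, nx, ny)
            write_polygon_collection(outdir / "microbasins.geojson", ids, polys)
            membership, unassigned = assign_sites_to_microbasins(coords, ids, polys)
            if unassigned:
                warn_log.append(f"{len(unassigned)} site(s) outside all microbasins")
            rasters = {t: landscape.surfaces[t].values for t in THREAT_NAMES}
            rasters["elevation"] = landscape.elevation
            rasters["slope"] = landscape.slope
            mb = _stage("aggregate")(
                aggregate_microbasins,
                landscape.eii,
                membership,
                ids,
                polys,
                landscape.grid,
                rasters,
            )
            mb.to_csv(outdir / "microbasins.csv", index=False)
            sampled = mb.dropna(subset=["eii"])
            table = sampled[predictor_names].reset_index(drop=True)
            response = sampled["eii"].to_numpy()
            unit = "microbasin"
            n_units = len(sampled)

        scaled, scaling = _stage("scale")(scale_predictors, table)
        best, aicc_table = _stage("select")(
            select_best, response, scaled, config.selection_config()
        )
        aicc_table.to_csv(outdir / "aicc_table.csv", index=False)

        cv = _stage("cv")(
            cross_validate,
            response,
            scaled,
            best.subset,
            int(config.cv.get("k", 7)),
            int(config.cv.get("repeats", 20)),
            int(config.cv.get("seed", config.seed)),
        )
        pd.DataFrame(
            cv.scores,
            columns=[f"fold_{i}" for i in range(cv.k)],
        ).to_csv(outdir / "cv_scores.csv", index=False)

        if scenario in LOCAL_SCENARIOS:
            rasters = {t: landscape.surfaces[t].values for t in THREAT_NAMES}
            lo_e, hi_e = landscape.env_ranges["elevation"]
            lo_s, hi_s = landscape.env_ranges["slope"]
            rasters["elevation"] = (landscape.elevation - lo_e) / (hi_e - lo_e)
            rasters["slope"] = (landscape.slope - lo_s) / (hi_s - lo_s)
            prediction, n_clamped = _stage("predict")(
                predict_surface, best, rasters, scaling
            )
            write_ascii_grid(outdir / "prediction.asc", landscape.grid, prediction)
        else:
            pred_in = mb[predictor_names]
            prediction, n_clamped = _stage("predict")(predict_table, best, pred_in, scaling)
            out = mb[["microbasin_id"]].copy()
            out["predicted_eii"] = prediction
            out.to_csv(outdir / "prediction.csv", index=False)
        if n_clamped:
            warn_log.append(f"{n_clamped} predicted values clamped to [0, 1]")

        warn_log.extend(str(w.message) for w in caught)

    report = {
        "scenario": scenario,
        "unit": unit,
        "n": int(n_units),
        "moran": moran,
        "selected_variables": list(best.subset),
        "intercept": best.intercept,
        "coefficients": best.coefficients,
        "coefficient_se": best.coefficient_se,
        "aicc": best.aicc,
        "r2_insample": best.r2_insample,
        "cv_mean_r2": cv.mean_r2,
        "cv_sd_r2": cv.sd_r2,
        "cv_k": cv.k,
        "cv_repeats": cv.repeats,
        "n_candidates": int(len(aicc_table)),
        "warnings": warn_log,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    snapshot = {
        "seed": config.seed,
        "scenario": scenario,
        "grid": asdict(config.grid),
        "simulation": config.simulation,
        "selection": config.selection,
        "cv": config.cv,
        "moran": config.moran,
        "microbasins": config.microbasins,
    }
    write_manifest(outdir, snapshot, warn_log)
    return report
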