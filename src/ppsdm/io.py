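"""Readers, writers, configuration schema, and the pipeline driver.

Interchange is deliberately plain: CSV for tables (observations, domains,
index series), GeoJSON for protected-area polygons, YAML/JSON for run
configuration with a versioned, strictly validated schema, and a JSON
manifest with content hashes for every artifact a pipeline run writes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator
from shapely.geometry import Polygon, shape

from .synthetic_survey import (
    BathymetryProfile,
    PredictionGrid,
    SimulationParams,
    SurveyDomain,
)

__all__ = [
    "OBS_COLUMNS",
    "read_observations",
    "write_observations",
    "write_domain",
    "read_domain",
    "read_polygons_geojson",
    "RunConfig",
    "load_config",
    "run_pipeline",
]

OBS_COLUMNS = ["year", "easting_km", "northing_km", "depth_m", "cpue_kg_km2"]
DOMAIN_COLUMNS = ["cell_id", "easting_km", "northing_km", "depth_m", "area_km2",
                  "protected"]


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read and validate a survey observation CSV.

    Requires the documented columns (year; planar km coordinates; depth in
    m; CPUE in kg/km²).  Non-numeric or negative-CPUE rows are reported by
    row number (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in OBS_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.where(vals.isna().to_numpy() | ~np.isfinite(vals.to_numpy()))[0]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric or missing {col!r} at rows "
                f"{(bad + 1).tolist()[:10]}"
            )
        df[col] = vals
    neg = np.where(df["cpue_kg_km2"].to_numpy() < 0)[0]
    if len(neg):
        raise ValueError(
            f"{path}: negative cpue_kg_km2 at rows {(neg + 1).tolist()[:10]}"
        )
    df["year"] = df["year"].astype(int)
    return df


def write_observations(obs: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["haul_id", *OBS_COLUMNS, "true_mean", "cell_id"]
            if c in obs.columns]
    obs[cols].to_csv(path, index=False)


def write_domain(domain: SurveyDomain, path: str | Path) -> None:
    domain.cells[DOMAIN_COLUMNS].to_csv(path, index=False)


def read_domain(path: str | Path, cell_size: tuple[float, float]) -> PredictionGrid:
    """Read a domain/grid CSV back as a prediction grid."""
    df = pd.read_csv(path)
    missing = [c for c in DOMAIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df["protected"] = df["protected"].astype(bool)
    return PredictionGrid(cells=df, cell_size=cell_size)


def read_polygons_geojson(path: str | Path) -> list[Polygon]:
    """Read protected-area polygons from a GeoJSON file."""
    data = json.loads(Path(path).read_text())
    feats = data["features"] if data.get("type") == "FeatureCollection" else [data]
    polys = []
    for f in feats:
        geom = shape(f.get("geometry", f))
        if geom.geom_type == "Polygon":
            polys.append(geom)
        elif geom.geom_type == "MultiPolygon":
            polys.extend(geom.geoms)
        else:
            raise ValueError(f"unsupported geometry type {geom.geom_type}")
    return polys


# ---------------------------------------------------------------------------
# Configuration schema (versioned, unknown keys rejected)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BathymetryConfig(_Strict):
    d_min: float = 60.0
    d_max: float = 1270.0
    break_km: float = 45.0
    width_km: float = 12.0
    alongshore_amp_km: float = 8.0
    alongshore_wavelength_km: float = 350.0
    alongshore_phase: float = 0.0
    flat: float | None = None

    def build(self) -> BathymetryProfile:
        return BathymetryProfile(**self.model_dump())


class DomainConfig(_Strict):
    n_east_cells: int = 36
    n_north_cells: int = 270
    cell_size: tuple[float, float] = (2.8, 3.7)
    bathymetry: BathymetryConfig = Field(default_factory=BathymetryConfig)
    protected_geojson: str | None = None


class SimulationConfig(_Strict):
    b0: float = 2.2
    b_depth1: float = 0.9
    b_depth2: float = -0.6
    b_north: float = 0.0
    sigma_omega: float = 0.8
    range_omega: float = 40.0
    sigma_eps: float = 0.4
    range_eps: float = 40.0
    phi_ar1: float = 0.3
    tweedie_p: float = 1.5
    tweedie_disp: float = 4.0
    st_mode: str = "none"
    n_years: int = 16
    stations_per_year: int = 400
    first_year: int = 2003
    n_sim_knots: int = 150

    @field_validator("st_mode")
    @classmethod
    def _check_mode(cls, v: str) -> str:
        if v not in ("none", "iid", "ar1"):
            raise ValueError(f"st_mode must be none|iid|ar1, got {v!r}")
        return v

    def build(self, seed: int) -> SimulationParams:
        return SimulationParams(seed=seed, **self.model_dump())


class ModelConfig(_Strict):
    include_depth: bool = True
    st_mode: str = "none"
    share_range: bool = True
    n_knots: int = 80
    knot_seed: int = 0
    n_starts: int = 2
    maxiter: int = 200
    compute_se: bool = True

    @field_validator("st_mode")
    @classmethod
    def _check_mode(cls, v: str) -> str:
        if v not in ("none", "iid", "ar1"):
            raise ValueError(f"st_mode must be none|iid|ar1, got {v!r}")
        return v

    def build(self):
        from .estimation import ModelSpec

        return ModelSpec(**self.model_dump())


class ExperimentsConfig(_Strict):
    run: list[str] = Field(default_factory=list)  # subset of structure/extent/resolution
    folds_k: int = 5
    fractions: list[float] = Field(default_factory=lambda: [0.0, 0.05, 0.10, 0.15, 0.20])
    factors: list[int] = Field(default_factory=lambda: [4])
    n_draws: int = 300


class RunConfig(_Strict):
    schema_version: int = 1
    seed: int = 0
    outdir: str = "results/run"
    domain: DomainConfig = Field(default_factory=DomainConfig)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    experiments: ExperimentsConfig = Field(default_factory=ExperimentsConfig)


def load_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML or JSON run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    version = data.get("schema_version", 1)
    if version != 1:
        raise ValueError(f"unsupported config schema_version {version}")
    return RunConfig.model_validate(data)


# ---------------------------------------------------------------------------
# Pipeline


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> fit -> validate -> experiments, as configured.

    Writes every artifact under ``config.outdir`` and a ``manifest.json``
    listing artifacts with content hashes; on a stage failure the partial
    artifacts are preserved and the manifest records the failure point.
    Returns the manifest dict.
    """
    from .decision_experiments import (
        extent_experiment,
        resolution_experiment,
        structure_experiment,
    )
    from .estimation import fit as fit_model
    from .synthetic_survey import make_domain, simulate_fields, simulate_survey
    from .validation import quantile_residuals

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "schema_version": config.schema_version,
                      "artifacts": [], "status": "running", "failed_stage": None}

    def record(path: Path):
        manifest["artifacts"].append(
            {"path": str(path.relative_to(outdir)), "sha256": _sha256(path)}
        )

    def flush():
        p = outdir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2))

    stage = "simulate"
    try:
        polys = (read_polygons_geojson(config.domain.protected_geojson)
                 if config.domain.protected_geojson else None)
        domain = make_domain(
            n_east_cells=config.domain.n_east_cells,
            n_north_cells=config.domain.n_north_cells,
            cell_size=tuple(config.domain.cell_size),
            bathymetry=config.domain.bathymetry.build(),
            protected_polygons=polys,
        )
        params = config.simulation.build(config.seed)
        fields = simulate_fields(domain, params, seed=config.seed)
        obs = simulate_survey(domain, fields, params, seed=config.seed)
        write_domain(domain, outdir / "domain.csv")
        record(outdir / "domain.csv")
        write_observations(obs, outdir / "obs.csv")
        record(outdir / "obs.csv")
        truth = pd.DataFrame({"cell_id": domain.cells["cell_id"],
                              "omega": fields.omega})
        for t, year in enumerate(params.years):
            truth[f"eps_{year}"] = fields.epsilon[t]
        truth.to_csv(outdir / "truth.csv", index=False)
        record(outdir / "truth.csv")

        stage = "fit"
        spec = config.model.build()
        res = fit_model(spec, obs)
        (outdir / "fit.json").write_text(json.dumps(res.to_report(), indent=2))
        record(outdir / "fit.json")

        stage = "validate"
        resid, ks = quantile_residuals(res, obs, n_sims=200, seed=config.seed)
        pd.DataFrame({"residual": resid}).to_csv(outdir / "residuals.csv", index=False)
        record(outdir / "residuals.csv")
        manifest["residual_ks"] = ks

        stage = "experiments"
        grid = domain.to_prediction_grid()
        ex = config.experiments
        if "structure" in ex.run:
            rep = structure_experiment(obs, grid, folds_k=ex.folds_k,
                                       seed=config.seed, n_draws=ex.n_draws)
            for p in rep.write(outdir):
                record(p)
        if "extent" in ex.run:
            rep = extent_experiment(obs, grid, spec,
                                    fractions=tuple(ex.fractions),
                                    seed=config.seed, n_draws=ex.n_draws)
            for p in rep.write(outdir):
                record(p)
        if "resolution" in ex.run:
            rep = resolution_experiment(res, grid, factors=tuple(ex.factors),
                                        seed=config.seed, n_draws=ex.n_draws)
            for p in rep.write(outdir):
                record(p)
    except Exception as err:  # noqa: BLE001 - manifest must record the failure
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(err).__name__}: {err}"
        flush()
        raise
    manifest["status"] = "ok"
    flush()
    return manifest
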