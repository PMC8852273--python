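"""Grid prediction and derived indices: annual biomass and center of gravity.

The fitted model predicts a density surface on a regular grid; the two
management-facing summaries are the annual biomass index

    B_t = sum_g area_g * density_{g,t}        (kg)

and the center of gravity (COG), the density-weighted mean location

    COG_t = sum_g area_g d_{g,t} (E_g, N_g) / sum_g area_g d_{g,t}   (km).

Uncertainty is simulation-based: joint draws of fixed effects from their
asymptotic Gaussian and of random effects from the Gaussian (Laplace)
approximation at the mode, the statistic recomputed per draw.  Biomass
intervals are built on the log scale (positivity), COG on the natural
scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.spatial.distance import cdist

from .estimation import FitResult
from .spatial_fields import MaternParams, chol_with_jitter, matern_cov
from .synthetic_survey import PredictionGrid

__all__ = [
    "DensitySurface",
    "IndexSeries",
    "predict_grid",
    "biomass_index",
    "center_of_gravity",
    "sample_uncertainty",
    "relative_series",
]


@dataclass
class DensitySurface:
    """Predicted density per (cell, year) on a prediction grid."""

    table: pd.DataFrame  # cell_id, year, easting_km, northing_km, area_km2, eta, density
    resolution: str = "fine"

    def years(self) -> np.ndarray:
        return np.sort(self.table["year"].unique())

    def to_geojson(self, path, year: int | None = None) -> None:
        """Write cell centroids with density as GeoJSON points for mapping."""
        import json

        tab = self.table if year is None else self.table[self.table["year"] == year]
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "Point",
                             "coordinates": [row.easting_km, row.northing_km]},
                "properties": {"cell_id": int(row.cell_id), "year": int(row.year),
                               "density_kg_km2": float(row.density),
                               "depth_m": float(row.depth_m)},
            }
            for row in tab.itertuples()
        ]
        from pathlib import Path

        Path(path).write_text(json.dumps(
            {"type": "FeatureCollection", "features": features}))


@dataclass
class IndexSeries:
    """Per-year estimates with SEs and 95% intervals, in tidy form.

    ``kind`` is "biomass" (single component, kg) or "cog" (components
    "east" and "north", km).  Columns: year, component, estimate, se,
    lwr, upr.
    """

    kind: str
    table: pd.DataFrame

    def component(self, name: str) -> pd.DataFrame:
        return self.table[self.table["component"] == name].reset_index(drop=True)


def _grid_weights(fit: FitResult, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kriging weight matrices from the fit's knots to new locations."""
    dist = cdist(coords, fit.knots.coords)
    dist_kk = cdist(fit.knots.coords, fit.knots.coords)
    mp = MaternParams(range_km=fit.theta["range_omega"], sigma=fit.theta["sigma_omega"])
    C_kk = matern_cov(dist_kk, mp)
    factor, _ = chol_with_jitter(C_kk, mp.sigma**2)
    from scipy.linalg import cho_solve

    A_om = cho_solve(factor, matern_cov(dist, mp).T).T
    A_eps = A_om
    if fit.spec.st_mode != "none" and not fit.spec.share_range:
        mp_e = MaternParams(range_km=fit.theta["range_eps"], sigma=fit.theta["sigma_eps"])
        fe, _ = chol_with_jitter(matern_cov(dist_kk, mp_e), mp_e.sigma**2)
        A_eps = cho_solve(fe, matern_cov(dist, mp_e).T).T
    return A_om, A_eps


def predict_grid(
    fit: FitResult,
    grid: PredictionGrid,
    years: int | list[int] | None = None,
    resolution: str = "fine",
) -> DensitySurface:
    """Predict density on the unmasked cells of a grid for one or all years.

    eta_g = x_g' b + (A u_omega)_g + (A u_eps[t])_g, density = exp(eta_g),
    with the fit's own depth standardization reused.  Warns when grid
    depths extend more than 20% beyond the fitted depth range.
    """
    cells = grid.unmasked()
    if len(cells) == 0:
        raise ValueError("prediction grid has no unmasked cells")
    if years is None:
        years = list(fit.design.years)
    elif np.isscalar(years):
        years = [int(years)]
    if fit.design.has_depth:
        lo, hi = _fitted_depth_range(fit)
        span = hi - lo
        gd = cells["depth_m"]
        if gd.min() < lo - 0.2 * span or gd.max() > hi + 0.2 * span:
            warnings.warn("extrapolation: grid depths extend well beyond the "
                          "fitted depth range", stacklevel=2)
    coords = cells[["easting_km", "northing_km"]].to_numpy()
    # a grid in a different coordinate frame sits far outside the knot
    # extent (mere extrapolation beyond the knots is allowed)
    klo, khi = fit.knots.coords.min(axis=0), fit.knots.coords.max(axis=0)
    diag = float(np.linalg.norm(khi - klo))
    gap = np.maximum(0.0, np.maximum(klo - coords.max(axis=0),
                                     coords.min(axis=0) - khi))
    if float(np.linalg.norm(gap)) > 5.0 * diag + 50.0:
        raise ValueError(
            "grid/fit coordinate-system mismatch: grid extent "
            f"E[{coords[:, 0].min():.0f},{coords[:, 0].max():.0f}] "
            f"N[{coords[:, 1].min():.0f},{coords[:, 1].max():.0f}] km lies far "
            "outside the fitted knots"
        )
    A_om, A_eps = _grid_weights(fit, coords)
    om = A_om @ fit.u_omega
    frames = []
    for year in years:
        t = int(np.searchsorted(fit.design.years, year))
        X = fit.design.row_for(year, cells["depth_m"].to_numpy())
        eta = X @ fit.b + om
        if fit.spec.st_mode != "none":
            eta = eta + A_eps @ fit.u_eps[t]
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": cells["cell_id"].to_numpy(),
                    "year": year,
                    "easting_km": cells["easting_km"].to_numpy(),
                    "northing_km": cells["northing_km"].to_numpy(),
                    "area_km2": cells["area_km2"].to_numpy(),
                    "depth_m": cells["depth_m"].to_numpy(),
                    "eta": eta,
                    "density": np.exp(eta),
                }
            )
        )
    return DensitySurface(table=pd.concat(frames, ignore_index=True),
                          resolution=resolution)


def _fitted_depth_range(fit: FitResult) -> tuple[float, float]:
    # reconstruct the fitted standardized-depth support from the stored
    # constants; +-3 SD covers the design by construction
    m, s = fit.design.depth_mean, fit.design.depth_sd
    return m - 3 * s, m + 3 * s


def biomass_index(surface: DensitySurface) -> IndexSeries:
    """Annual biomass: area-weighted sum of predicted density (kg)."""
    tab = surface.table
    if len(tab) == 0:
        raise ValueError("empty density surface")
    g = tab.groupby("year", sort=True)
    est = g.apply(lambda d: float(np.sum(d["area_km2"] * d["density"])),
                  include_groups=False)
    out = pd.DataFrame(
        {"year": est.index.to_numpy(), "component": "biomass",
         "estimate": est.to_numpy(), "se": np.nan, "lwr": np.nan, "upr": np.nan}
    )
    return IndexSeries(kind="biomass", table=out)


def center_of_gravity(surface: DensitySurface) -> IndexSeries:
    """Annual density-weighted mean Eastings and Northings (km)."""
    tab = surface.table
    if len(tab) == 0:
        raise ValueError("empty density surface")
    rows = []
    for year, d in tab.groupby("year", sort=True):
        w = (d["area_km2"] * d["density"]).to_numpy()
        tot = w.sum()
        if tot <= 0:
            raise ValueError(f"zero total density in year {year}")
        rows.append((year, "east", float(np.sum(w * d["easting_km"]) / tot)))
        rows.append((year, "north", float(np.sum(w * d["northing_km"]) / tot)))
    out = pd.DataFrame(rows, columns=["year", "component", "estimate"])
    out["se"] = np.nan
    out["lwr"] = np.nan
    out["upr"] = np.nan
    return IndexSeries(kind="cog", table=out)


def relative_series(series: IndexSeries) -> IndexSeries:
    """Standardize a biomass series (and its interval) to its maximum."""
    tab = series.table.copy()
    m = tab["estimate"].max()
    for col in ("estimate", "se", "lwr", "upr"):
        tab[col] = tab[col] / m
    return IndexSeries(kind=series.kind, table=tab)


def sample_uncertainty(
    fit: FitResult,
    grid: PredictionGrid,
    statistic: str = "biomass",
    n_draws: int = 500,
    seed: int = 0,
    b_cov: np.ndarray | None = None,
    u_chol: np.ndarray | None = None,
) -> IndexSeries:
    """Simulation-based SEs and 95% intervals for biomass or COG.

    Draws fixed effects from N(b_hat, cov) and random effects from
    N(mode, inverse inner Hessian), recomputes the statistic per draw.
    ``statistic='relative_biomass'`` standardizes each draw's biomass
    series to its own maximum before summarizing — the scale the relative-
    index figures report, in which uncertainty common to all years
    cancels.  ``b_cov`` / ``u_chol`` override the fit's own curvature
    (test hooks; ``u_chol`` is a factor S with random-effect covariance
    S S').  Deterministic per seed.
    """
    if statistic not in ("biomass", "cog", "relative_biomass"):
        raise ValueError("statistic must be 'biomass', 'relative_biomass' or 'cog'")
    nb = len(fit.b)
    if b_cov is None:
        if fit.param_cov is None:
            raise ValueError("fit has no parameter covariance; refit with compute_se=True")
        b_cov = fit.param_cov[:nb, :nb]
    # random-effect draw factor: Hpos = L L' -> cov = L'^-1 L^-1, draws via
    # solving L' x = z
    L_inner = np.tril(fit.inner_hess_cho[0]) if fit.inner_hess_cho is not None else None

    cells = grid.unmasked()
    coords = cells[["easting_km", "northing_km"]].to_numpy()
    A_om, A_eps = _grid_weights(fit, coords)
    areas = cells["area_km2"].to_numpy()
    east = cells["easting_km"].to_numpy()
    north = cells["northing_km"].to_numpy()
    years = fit.design.years
    X_by_year = [fit.design.row_for(y, cells["depth_m"].to_numpy()) for y in years]

    rng = np.random.default_rng(np.random.SeedSequence((seed, 40_009)))
    # symmetric square root of b_cov (tolerates exactly singular hooks)
    evals, evecs = np.linalg.eigh(0.5 * (b_cov + b_cov.T))
    b_fac = evecs * np.sqrt(np.clip(evals, 0.0, None))

    k = fit.knots.n_knots
    dim_u = k + (len(years) * k if fit.spec.st_mode != "none" else 0)
    u_mode = np.concatenate([fit.u_omega, fit.u_eps.ravel()])

    stats = {y: [] for y in years}
    for _ in range(n_draws):
        b_draw = fit.b + b_fac @ rng.standard_normal(nb)
        if u_chol is not None:
            u_draw = u_mode + u_chol @ rng.standard_normal(dim_u)
        elif L_inner is not None:
            z = rng.standard_normal(dim_u)
            u_draw = u_mode + solve_triangular(L_inner.T, z, lower=False)
        else:
            u_draw = u_mode
        om = A_om @ u_draw[:k]
        series = []
        for t, y in enumerate(years):
            eta = X_by_year[t] @ b_draw + om
            if fit.spec.st_mode != "none":
                eta = eta + A_eps @ u_draw[k + t * k: k + (t + 1) * k]
            dens = np.exp(eta)
            w = areas * dens
            if statistic == "cog":
                tot = w.sum()
                stats[y].append((np.sum(w * east) / tot, np.sum(w * north) / tot))
            else:
                series.append(w.sum())
        if statistic != "cog":
            series = np.asarray(series)
            if statistic == "relative_biomass":
                series = series / series.max()
            for t, y in enumerate(years):
                stats[y].append(series[t])

    surface = predict_grid(fit, grid)
    if statistic == "cog":
        point = center_of_gravity(surface)
    else:
        point = biomass_index(surface)
        if statistic == "relative_biomass":
            point = relative_series(point)
            point.table["component"] = "relative_biomass"
    tab = point.table.copy()
    z95 = 1.959963984540054
    for y in years:
        draws = np.asarray(stats[y])
        if statistic in ("biomass", "relative_biomass"):
            est = float(tab.loc[tab["year"] == y, "estimate"].iloc[0])
            se = float(np.std(draws, ddof=1))
            sd_log = float(np.std(np.log(np.maximum(draws, 1e-300)), ddof=1))
            sel = tab["year"] == y
            tab.loc[sel, "se"] = se
            tab.loc[sel, "lwr"] = est * np.exp(-z95 * sd_log)
            tab.loc[sel, "upr"] = est * np.exp(z95 * sd_log)
        else:
            for j, comp in enumerate(("east", "north")):
                est = float(
                    tab.loc[(tab["year"] == y) & (tab["component"] == comp),
                            "estimate"].iloc[0]
                )
                se = float(np.std(draws[:, j], ddof=1))
                sel = (tab["year"] == y) & (tab["component"] == comp)
                tab.loc[sel, "se"] = se
                tab.loc[sel, "lwr"] = est - z95 * se
                tab.loc[sel, "upr"] = est + z95 * se
    return IndexSeries(kind=point.kind, table=tab)
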