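"""Synthetic coastal trawl-survey generator.

Emulates the sampling situation of a fishery-independent bottom-trawl
survey on a long, narrow continental shelf: a rectangular lattice of cells
over a domain roughly 100 km across-shore by 1,000 km along-shore, depth
increasing offshore from ~55 m across a logistic shelf break down to
~1,280 m, a time-constant spatial field plus optional IID or AR(1)
per-year spatiotemporal fields on the log-density scale, a quadratic
effect of standardized depth, and Tweedie-distributed CPUE (kg/km²)
observed at stratified-random stations each year.  Optional polygonal
"protected areas" are never sampled and are masked out of prediction
grids.

Everything is deterministic given ``(params, seed)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .spatial_fields import MaternParams, chol_with_jitter, matern_cov, project, select_knots

__all__ = [
    "BathymetryProfile",
    "SurveyDomain",
    "PredictionGrid",
    "SimulationParams",
    "TrueFields",
    "make_domain",
    "simulate_fields",
    "simulate_survey",
    "default_params",
]


@dataclass(frozen=True)
class BathymetryProfile:
    """Parametric cross-shore depth profile with a logistic shelf break.

    Depth at offshore distance x (km):

        d(x, y) = d_min + (d_max - d_min) * expit((x - x0(y)) / width)

    with the break location meandering smoothly along-shore,
    ``x0(y) = break_km + amp * sin(2 pi y / wavelength + phase)``.
    ``flat`` (m) overrides everything with a constant depth — useful for
    tests.
    """

    d_min: float = 60.0
    d_max: float = 1270.0
    break_km: float = 45.0
    width_km: float = 12.0
    alongshore_amp_km: float = 8.0
    alongshore_wavelength_km: float = 350.0
    alongshore_phase: float = 0.0
    flat: float | None = None

    def depth(self, easting_km, northing_km):
        if self.flat is not None:
            return np.full_like(np.asarray(easting_km, dtype=float), self.flat)
        from scipy.special import expit

        x0 = self.break_km + self.alongshore_amp_km * np.sin(
            2.0 * np.pi * np.asarray(northing_km) / self.alongshore_wavelength_km
            + self.alongshore_phase
        )
        z = (np.asarray(easting_km, dtype=float) - x0) / self.width_km
        return self.d_min + (self.d_max - self.d_min) * expit(z)


@dataclass
class SurveyDomain:
    """Rectangular lattice of survey cells with depth and protected mask."""

    cells: pd.DataFrame  # cell_id, easting_km, northing_km, depth_m, area_km2, protected
    extent: tuple[float, float, float, float]  # E_min, E_max, N_min, N_max
    cell_size: tuple[float, float]
    protected_polygons: list[Polygon] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def coords(self) -> np.ndarray:
        return self.cells[["easting_km", "northing_km"]].to_numpy()

    def sampleable(self) -> pd.DataFrame:
        return self.cells[~self.cells["protected"]]

    def to_prediction_grid(self) -> "PredictionGrid":
        return PredictionGrid(cells=self.cells.copy(), cell_size=self.cell_size)


@dataclass
class PredictionGrid:
    """Prediction surface: cell centroids, depth, area, protected mask."""

    cells: pd.DataFrame  # same columns as SurveyDomain.cells
    cell_size: tuple[float, float]

    @property
    def coords(self) -> np.ndarray:
        return self.cells[["easting_km", "northing_km"]].to_numpy()

    def unmasked(self) -> pd.DataFrame:
        return self.cells[~self.cells["protected"]]


def make_domain(
    n_east_cells: int = 36,
    n_north_cells: int = 270,
    cell_size: tuple[float, float] = (2.8, 3.7),
    bathymetry: BathymetryProfile | None = None,
    protected_polygons: list[Polygon] | None = None,
) -> SurveyDomain:
    """Build a rectangular survey lattice with bathymetry and protected areas.

    Defaults give a 36 x 270 grid of 2.8 x 3.7 km cells (about 100.8 by
    999 km), the scale of a US West Coast shelf survey frame.  Cells whose
    centroid lies inside a protected polygon are flagged; an entirely
    protected domain is an error.
    """
    if n_east_cells < 2 or n_north_cells < 2:
        raise ValueError("need at least 2 cells per axis")
    dE, dN = cell_size
    if dE <= 0 or dN <= 0:
        raise ValueError("cell sizes must be positive")
    bathymetry = bathymetry or BathymetryProfile()
    e = (np.arange(n_east_cells) + 0.5) * dE
    n = (np.arange(n_north_cells) + 0.5) * dN
    E, N = np.meshgrid(e, n, indexing="ij")
    E, N = E.ravel(), N.ravel()
    depth = np.asarray(bathymetry.depth(E, N), dtype=float)
    if np.any(depth <= 0) or depth.min() < 50 or depth.max() > 1300:
        raise ValueError(
            f"bathymetry out of the survey's depth envelope: "
            f"[{depth.min():.1f}, {depth.max():.1f}] m"
        )
    protected = np.zeros(E.shape, dtype=bool)
    for poly in protected_polygons or []:
        inside = np.fromiter(
            (poly.contains(Point(x, y)) for x, y in zip(E, N)),
            dtype=bool, count=len(E),
        )
        protected |= inside
    if protected.all():
        raise ValueError("empty sampleable domain: protected polygons cover every cell")
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(E.size),
            "easting_km": E,
            "northing_km": N,
            "depth_m": depth,
            "area_km2": dE * dN,
            "protected": protected,
        }
    )
    extent = (0.0, n_east_cells * dE, 0.0, n_north_cells * dN)
    return SurveyDomain(
        cells=cells, extent=extent, cell_size=(dE, dN),
        protected_polygons=list(protected_polygons or []),
    )


@dataclass(frozen=True)
class SimulationParams:
    """True parameter values driving the synthetic survey.

    Defaults are calibrated so simulated surveys resemble the published
    sablefish situation: occurrence near 0.65, AR(1) autocorrelation in the
    0.2–0.4 band, Matérn ranges of a few tens of km, a dome-shaped depth
    response peaking seaward of the shelf break, and 16 annual surveys.
    """

    b0: float = 2.2
    b_depth1: float = 0.9
    b_depth2: float = -0.6
    b_north: float = 0.0  # linear along-shore trend (gradient-bearing populations)
    year_effects: tuple[float, ...] | None = None  # defaults to zeros
    sigma_omega: float = 0.8
    range_omega: float = 40.0
    sigma_eps: float = 0.4
    range_eps: float = 40.0
    phi_ar1: float = 0.3
    tweedie_p: float = 1.5
    tweedie_disp: float = 4.0
    st_mode: str = "none"  # none | iid | ar1
    n_years: int = 16
    stations_per_year: int = 400
    first_year: int = 2003
    n_sim_knots: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_omega", "range_omega", "sigma_eps", "range_eps",
                     "tweedie_disp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (1.0 < self.tweedie_p < 2.0):
            raise ValueError("tweedie_p must lie in (1, 2)")
        if not abs(self.phi_ar1) < 1:
            raise ValueError("|phi_ar1| must be < 1")
        if self.st_mode not in ("none", "iid", "ar1"):
            raise ValueError(f"unknown st_mode {self.st_mode!r}")
        if self.n_years < 1 or self.stations_per_year < 1:
            raise ValueError("n_years and stations_per_year must be >= 1")
        if self.year_effects is not None and len(self.year_effects) != self.n_years:
            raise ValueError("year_effects length must equal n_years")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.n_years)

    def year_effect_array(self) -> np.ndarray:
        if self.year_effects is None:
            return np.zeros(self.n_years)
        return np.asarray(self.year_effects, dtype=float)


def default_params(**overrides) -> SimulationParams:
    """The study-condition defaults, with keyword overrides."""
    return replace(SimulationParams(), **overrides) if overrides else SimulationParams()


@dataclass
class TrueFields:
    """True latent fields on the domain lattice."""

    omega: np.ndarray  # (n_cells,)
    epsilon: np.ndarray  # (n_years, n_cells); zeros when st_mode == "none"
    params: SimulationParams


def _draw_field(
    coords: np.ndarray,
    mp: MaternParams,
    n_draws: int,
    n_knots: int,
    rng: np.random.Generator,
    knot_seed: int,
) -> np.ndarray:
    """Draw Matérn GP realisations via the knot machinery.

    The field is the predictive-process projection of a dense draw at the
    knots plus independent residuals with the exact conditional variance,
    so every cell's marginal variance is sigma^2 exactly and the cost stays
    O(knots^2 * cells).
    """
    n_knots = min(n_knots, np.unique(coords, axis=0).shape[0])
    knots = select_knots(coords, n_knots, seed=knot_seed)
    proj = project(knots, coords, mp)
    from scipy.spatial.distance import cdist

    C_kk = matern_cov(cdist(knots.coords, knots.coords), mp)
    factor, jitter = chol_with_jitter(C_kk, mp.sigma**2)
    L = np.tril(factor[0])
    z = rng.standard_normal((n_draws, knots.n_knots))
    u = z @ L.T
    resid = rng.standard_normal((n_draws, coords.shape[0])) * np.sqrt(proj.cond_var)
    return u @ proj.weights.T + resid


def simulate_fields(
    domain: SurveyDomain, params: SimulationParams, seed: int | None = None
) -> TrueFields:
    """Draw the true spatial and spatiotemporal fields on the lattice.

    omega is a single Matérn draw; epsilon is zero (mode "none"),
    independent per year ("iid"), or a stationary AR(1) chain
    ``eps_t = phi eps_{t-1} + sqrt(1 - phi^2) delta_t`` whose innovations
    are scaled so each year's marginal variance is exactly sigma_eps^2.
    """
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    coords = domain.coords
    mp_om = MaternParams(range_km=params.range_omega, sigma=params.sigma_omega)
    omega = _draw_field(coords, mp_om, 1, params.n_sim_knots, rng, knot_seed=seed % (2**31))[0]
    T, n = params.n_years, domain.n_cells
    if params.st_mode == "none":
        eps = np.zeros((T, n))
    else:
        mp_eps = MaternParams(range_km=params.range_eps, sigma=params.sigma_eps)
        delta = _draw_field(coords, mp_eps, T, params.n_sim_knots, rng,
                            knot_seed=(seed + 1) % (2**31))
        if params.st_mode == "iid":
            eps = delta
        else:
            phi = params.phi_ar1
            eps = np.empty((T, n))
            eps[0] = delta[0]
            for t in range(1, T):
                eps[t] = phi * eps[t - 1] + np.sqrt(1.0 - phi**2) * delta[t]
    return TrueFields(omega=omega, epsilon=eps, params=params)


def _stratum_labels(cells: pd.DataFrame, extent, n_lat: int = 5, n_depth: int = 3):
    """Assign each sampleable cell to a latitude x depth stratum.

    Latitude bands split the along-shore extent into equal slices; depth
    bands are depth terciles of the sampleable cells (quantile cuts), so
    shallow shelf, break, and slope each get coverage.
    """
    _, _, N_min, N_max = extent
    lat_edges = np.linspace(N_min, N_max, n_lat + 1)
    lat_band = np.clip(
        np.searchsorted(lat_edges, cells["northing_km"].to_numpy(), side="right") - 1,
        0, n_lat - 1,
    )
    depth = cells["depth_m"].to_numpy()
    qs = np.quantile(depth, np.linspace(0, 1, n_depth + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    depth_band = np.clip(np.searchsorted(qs, depth, side="right") - 1, 0, n_depth - 1)
    return lat_band * n_depth + depth_band, n_lat * n_depth


def simulate_survey(
    domain: SurveyDomain,
    fields: TrueFields,
    params: SimulationParams,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the observation table for all survey years.

    Stations are allocated equally across 5 latitude x 3 depth strata
    (remainders round-robin), drawn uniformly over each stratum's
    sampleable cells, and observed CPUE is Tweedie about
    ``exp(b0 + year_effect + b1 z + b2 z^2 + omega + eps)`` with z the
    depth standardized over sampleable cells.  Returns a long-format table
    with the true mean retained per record.
    """
    from .observation_model import TweedieParams, tweedie_rvs

    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7_001)))
    samp = domain.sampleable()
    labels, n_strata = _stratum_labels(samp, domain.extent)
    cells_by_stratum = [samp.index.to_numpy()[labels == s] for s in range(n_strata)]
    n_per = np.full(n_strata, params.stations_per_year // n_strata)
    for s in range(params.stations_per_year % n_strata):
        n_per[s] += 1
    empty = [s for s in range(n_strata) if len(cells_by_stratum[s]) == 0]
    if empty:
        orphaned = int(n_per[empty].sum())
        warnings.warn(
            f"strata {empty} have no sampleable cells; reallocating "
            f"{orphaned} stations proportionally", stacklevel=2,
        )
        live = [s for s in range(n_strata) if s not in empty]
        n_per[empty] = 0
        for i in range(orphaned):
            n_per[live[i % len(live)]] += 1

    depth_all = samp["depth_m"].to_numpy()
    zmean, zsd = float(depth_all.mean()), float(depth_all.std())
    if zsd == 0.0:
        zsd = 1.0  # flat bathymetry: standardized depth is identically 0
    north_all = samp["northing_km"].to_numpy()
    nmean, nsd = float(north_all.mean()), max(float(north_all.std()), 1e-12)
    tw = TweedieParams(p=params.tweedie_p, disp=params.tweedie_disp)
    year_eff = params.year_effect_array()
    dE, dN = domain.cell_size

    recs = []
    haul = 0
    for t, year in enumerate(params.years):
        chosen = []
        for s in range(n_strata):
            if n_per[s] == 0:
                continue
            chosen.append(rng.choice(cells_by_stratum[s], size=n_per[s], replace=True))
        idx = np.concatenate(chosen)
        cell = domain.cells.loc[idx]
        pos = cell["cell_id"].to_numpy()
        depth = cell["depth_m"].to_numpy()
        z = (depth - zmean) / zsd
        eta = (
            params.b0
            + year_eff[t]
            + params.b_depth1 * z
            + params.b_depth2 * z**2
            + params.b_north * (cell["northing_km"].to_numpy() - nmean) / nsd
            + fields.omega[pos]
            + fields.epsilon[t, pos]
        )
        mu = np.exp(eta)
        y = tweedie_rvs(mu, tw, rng)
        jx = rng.uniform(-0.5, 0.5, size=len(idx)) * dE
        jy = rng.uniform(-0.5, 0.5, size=len(idx)) * dN
        ex = cell["easting_km"].to_numpy() + jx
        ny = cell["northing_km"].to_numpy() + jy
        # a jittered point in a sampleable cell can still cross a polygon
        # edge that cuts the cell; snap those back to the centroid
        for poly in domain.protected_polygons:
            import shapely

            bad = shapely.contains_xy(poly, ex, ny)
            ex[bad] = cell["easting_km"].to_numpy()[bad]
            ny[bad] = cell["northing_km"].to_numpy()[bad]
        recs.append(
            pd.DataFrame(
                {
                    "haul_id": haul + np.arange(len(idx)),
                    "year": year,
                    "easting_km": ex,
                    "northing_km": ny,
                    "depth_m": depth,
                    "cpue_kg_km2": y,
                    "true_mean": mu,
                    "cell_id": pos,
                }
            )
        )
        haul += len(idx)
    obs = pd.concat(recs, ignore_index=True)
    return obs
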