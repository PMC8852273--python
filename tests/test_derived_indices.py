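"""Grid prediction, biomass, COG, and draw-based uncertainty."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import cho_factor
from shapely.geometry import MultiPoint, Point

from ppsdm.derived_indices import (
    DensitySurface,
    biomass_index,
    center_of_gravity,
    predict_grid,
    relative_series,
    sample_uncertainty,
)
from ppsdm.estimation import FitResult, ModelSpec
from ppsdm.observation_model import build_design
from ppsdm.spatial_fields import KnotSet
from ppsdm.synthetic_survey import PredictionGrid


def make_grid(coords, depth=100.0, area=1.0, protected=None):
    n = len(coords)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "easting_km": [c[0] for c in coords],
            "northing_km": [c[1] for c in coords],
            "depth_m": np.broadcast_to(depth, n).astype(float),
            "area_km2": np.broadcast_to(area, n).astype(float),
            "protected": protected if protected is not None else np.zeros(n, bool),
        }
    )
    return PredictionGrid(cells=cells, cell_size=(1.0, 1.0))


def make_hook_fit(knot_coords, u_omega, b, years=(2003,), include_depth=False,
                  b_cov_scale=0.0, theta=None):
    """Hand-built FitResult for exercising the prediction path."""
    n_per = 3
    obs = pd.DataFrame(
        {
            "year": np.repeat(list(years), n_per),
            "depth_m": np.tile(np.array([80.0, 100.0, 120.0]), len(years)),
            "easting_km": 0.0,
            "northing_km": 0.0,
            "cpue_kg_km2": 1.0,
        }
    )
    design = build_design(obs, include_depth=include_depth)
    k = len(knot_coords)
    knots = KnotSet(coords=np.asarray(knot_coords, float),
                    assignment=np.zeros(k, int), seed=0)
    spec = ModelSpec(include_depth=include_depth, st_mode="none", n_knots=k)
    theta = theta or {"range_omega": 30.0, "sigma_omega": 0.8, "p": 1.5, "disp": 1.0}
    nb = design.X.shape[1]
    return FitResult(
        spec=spec, design=design, knots=knots,
        b=np.asarray(b, float), b_names=list(design.columns),
        b_se=np.zeros(nb), theta=theta, theta_se=None,
        u_omega=np.asarray(u_omega, float), u_eps=np.zeros((len(years), 0)),
        nll=0.0, loglik=0.0, converged=True, n_obs=len(obs),
        param_names=list(design.columns),
        param_cov=b_cov_scale * np.eye(nb),
        inner_hess_cho=cho_factor(np.eye(k) * 1e12, lower=True),
    )


def surface_from(coords, density, area=1.0, year=2003):
    n = len(coords)
    return DensitySurface(
        table=pd.DataFrame(
            {
                "cell_id": np.arange(n),
                "year": year,
                "easting_km": [c[0] for c in coords],
                "northing_km": [c[1] for c in coords],
                "area_km2": np.broadcast_to(area, n).astype(float),
                "depth_m": 100.0,
                "eta": np.log(density),
                "density": np.asarray(density, float),
            }
        )
    )


class TestPredictGrid:
    def test_density_at_knot_is_exponential_of_mode(self):
        knot_coords = [(5.0, 5.0), (20.0, 25.0), (40.0, 10.0)]
        u = [0.7, -0.3, 0.1]
        fitres = make_hook_fit(knot_coords, u, b=[1.2])
        grid = make_grid(knot_coords)
        surf = predict_grid(fitres, grid)
        np.testing.assert_allclose(
            surf.table["density"].to_numpy(),
            np.exp(1.2 + np.array(u)), atol=1e-8,
        )

    def test_all_masked_grid_raises(self):
        fitres = make_hook_fit([(0.0, 0.0), (10.0, 10.0)], [0.0, 0.0], b=[0.0])
        grid = make_grid([(1.0, 1.0), (2.0, 2.0)], protected=np.array([True, True]))
        with pytest.raises(ValueError, match="unmasked"):
            predict_grid(fitres, grid)

    def test_matches_cell_by_cell_recomputation(self, rng):
        from ppsdm.spatial_fields import MaternParams, matern_cov

        knot_coords = rng.uniform(0, 50, size=(6, 2))
        u = rng.normal(0, 0.5, 6)
        fitres = make_hook_fit(knot_coords, u, b=[0.8, 1.1, 0.2, -0.1],
                               years=(2003, 2004), include_depth=True)
        coords = rng.uniform(0, 50, size=(1000, 2))
        depths = rng.uniform(80, 120, size=1000)
        grid = make_grid([tuple(c) for c in coords], depth=depths)
        surf = predict_grid(fitres, grid, years=2004)
        mp = MaternParams(range_km=30.0, sigma=0.8)
        C_kk = matern_cov(
            np.linalg.norm(knot_coords[:, None] - knot_coords[None], axis=2), mp
        )
        dm, ds = fitres.design.depth_mean, fitres.design.depth_sd
        for i in rng.choice(1000, 40, replace=False):
            c = coords[i]
            C_ik = matern_cov(np.linalg.norm(knot_coords - c, axis=1), mp)
            a_i = np.linalg.solve(C_kk, C_ik)
            z = (depths[i] - dm) / ds
            eta = fitres.b[1] + fitres.b[2] * z + fitres.b[3] * z**2 + a_i @ u
            assert surf.table["eta"].iloc[i] == pytest.approx(eta, abs=1e-10)

    def test_disjoint_coordinate_frame_rejected(self):
        fitres = make_hook_fit([(0.0, 0.0), (10.0, 10.0)], [0.0, 0.0], b=[0.0])
        grid = make_grid([(5000.0, 9000.0), (5001.0, 9001.0)])
        with pytest.raises(ValueError, match="coordinate-system mismatch"):
            predict_grid(fitres, grid)

    def test_extrapolation_warns(self):
        fitres = make_hook_fit([(0.0, 0.0), (10.0, 10.0)], [0.0, 0.0],
                               b=[0.0, 0.0, 0.0], include_depth=True)
        grid = make_grid([(1.0, 1.0)], depth=5000.0)
        with pytest.warns(UserWarning, match="extrapolation"):
            predict_grid(fitres, grid)


class TestBiomassIndex:
    def test_constant_density(self):
        surf = surface_from([(i, 0.0) for i in range(7)], np.full(7, 2.5), area=3.0)
        b = biomass_index(surf)
        assert b.table["estimate"].iloc[0] == pytest.approx(7 * 3.0 * 2.5, abs=1e-9)

    def test_vanishing_density_limit(self):
        surf = surface_from([(0, 0), (1, 0)], np.full(2, 1e-300))
        b = biomass_index(surf)
        assert 0 < b.table["estimate"].iloc[0] < 1e-290

    def test_permutation_invariance(self, rng):
        coords = [tuple(c) for c in rng.uniform(0, 10, (50, 2))]
        dens = rng.gamma(1.0, 2.0, 50)
        area = rng.uniform(0.5, 2.0, 50)
        s1 = surface_from(coords, dens, area=area)
        perm = rng.permutation(50)
        s2 = DensitySurface(table=s1.table.iloc[perm].reset_index(drop=True))
        b1 = biomass_index(s1).table["estimate"].iloc[0]
        b2 = biomass_index(s2).table["estimate"].iloc[0]
        assert b1 == pytest.approx(b2, abs=1e-9 * max(1.0, b1))

    def test_relative_series_max_is_one(self, rng):
        tab = pd.DataFrame(
            {"year": np.arange(2003, 2011), "component": "biomass",
             "estimate": rng.gamma(5.0, 100.0, 8),
             "se": 1.0, "lwr": 1.0, "upr": 1.0}
        )
        from ppsdm.derived_indices import IndexSeries

        rel = relative_series(IndexSeries(kind="biomass", table=tab))
        assert rel.table["estimate"].max() == pytest.approx(1.0, abs=0)


class TestCenterOfGravity:
    def test_uniform_density_gives_grid_centroid(self):
        coords = [(float(i), float(j)) for i in range(5) for j in range(4)]
        surf = surface_from(coords, np.ones(20))
        cog = center_of_gravity(surf)
        assert cog.component("east")["estimate"].iloc[0] == pytest.approx(2.0, abs=1e-9)
        assert cog.component("north")["estimate"].iloc[0] == pytest.approx(1.5, abs=1e-9)

    def test_point_mass_gives_that_cell(self):
        coords = [(0.0, 0.0), (3.0, 7.0), (9.0, 1.0)]
        dens = np.array([1e-14, 5.0, 1e-14])
        cog = center_of_gravity(surface_from(coords, dens))
        assert cog.component("east")["estimate"].iloc[0] == pytest.approx(3.0, abs=1e-9)
        assert cog.component("north")["estimate"].iloc[0] == pytest.approx(7.0, abs=1e-9)

    def test_matches_brute_force_weighted_mean(self, rng):
        coords = rng.uniform(0, 100, (60, 2))
        dens = rng.gamma(1.5, 3.0, 60)
        area = rng.uniform(0.5, 2.0, 60)
        surf = surface_from([tuple(c) for c in coords], dens, area=area)
        cog = center_of_gravity(surf)
        w = area * dens
        assert cog.component("east")["estimate"].iloc[0] == pytest.approx(
            np.sum(w * coords[:, 0]) / w.sum(), rel=1e-12
        )
        assert cog.component("north")["estimate"].iloc[0] == pytest.approx(
            np.sum(w * coords[:, 1]) / w.sum(), rel=1e-12
        )

    def test_cog_inside_convex_hull(self, rng):
        coords = rng.uniform(0, 50, (30, 2))
        dens = rng.gamma(1.0, 1.0, 30)
        surf = surface_from([tuple(c) for c in coords], dens)
        cog = center_of_gravity(surf)
        hull = MultiPoint([tuple(c) for c in coords]).convex_hull
        pt = Point(cog.component("east")["estimate"].iloc[0],
                   cog.component("north")["estimate"].iloc[0])
        assert hull.buffer(1e-9).contains(pt)

    def test_zero_density_errors(self):
        surf = surface_from([(0.0, 0.0)], np.array([1.0]))
        surf.table["density"] = 0.0
        with pytest.raises(ValueError, match="zero total density"):
            center_of_gravity(surf)


class TestSplittingInvariance:
    def test_quartered_cells_leave_indices_unchanged(self, rng):
        coords = np.array([(2.0 * i + 1.0, 2.0 * j + 1.0)
                           for i in range(4) for j in range(3)])
        dens = rng.gamma(2.0, 1.0, 12)
        parent = surface_from([tuple(c) for c in coords], dens, area=4.0)
        # each 2x2 parent cell split into 4 unit cells with equal density
        sub_coords, sub_dens = [], []
        for c, d in zip(coords, dens):
            for dx in (-0.5, 0.5):
                for dy in (-0.5, 0.5):
                    sub_coords.append((c[0] + dx, c[1] + dy))
                    sub_dens.append(d)
        child = surface_from(sub_coords, np.array(sub_dens), area=1.0)
        bp = biomass_index(parent).table["estimate"].iloc[0]
        bc = biomass_index(child).table["estimate"].iloc[0]
        assert bc == pytest.approx(bp, abs=1e-9 * bp)
        for comp in ("east", "north"):
            cp = center_of_gravity(parent).component(comp)["estimate"].iloc[0]
            cc = center_of_gravity(child).component(comp)["estimate"].iloc[0]
            assert cc == pytest.approx(cp, abs=1e-9)


class TestSampleUncertainty:
    def test_zeroed_covariance_collapses_interval(self):
        fitres = make_hook_fit([(0.0, 0.0), (10.0, 10.0)], [0.2, -0.2], b=[1.0])
        grid = make_grid([(2.0, 2.0), (8.0, 8.0)])
        series = sample_uncertainty(
            fitres, grid, "biomass", n_draws=2, seed=0,
            b_cov=np.zeros((1, 1)), u_chol=np.zeros((2, 2)),
        )
        row = series.table.iloc[0]
        assert row["se"] == 0.0
        assert row["lwr"] == pytest.approx(row["estimate"], rel=1e-12)
        assert row["upr"] == pytest.approx(row["estimate"], rel=1e-12)

    def test_matches_delta_method_for_lognormal_statistic(self):
        """Single cell, single fixed effect: B = a exp(b0 + Z sqrt(v)) whose
        SD has the closed lognormal form; 5000 draws must land within 5%."""
        v = 0.01
        fitres = make_hook_fit([(0.0, 0.0), (10.0, 10.0)], [0.0, 0.0], b=[1.3],
                               b_cov_scale=v)
        grid = make_grid([(50.0, 50.0)], area=2.0)  # far from knots, u ~ 0
        series = sample_uncertainty(
            fitres, grid, "biomass", n_draws=5000, seed=1,
            u_chol=np.zeros((2, 2)),
        )
        est = 2.0 * np.exp(1.3)
        exact_sd = est * np.sqrt(np.exp(v) - 1.0) * np.exp(v / 2)
        assert series.table["se"].iloc[0] == pytest.approx(exact_sd, rel=0.05)

    def test_deterministic_under_seed(self):
        fitres = make_hook_fit([(0.0, 0.0), (10.0, 10.0)], [0.3, -0.1], b=[0.5],
                               b_cov_scale=0.04)
        grid = make_grid([(1.0, 1.0), (9.0, 9.0)])
        s1 = sample_uncertainty(fitres, grid, "cog", n_draws=50, seed=42)
        s2 = sample_uncertainty(fitres, grid, "cog", n_draws=50, seed=42)
        pd.testing.assert_frame_equal(s1.table, s2.table)

    def test_interval_orders_around_estimate(self, model1_fit, small_domain):
        grid = small_domain.to_prediction_grid()
        series = sample_uncertainty(model1_fit, grid, "biomass", n_draws=60, seed=3)
        t = series.table
        assert (t["lwr"] <= t["estimate"] + 1e-9).all()
        assert (t["estimate"] <= t["upr"] + 1e-9).all()
        assert (t["estimate"] > 0).all()
        assert (t["se"] > 0).all()
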