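"""Laplace machinery: inner Newton, marginal likelihood, outer fit."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from ppsdm.estimation import (
    ModelSpec,
    ThetaMap,
    build_structures,
    fit,
    inner_mode,
    laplace_nll,
)
from ppsdm.observation_model import build_design, tweedie_logpdf
from ppsdm.spatial_fields import select_knots


def _toy_obs(rng, n=60, n_years=3, gaussian=False):
    n = (n // n_years) * n_years
    years = np.repeat(np.arange(2003, 2003 + n_years), n // n_years)
    coords = rng.uniform(0, 50, size=(n, 2))
    y = rng.normal(1.0, 1.0, n) if gaussian else rng.gamma(2.0, 2.0, n)
    return pd.DataFrame(
        {
            "year": years,
            "easting_km": coords[:, 0],
            "northing_km": coords[:, 1],
            "depth_m": rng.uniform(60, 1200, n),
            "cpue_kg_km2": y,
        }
    )


def _gaussian_setup(rng, n=60, k=8, sd=0.7, **theta):
    obs = _toy_obs(rng, n=n, gaussian=True)
    spec = ModelSpec(include_depth=True, st_mode="none", n_knots=k,
                     family="gaussian", gaussian_sd=sd)
    design = build_design(obs, include_depth=True)
    knots = select_knots(obs[["easting_km", "northing_km"]].to_numpy(), k, seed=0)
    nat = {"range_omega": 25.0, "sigma_omega": 0.9, **theta}
    s = build_structures(obs, design, knots, spec, nat)
    return obs, design, knots, spec, nat, s


class TestInnerMode:
    def test_gaussian_mode_equals_gls_solution(self, rng):
        """With a Gaussian response the penalized problem is quadratic and
        the Newton mode must equal the generalized-least-squares solution."""
        obs, design, knots, spec, nat, s = _gaussian_setup(rng)
        b = rng.normal(0.0, 0.5, design.X.shape[1])
        u, _, _, conv = inner_mode(b, s)
        assert conv
        # direct dense solve of (Q + A'A/sd^2) u = A'(y - Xb)/sd^2
        r = (s.y - s.X @ b) / spec.gaussian_sd**2
        H = s.Q + s.A_om.T @ s.A_om / spec.gaussian_sd**2
        direct = np.linalg.solve(H, s.A_om.T @ r)
        np.testing.assert_allclose(u, direct, atol=1e-8)

    def test_zero_variance_limit_shrinks_modes(self, rng):
        obs, design, knots, spec, nat, _ = _gaussian_setup(rng)
        s = build_structures(obs, design, knots, spec,
                             {**nat, "sigma_omega": 1e-6})
        b = np.zeros(design.X.shape[1])
        u, _, _, _ = inner_mode(b, s)
        assert np.max(np.abs(u)) < 1e-3

    def test_warm_and_cold_start_agree(self, model1_data):
        _, _, obs = model1_data
        spec = ModelSpec(n_knots=25, n_starts=1)
        design = build_design(obs)
        knots = select_knots(obs[["easting_km", "northing_km"]].to_numpy(), 25, seed=0)
        nat = {"range_omega": 40.0, "sigma_omega": 0.8, "p": 1.5, "disp": 4.0}
        s = build_structures(obs, design, knots, spec, nat)
        b = np.concatenate([np.full(8, 1.5), [0.5, -0.4]])
        u_cold, _, _, _ = inner_mode(b, s)
        rng = np.random.default_rng(1)
        u_warm, _, _, _ = inner_mode(b, s, u0=u_cold + rng.normal(0, 0.5, s.dim))
        np.testing.assert_allclose(u_cold, u_warm, atol=1e-7)


class TestLaplaceNLL:
    def test_matches_exact_gaussian_marginal(self, rng):
        """Laplace is exact for a Gaussian response: compare against the
        closed-form marginal N(Xb, sd^2 I + A Sigma A')."""
        obs, design, knots, spec, nat, s = _gaussian_setup(rng, n=21, k=3)
        b = rng.normal(0.0, 0.3, design.X.shape[1])
        nll, _, _, _ = laplace_nll(b, s)
        Sigma = np.linalg.inv(s.Q)
        cov = spec.gaussian_sd**2 * np.eye(len(obs)) + s.A_om @ Sigma @ s.A_om.T
        exact = -multivariate_normal.logpdf(s.y, mean=s.X @ b, cov=cov)
        assert nll == pytest.approx(exact, abs=1e-8)

    def test_vanishing_field_approaches_glm_likelihood(self, model1_data):
        """As sigma_omega -> 0 the marginal collapses onto the fixed-effect
        Tweedie GLM; compare at the GLM's own coefficient estimates."""
        import statsmodels.api as sm

        _, _, obs = model1_data
        sub = obs.iloc[:400].reset_index(drop=True)
        design = build_design(sub)
        glm = sm.GLM(
            sub["cpue_kg_km2"].to_numpy(), design.X,
            family=sm.families.Tweedie(var_power=1.5,
                                       link=sm.families.links.Log()),
        ).fit()
        spec = ModelSpec(n_knots=15)
        knots = select_knots(sub[["easting_km", "northing_km"]].to_numpy(), 15, seed=0)
        nat = {"range_omega": 30.0, "sigma_omega": 1e-6, "p": 1.5, "disp": 2.0}
        s = build_structures(sub, design, knots, spec, nat)
        nll, _, _, _ = laplace_nll(np.asarray(glm.params), s)
        from ppsdm.observation_model import TweedieParams

        mu = np.exp(design.X @ np.asarray(glm.params))
        direct = -np.sum(tweedie_logpdf(sub["cpue_kg_km2"].to_numpy(), mu,
                                        TweedieParams(p=1.5, disp=2.0)))
        assert nll == pytest.approx(direct, abs=1e-4)

    def test_duplicated_data_does_not_double_nll(self, rng):
        obs, design, knots, spec, nat, s = _gaussian_setup(rng, n=30, k=5)
        b = np.zeros(design.X.shape[1])
        nll, _, _, _ = laplace_nll(b, s)
        dup = pd.concat([obs, obs], ignore_index=True)
        design2 = build_design(dup, include_depth=True)
        s2 = build_structures(dup, design2, knots, spec, nat)
        nll2, _, _, _ = laplace_nll(b, s2)
        assert nll2 < 2 * nll  # penalty and normalizing terms counted once

    def test_coordinate_shift_invariance(self, rng):
        obs, design, knots, spec, nat, s = _gaussian_setup(rng, n=40, k=6)
        b = rng.normal(0.0, 0.3, design.X.shape[1])
        nll, _, _, _ = laplace_nll(b, s)
        shifted = obs.copy()
        shifted["easting_km"] += 1234.5
        shifted["northing_km"] -= 987.6
        k2 = select_knots(shifted[["easting_km", "northing_km"]].to_numpy(),
                          knots.n_knots, seed=0)
        s2 = build_structures(shifted, design, k2, spec, nat)
        nll2, _, _, _ = laplace_nll(b, s2)
        assert nll2 == pytest.approx(nll, abs=1e-6)

    def test_ar1_at_phi_zero_equals_iid_objective(self, rng):
        """Model nesting: the AR(1) likelihood with phi pinned at 0 must
        coincide with the IID spatiotemporal likelihood everywhere."""
        obs = _toy_obs(rng, n=90, n_years=3)
        design = build_design(obs)
        knots = select_knots(obs[["easting_km", "northing_km"]].to_numpy(), 10, seed=0)
        spec_ar = ModelSpec(st_mode="ar1", n_knots=10, fixed_params=(("phi", 0.0),))
        spec_iid = ModelSpec(st_mode="iid", n_knots=10)
        for trial in range(3):
            nat = {
                "range_omega": float(rng.uniform(15, 60)),
                "sigma_omega": float(rng.uniform(0.3, 1.2)),
                "sigma_eps": float(rng.uniform(0.2, 0.8)),
                "p": 1.5, "disp": 2.0, "phi": 0.0,
            }
            b = rng.normal(0.5, 0.3, design.X.shape[1])
            s_ar = build_structures(obs, design, knots, spec_ar,
                                    {**nat, "range_eps": nat["range_omega"]})
            s_iid = build_structures(obs, design, knots, spec_iid,
                                     {**nat, "range_eps": nat["range_omega"]})
            nll_ar, *_ = laplace_nll(b, s_ar)
            nll_iid, *_ = laplace_nll(b, s_iid)
            assert nll_ar == pytest.approx(nll_iid, abs=1e-6)


class TestFit:
    def test_depth_coefficients_recovered_within_two_se(self, model1_fit, model1_data):
        params, _, _ = model1_data
        res = model1_fit
        i1 = res.b_names.index("depth_z")
        i2 = res.b_names.index("depth_z2")
        assert abs(res.b[i1] - params.b_depth1) < 2 * res.b_se[i1]
        assert abs(res.b[i2] - params.b_depth2) < 2 * res.b_se[i2]

    def test_covariance_parameters_plausible(self, model1_fit):
        th = model1_fit.theta
        assert 5.0 < th["range_omega"] < 500.0
        assert 0.1 < th["sigma_omega"] < 5.0
        assert 1.0 < th["p"] < 2.0
        assert th["disp"] > 0

    def test_nested_model_has_no_smaller_nll(self, model1_data):
        """Dropping a real depth effect cannot improve the in-sample fit."""
        _, _, obs = model1_data
        sub = obs[obs["year"] <= 2006].reset_index(drop=True)
        spec1 = ModelSpec(include_depth=True, st_mode="none", n_knots=20,
                          n_starts=1, compute_se=False)
        spec4 = spec1.with_(include_depth=False)
        r1 = fit(spec1, sub)
        r4 = fit(spec4, sub)
        assert r4.nll >= r1.nll - 1e-6

    def test_theta_map_round_trip(self):
        spec = ModelSpec(st_mode="ar1", share_range=False)
        tmap = ThetaMap(spec)
        nat = {"range_omega": 40.0, "sigma_omega": 0.8, "sigma_eps": 0.4,
               "range_eps": 30.0, "phi": 0.35, "p": 1.5, "disp": 4.0}
        back = tmap.to_natural(tmap.to_unconstrained(nat))
        for k, v in nat.items():
            assert back[k] == pytest.approx(v, rel=1e-12)

    def test_knot_count_sensitivity(self, model1_fit, model1_data):
        """Halving the knot count perturbs, but does not upend, the fixed
        effects: depth estimates agree within their combined 2-SE band."""
        _, _, obs = model1_data
        res20 = fit(ModelSpec(include_depth=True, st_mode="none", n_knots=20,
                              n_starts=1, compute_se=True), obs)
        assert res20.converged
        for name in ("depth_z", "depth_z2"):
            i40 = model1_fit.b_names.index(name)
            i20 = res20.b_names.index(name)
            gap = abs(model1_fit.b[i40] - res20.b[i20])
            band = 2 * np.hypot(model1_fit.b_se[i40], res20.b_se[i20])
            assert gap < band

    def test_shared_range_is_a_restriction(self, rng):
        """Freeing the spatiotemporal field's range (share_range=False) is a
        superset model: its optimised NLL cannot be meaningfully worse."""
        obs = _toy_obs(rng, n=240, n_years=3)
        shared = fit(ModelSpec(st_mode="iid", share_range=True, n_knots=10,
                               n_starts=1, compute_se=False, maxiter=120), obs)
        free = fit(ModelSpec(st_mode="iid", share_range=False, n_knots=10,
                             n_starts=1, compute_se=False, maxiter=120), obs)
        assert "range_eps" in free.theta
        assert free.nll <= shared.nll + 0.5  # optimizer noise allowance

    def test_few_observations_warn(self, rng):
        obs = _toy_obs(rng, n=24, n_years=3)
        with pytest.warns(UserWarning, match="observations"):
            fit(ModelSpec(n_knots=5, n_starts=1, compute_se=False, maxiter=5), obs)
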