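"""Model validation: latitude-blocked cross-validation and PIT residuals.

Random k-fold CV leaks information through spatial autocorrelation, so
folds are contiguous latitude bands: boundaries at the j/k quantiles of
Northings pooled across years, each observation assigned by its band
(boundary ties go to the lower band).  The score is the held-out Tweedie
log-density, summed over observations and folds, using the training fit's
dispersion and power.

Goodness of fit uses simulation-based randomized quantile (PIT) residuals:
replicate datasets are simulated from the fitted model conditional on the
fitted random effects, and each observation's randomized rank among its
replicates is uniform under a correct model (the zero atom is handled by
uniform tie-breaking).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kstest

from .estimation import FitResult, ModelSpec, fit as fit_model
from .observation_model import tweedie_logpdf

__all__ = ["FoldAssignment", "CVResult", "latitude_folds", "cross_validate",
           "predict_mu", "quantile_residuals"]


@dataclass
class FoldAssignment:
    """Fold label (1..k) per observation, plus the boundary latitudes."""

    labels: np.ndarray
    boundaries: np.ndarray  # interior quantile boundaries, length k-1
    k: int


def latitude_folds(obs: pd.DataFrame, k: int = 5) -> FoldAssignment:
    """Split observations into k contiguous latitude (Northings) bands.

    Boundaries are the j/k sample quantiles of Northings pooled across
    years; ties at a boundary go to the lower band.  A fold that ends up
    empty (mass of tied latitudes) is an error.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    lat = obs["northing_km"].to_numpy(dtype=float)
    if np.unique(lat).size < k:
        raise ValueError(f"need at least {k} distinct latitudes for {k} folds")
    bounds = np.quantile(lat, np.arange(1, k) / k)
    labels = np.searchsorted(bounds, lat, side="left") + 1  # ties -> lower band
    sizes = np.bincount(labels, minlength=k + 1)[1:]
    if np.any(sizes == 0):
        raise ValueError(f"degenerate latitude folds (sizes {sizes.tolist()})")
    return FoldAssignment(labels=labels, boundaries=bounds, k=k)


def predict_mu(fit: FitResult, new_obs: pd.DataFrame) -> np.ndarray:
    """Predicted mean CPUE at new locations from a fitted model.

    Fixed effects use the training standardization; random fields are
    projected from the fitted knot modes (spatiotemporal effects taken from
    the training modes of the matching year — they are predicted, not
    re-estimated).
    """
    from .derived_indices import _grid_weights

    coords = new_obs[["easting_km", "northing_km"]].to_numpy()
    A_om, A_eps = _grid_weights(fit, coords)
    om = A_om @ fit.u_omega
    eta = np.empty(len(new_obs))
    years = fit.design.years
    for year, idx in new_obs.groupby("year").groups.items():
        pos = new_obs.index.get_indexer(idx)
        X = fit.design.row_for(int(year), new_obs["depth_m"].to_numpy()[pos])
        e = X @ fit.b + om[pos]
        if fit.spec.st_mode != "none":
            t = int(np.searchsorted(years, year))
            e = e + A_eps[pos] @ fit.u_eps[t]
        eta[pos] = e
    return np.exp(eta)


@dataclass
class CVResult:
    """Per-fold held-out log-densities and parameters of interest."""

    fold_logdens: list[float]
    fold_params: list[dict]
    excluded_folds: list[int]

    @property
    def total(self) -> float:
        return float(np.sum(self.fold_logdens))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fold": np.arange(1, len(self.fold_logdens) + 1),
             "logdens": self.fold_logdens}
        )


def cross_validate(spec: ModelSpec, obs: pd.DataFrame, folds: FoldAssignment) -> CVResult:
    """Latitude-blocked k-fold CV of one model specification.

    Each fold is held out in turn; the model is fitted to the complement
    and the held-out records scored by their Tweedie log-density at the
    predicted means, with the training fit's (p, disp).  A non-convergent
    fold is excluded from the total with a warning.
    """
    obs = obs.reset_index(drop=True)
    logdens, params, excluded = [], [], []
    for fold in range(1, folds.k + 1):
        test_mask = folds.labels == fold
        train = obs[~test_mask].reset_index(drop=True)
        test = obs[test_mask].reset_index(drop=True)
        res = fit_model(spec.with_(compute_se=False), train)
        if not res.converged:
            warnings.warn(f"fold {fold} fit did not converge; excluded from total",
                          stacklevel=2)
            excluded.append(fold)
            logdens.append(0.0)
            params.append({})
            continue
        mu = predict_mu(res, test)
        ll = float(
            np.sum(tweedie_logpdf(test["cpue_kg_km2"].to_numpy(), mu,
                                  res.tweedie_params))
        )
        logdens.append(ll)
        params.append(
            {k: v for k, v in res.theta.items()
             if k in ("range_omega", "sigma_omega", "phi")}
        )
    return CVResult(fold_logdens=logdens, fold_params=params, excluded_folds=excluded)


def quantile_residuals(
    fit: FitResult, obs: pd.DataFrame, n_sims: int = 200, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Simulation-based randomized PIT residuals and a KS uniformity distance.

    Simulates ``n_sims`` replicate response vectors from the fitted
    observation model at the conditional means (random effects fixed at
    their modes); the residual of observation i is its randomized rank
    among the replicates, ties (including the zero atom) broken uniformly.
    Returns ``(residuals in (0,1), KS distance vs uniform)``.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    obs = obs.reset_index(drop=True)
    mu = predict_mu(fit, obs)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 90_017)))
    y = obs["cpue_kg_km2"].to_numpy(dtype=float)
    sims = np.empty((n_sims, len(y)))
    if fit.spec.family == "gaussian":
        for s in range(n_sims):
            sims[s] = rng.normal(eta, fit.spec.gaussian_sd)
    else:
        from .observation_model import tweedie_rvs

        for s in range(n_sims):
            sims[s] = tweedie_rvs(mu, fit.tweedie_params, rng)
    below = np.sum(sims < y[None, :], axis=0)
    ties = np.sum(sims == y[None, :], axis=0)
    u = rng.uniform(size=len(y))
    resid = (below + u * (ties + 1)) / (n_sims + 1)
    ks = kstest(resid, "uniform").statistic
    return resid, float(ks)
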