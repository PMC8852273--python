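"""Matérn covariance, knot selection, and the Gaussian predictive process.

The spatial random fields in the model are Gaussian processes with Matérn
covariance.  To keep the random-effect dimension manageable, a field is
represented by its values at a reduced set of locations (*knots*) and
projected to any other location by the conditional expectation of the
Gaussian process (kriging weights) — the classic predictive-process
approximation.  Knots are chosen as k-means cluster centres of the source
locations, so their density follows the sampling density.

Conventions
-----------
* Coordinates are planar, in km (Eastings/Northings).
* Matérn smoothness ``nu`` defaults to 1.
* The *range* is parametrised so that the correlation is approximately 0.1
  at distance ``range_km``: the decay rate is ``kappa = sqrt(8 * nu) /
  range_km``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.spatial.distance import cdist
from scipy.special import gamma as gamma_fn
from scipy.special import k1, kv
from sklearn.cluster import KMeans

__all__ = [
    "MaternParams",
    "KnotSet",
    "Projection",
    "SpatioTemporalStructure",
    "matern_cov",
    "select_knots",
    "project",
    "st_joint_structure",
    "chol_with_jitter",
]

# Jitter ladder for near-singular covariance factorisations, as a fraction
# of the marginal variance: 1e-8, 1e-7, ..., 1e-4, then fail.
_JITTER_LADDER = tuple(10.0 ** e for e in range(-8, -3))


@dataclass(frozen=True)
class MaternParams:
    """Marginal SD and range of a Matérn field.

    ``range_km`` is the distance at which correlation has decayed to ~0.1
    under the ``kappa = sqrt(8 nu) / range`` convention; ``sigma`` is the
    marginal standard deviation; ``nu`` is the smoothness (fixed at 1 by
    convention, overridable for testing against closed forms).
    """

    range_km: float
    sigma: float
    nu: float = 1.0

    def __post_init__(self) -> None:
        if not (self.range_km > 0 and np.isfinite(self.range_km)):
            raise ValueError(f"range_km must be positive, got {self.range_km}")
        if not (self.sigma > 0 and np.isfinite(self.sigma)):
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not (self.nu > 0 and np.isfinite(self.nu)):
            raise ValueError(f"nu must be positive, got {self.nu}")

    @property
    def kappa(self) -> float:
        return math.sqrt(8.0 * self.nu) / self.range_km


def matern_correlation(distances: np.ndarray, params: MaternParams) -> np.ndarray:
    """Matérn correlation ``m_nu(kappa * d)``; exactly 1 at d = 0."""
    d = np.asarray(distances, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    nu = params.nu
    x = params.kappa * d
    with np.errstate(invalid="ignore", over="ignore"):
        if nu == 1.0:
            corr = x * k1(x)  # fast special case (the default smoothness)
        elif nu == 0.5:
            corr = np.exp(-x)
        else:
            corr = (2.0 ** (1.0 - nu) / gamma_fn(nu)) * (x**nu) * kv(nu, x)
    # kv(nu, 0) is inf and 0**nu is 0; the limit is 1.
    corr = np.where(x == 0.0, 1.0, corr)
    return np.clip(corr, 0.0, 1.0)


def matern_cov(distances: np.ndarray, params: MaternParams) -> np.ndarray:
    """Matérn covariance ``sigma^2 * m_nu(kappa d)`` over a distance array.

    Parameters
    ----------
    distances
        Array of pairwise distances in km (any shape; symmetric if square).
    params
        Matérn range/SD/smoothness.
    """
    return params.sigma**2 * matern_correlation(distances, params)


def chol_with_jitter(cov: np.ndarray, scale: float):
    """Cholesky factor of ``cov``, escalating diagonal jitter if needed.

    Jitter starts at ``1e-8 * scale`` and escalates tenfold up to
    ``1e-4 * scale`` before raising.  Returns ``(cho_factor result, jitter)``.
    """
    try:
        return cho_factor(cov, lower=True), 0.0
    except np.linalg.LinAlgError:
        pass
    for frac in _JITTER_LADDER:
        jitter = frac * scale
        try:
            return cho_factor(cov + jitter * np.eye(cov.shape[0]), lower=True), jitter
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        "covariance not positive definite after jitter escalation to "
        f"{_JITTER_LADDER[-1]:.0e} * scale"
    )


@dataclass(frozen=True)
class KnotSet:
    """Reduced set of locations carrying the random-effect dimension."""

    coords: np.ndarray  # (k, 2) km
    assignment: np.ndarray  # nearest-knot index per source location
    seed: int

    @property
    def n_knots(self) -> int:
        return self.coords.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"knot_id": np.arange(self.n_knots),
             "easting_km": self.coords[:, 0],
             "northing_km": self.coords[:, 1]}
        )


def select_knots(locations: np.ndarray, n_knots: int, seed: int = 0) -> KnotSet:
    """Place ``n_knots`` knots at k-means cluster centres of ``locations``.

    Deterministic under a fixed seed; at most 100 Lloyd iterations.
    """
    locs = np.asarray(locations, dtype=float)
    if locs.ndim != 2 or locs.shape[1] != 2:
        raise ValueError("locations must be (n, 2)")
    distinct = np.unique(locs, axis=0)
    if distinct.shape[0] < 2:
        raise ValueError("need at least 2 distinct locations to place knots")
    if n_knots < 2:
        raise ValueError("n_knots must be >= 2")
    if n_knots > distinct.shape[0]:
        raise ValueError(
            f"n_knots={n_knots} exceeds {distinct.shape[0]} distinct locations"
        )
    if n_knots == distinct.shape[0]:
        coords = distinct
    else:
        # canonical (sorted) input order makes the knot set invariant to
        # permutations of the source records
        order = np.lexsort((locs[:, 1], locs[:, 0]))
        km = KMeans(n_clusters=n_knots, n_init=5, max_iter=100,
                    random_state=seed).fit(locs[order])
        coords = km.cluster_centers_
    assignment = np.argmin(cdist(locs, coords), axis=1)
    return KnotSet(coords=coords, assignment=assignment, seed=seed)


@dataclass(frozen=True)
class Projection:
    """Kriging weights from knot values to target locations.

    ``weights @ u`` gives the conditional mean of the field at the targets
    given its values ``u`` at the knots; ``cond_var`` is the per-target
    conditional variance (0 where a target coincides with a knot, at most
    the marginal variance far from all knots).
    """

    weights: np.ndarray  # (n_targets, n_knots)
    cond_var: np.ndarray  # (n_targets,)
    jitter: float = 0.0

    def apply(self, u: np.ndarray) -> np.ndarray:
        return self.weights @ u

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            self.weights,
            columns=[f"w_knot_{j}" for j in range(self.weights.shape[1])],
        )
        df.insert(0, "target_id", np.arange(len(df)))
        df["cond_var"] = self.cond_var
        return df


def project(knots: KnotSet, targets: np.ndarray, params: MaternParams) -> Projection:
    """Predictive-process projection A = C(targets, knots) C(knots, knots)^-1.

    The conditional variance per target is ``sigma^2 - a_i' C_kk a_i`` with
    ``a_i`` the i-th row of A.  The knot covariance is factorised with the
    documented jitter ladder; exhaustion raises, naming the closest knot
    pair (near-duplicate knots are the usual culprit).
    """
    tg = np.atleast_2d(np.asarray(targets, dtype=float))
    C_kk = matern_cov(cdist(knots.coords, knots.coords), params)
    try:
        factor, jitter = chol_with_jitter(C_kk, params.sigma**2)
    except np.linalg.LinAlgError as err:
        dk = cdist(knots.coords, knots.coords)
        np.fill_diagonal(dk, np.inf)
        i, j = np.unravel_index(np.argmin(dk), dk.shape)
        raise np.linalg.LinAlgError(
            f"knot covariance not factorisable (closest knots {i} and {j} at "
            f"{dk[i, j]:.3g} km): {err}"
        ) from err
    C_tk = matern_cov(cdist(tg, knots.coords), params)
    A = cho_solve(factor, C_tk.T).T
    cond_var = params.sigma**2 - np.einsum("ij,ij->i", A, C_tk)
    cond_var = np.clip(cond_var, 0.0, params.sigma**2)
    return Projection(weights=A, cond_var=cond_var, jitter=jitter)


@dataclass
class SpatioTemporalStructure:
    """Joint Gaussian structure for all knot-year spatiotemporal effects.

    The structure is separable: a temporal AR(1) (or identity, for IID)
    correlation across years, Kronecker a Matérn block across knots, each
    year's marginal variance being ``sigma^2``.  Provides the pieces the
    Laplace machinery needs — precision matrix, log-determinant of the
    covariance, and a sampling factor — without ever forming the dense
    (knots x years) covariance unless asked.
    """

    mode: str  # "none" | "iid" | "ar1"
    n_years: int
    n_knots: int
    phi: float
    spatial_cov: np.ndarray | None  # (k, k) Matérn block, marginal var sigma^2
    jitter: float = 0.0
    _spatial_prec: np.ndarray | None = field(default=None, repr=False)
    _spatial_logdet: float = field(default=0.0, repr=False)

    @property
    def dim(self) -> int:
        return 0 if self.mode == "none" else self.n_years * self.n_knots

    def temporal_corr(self) -> np.ndarray:
        t = np.arange(self.n_years)
        if self.mode == "iid":
            return np.eye(self.n_years)
        return self.phi ** np.abs(np.subtract.outer(t, t))

    def temporal_prec(self) -> np.ndarray:
        """Tridiagonal inverse of the stationary AR(1) correlation."""
        n = self.n_years
        if self.mode == "iid" or n == 1:
            return np.eye(n)
        phi = self.phi
        P = np.zeros((n, n))
        idx = np.arange(n)
        P[idx, idx] = 1.0 + phi**2
        P[0, 0] = P[-1, -1] = 1.0
        P[idx[:-1], idx[:-1] + 1] = -phi
        P[idx[:-1] + 1, idx[:-1]] = -phi
        return P / (1.0 - phi**2)

    def covariance(self) -> np.ndarray:
        """Dense joint covariance, ordered year-major (year 0 knots first)."""
        if self.mode == "none":
            return np.zeros((0, 0))
        return np.kron(self.temporal_corr(), self.spatial_cov)

    def precision(self) -> np.ndarray:
        if self.mode == "none":
            return np.zeros((0, 0))
        return np.kron(self.temporal_prec(), self._spatial_prec)

    def logdet_cov(self) -> float:
        """log|covariance| via the Kronecker identity."""
        if self.mode == "none":
            return 0.0
        logdet_T = 0.0
        if self.mode == "ar1" and self.n_years > 1:
            logdet_T = (self.n_years - 1) * math.log1p(-self.phi**2)
        return self.n_knots * logdet_T + self.n_years * self._spatial_logdet


def st_joint_structure(
    knots: KnotSet,
    n_years: int,
    mode: str,
    phi: float = 0.0,
    params: MaternParams | None = None,
) -> SpatioTemporalStructure:
    """Build the joint covariance description for knot-year effects.

    ``mode='none'`` yields an empty structure; ``'iid'`` a block-diagonal
    repetition of the Matérn block; ``'ar1'`` the separable AR(1)-in-time
    structure with temporal correlation ``phi^|t-t'|`` and exact marginal
    variance ``sigma^2`` every year.
    """
    if mode not in ("none", "iid", "ar1"):
        raise ValueError(f"unknown spatiotemporal mode {mode!r}")
    if mode == "ar1" and not abs(phi) < 1:
        raise ValueError(f"|phi| must be < 1 for ar1, got {phi}")
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if mode == "none":
        return SpatioTemporalStructure(
            mode="none", n_years=n_years, n_knots=knots.n_knots,
            phi=0.0, spatial_cov=None,
        )
    if params is None:
        raise ValueError("Matérn params required for iid/ar1 structures")
    S = matern_cov(cdist(knots.coords, knots.coords), params)
    factor, jitter = chol_with_jitter(S, params.sigma**2)
    if jitter:
        S = S + jitter * np.eye(S.shape[0])
    L = np.tril(factor[0])
    k = S.shape[0]
    Linv = solve_triangular(L, np.eye(k), lower=True)
    prec = Linv.T @ Linv
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return SpatioTemporalStructure(
        mode=mode, n_years=n_years, n_knots=k,
        phi=phi if mode == "ar1" else 0.0,
        spatial_cov=S, jitter=jitter,
        _spatial_prec=prec, _spatial_logdet=logdet,
    )
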