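"""Maximum-likelihood fitting of the spatiotemporal GLMM by Laplace approximation.

The model for the linear predictor of observation i (year t, location s):

    eta_i = x_i' b + (A_omega u_omega)_i + (A_eps u_eps[t])_i

where ``u_omega`` are the time-constant spatial-field values at the knots,
``u_eps[t]`` the per-year spatiotemporal values, and the A matrices are the
predictive-process kriging weights from knots to observation locations.
The random effects are jointly Gaussian with Matérn (and, over years,
IID or AR(1)) covariance.

Estimation follows the standard nested scheme: for given fixed effects
``b`` and covariance/observation parameters ``theta``, the random-effect
modes are found by Newton iteration on the penalized log-likelihood
(step-halving on non-increase), and the marginal likelihood is the Laplace
approximation at that mode.  The outer optimisation runs a quasi-Newton
method on the transformed-parameter scale with finite-difference
gradients, from two starting points by default.  Standard errors come
from the finite-difference Hessian at the optimum, delta-method-mapped to
the natural scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .observation_model import (
    DesignMatrix,
    GaussianFamily,
    TweedieFamily,
    TweedieParams,
    build_design,
)
from .spatial_fields import (
    KnotSet,
    MaternParams,
    chol_with_jitter,
    matern_cov,
    select_knots,
    st_joint_structure,
)

__all__ = ["ModelSpec", "FitResult", "Structures", "build_structures",
           "inner_mode", "laplace_nll", "fit"]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one candidate model.

    ``include_depth`` toggles the quadratic depth covariate; year is always
    a fixed effect.  ``st_mode`` selects the spatiotemporal field (none /
    iid / ar1); ``share_range`` reuses the spatial field's Matérn range for
    the spatiotemporal field (default, reduces confounding).
    ``fixed_params`` pins named natural-scale parameters (e.g.
    ``{"phi": 0.0}``) out of the optimisation — a testing hook.
    """

    include_depth: bool = True
    st_mode: str = "none"
    share_range: bool = True
    n_knots: int = 80
    knot_seed: int = 0
    family: str = "tweedie"  # "gaussian" is a validation hook (known sd)
    gaussian_sd: float = 1.0
    n_starts: int = 2
    maxiter: int = 200
    gtol: float = 1e-5
    inner_tol: float = 1e-8
    inner_maxiter: int = 50
    compute_se: bool = True
    fixed_params: tuple = ()  # (("phi", 0.0), ...)

    def __post_init__(self) -> None:
        if self.st_mode not in ("none", "iid", "ar1"):
            raise ValueError(f"unknown st_mode {self.st_mode!r}")
        if self.family not in ("tweedie", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def fixed(self) -> dict:
        return dict(self.fixed_params)

    def with_(self, **kw) -> "ModelSpec":
        return replace(self, **kw)


# the four candidate model structures of the case study
CANDIDATE_SPECS = {
    1: ModelSpec(include_depth=True, st_mode="none"),
    2: ModelSpec(include_depth=True, st_mode="iid"),
    3: ModelSpec(include_depth=True, st_mode="ar1"),
    4: ModelSpec(include_depth=False, st_mode="none"),
}


# ---------------------------------------------------------------------------
# Parameter transforms


class ThetaMap:
    """Packing of covariance/observation parameters to unconstrained scale.

    Natural names: range_omega, sigma_omega, sigma_eps, range_eps (only if
    the range is not shared), phi (ar1 only), p, disp (Tweedie only).
    Transforms: logs for positive parameters, atanh for phi, logit to
    (1, 2) for the Tweedie power.
    """

    def __init__(self, spec: ModelSpec):
        names = ["range_omega", "sigma_omega"]
        if spec.st_mode != "none":
            names.append("sigma_eps")
            if not spec.share_range:
                names.append("range_eps")
        if spec.st_mode == "ar1":
            names.append("phi")
        if spec.family == "tweedie":
            names += ["p", "disp"]
        self.fixed = spec.fixed
        self.names = [n for n in names if n not in self.fixed]
        self.spec = spec

    def to_unconstrained(self, nat: dict) -> np.ndarray:
        out = []
        for n in self.names:
            v = nat[n]
            if n == "phi":
                out.append(math.atanh(v))
            elif n == "p":
                out.append(math.log((v - 1.0) / (2.0 - v)))
            else:
                out.append(math.log(v))
        return np.array(out)

    def to_natural(self, vec: np.ndarray) -> dict:
        nat = dict(self.fixed)
        for n, v in zip(self.names, vec):
            if n == "phi":
                nat[n] = math.tanh(v)
            elif n == "p":
                nat[n] = 1.0 + 1.0 / (1.0 + math.exp(-v))
            else:
                nat[n] = math.exp(v)
        if self.spec.share_range and self.spec.st_mode != "none":
            nat.setdefault("range_eps", nat["range_omega"])
        return nat

    def natural_jacobian(self, vec: np.ndarray) -> np.ndarray:
        """d(natural)/d(unconstrained), diagonal, for delta-method SEs."""
        jac = []
        for n, v in zip(self.names, vec):
            if n == "phi":
                jac.append(1.0 - math.tanh(v) ** 2)
            elif n == "p":
                e = 1.0 / (1.0 + math.exp(-v))
                jac.append(e * (1.0 - e))
            else:
                jac.append(math.exp(v))
        return np.array(jac)


# ---------------------------------------------------------------------------
# Model structures for one theta


@dataclass
class Structures:
    """Everything the inner problem needs for fixed theta."""

    y: np.ndarray
    X: np.ndarray
    A_om: np.ndarray  # (n, k)
    A_eps: np.ndarray | None  # (n, k) kriging weights for the eps field
    year_idx: np.ndarray  # obs -> 0..T-1
    obs_by_year: list[np.ndarray]
    Q: np.ndarray  # (dim, dim) joint random-effect precision
    logdet_cov: float
    family: object
    n_knots: int
    n_years: int
    st_mode: str

    @property
    def dim(self) -> int:
        k = self.n_knots
        return k + (0 if self.st_mode == "none" else self.n_years * k)

    def eta(self, b: np.ndarray, u: np.ndarray) -> np.ndarray:
        k = self.n_knots
        eta = self.X @ b + self.A_om @ u[:k]
        if self.st_mode != "none":
            ue = u[k:].reshape(self.n_years, k)
            for t, idx in enumerate(self.obs_by_year):
                if len(idx):
                    eta[idx] += self.A_eps[idx] @ ue[t]
        return eta

    def Jt_dot(self, g: np.ndarray) -> np.ndarray:
        """J' g where J = [A_om | per-year A_eps blocks]."""
        k = self.n_knots
        out = np.empty(self.dim)
        out[:k] = self.A_om.T @ g
        if self.st_mode != "none":
            for t, idx in enumerate(self.obs_by_year):
                seg = out[k + t * k: k + (t + 1) * k]
                seg[:] = self.A_eps[idx].T @ g[idx] if len(idx) else 0.0
        return out

    def JtWJ(self, w: np.ndarray) -> np.ndarray:
        """J' diag(w) J assembled blockwise (w enters with its sign)."""
        k = self.n_knots
        M = np.zeros((self.dim, self.dim))
        if self.st_mode == "none":
            M[:k, :k] = (self.A_om * w[:, None]).T @ self.A_om
            return M
        for t, idx in enumerate(self.obs_by_year):
            if not len(idx):
                continue
            Ao, Ae, wt = self.A_om[idx], self.A_eps[idx], w[idx]
            Go = (Ao * wt[:, None]).T
            M[:k, :k] += Go @ Ao
            cross = Go @ Ae
            lo = k + t * k
            M[:k, lo:lo + k] += cross
            M[lo:lo + k, :k] += cross.T
            M[lo:lo + k, lo:lo + k] += (Ae * wt[:, None]).T @ Ae
        return M


def _make_family(spec: ModelSpec, nat: dict):
    if spec.family == "gaussian":
        return GaussianFamily(sd=spec.gaussian_sd)
    return TweedieFamily(TweedieParams(p=nat["p"], disp=nat["disp"]))


def build_structures(
    obs: pd.DataFrame,
    design: DesignMatrix,
    knots: KnotSet,
    spec: ModelSpec,
    nat: dict,
    dist_ok: np.ndarray | None = None,
    dist_kk: np.ndarray | None = None,
) -> Structures:
    """Assemble projections and precisions for one natural-parameter dict."""
    coords = obs[["easting_km", "northing_km"]].to_numpy()
    if dist_ok is None:
        dist_ok = cdist(coords, knots.coords)
    if dist_kk is None:
        dist_kk = cdist(knots.coords, knots.coords)
    mp_om = MaternParams(range_km=nat["range_omega"], sigma=nat["sigma_omega"])
    C_kk = matern_cov(dist_kk, mp_om)
    factor, jitter = chol_with_jitter(C_kk, mp_om.sigma**2)
    if jitter:
        C_kk = C_kk + jitter * np.eye(C_kk.shape[0])
    k = C_kk.shape[0]
    C_ok = matern_cov(dist_ok, mp_om)
    A_om = cho_solve(factor, C_ok.T).T
    Q_om = cho_solve(factor, np.eye(k))
    L = np.tril(factor[0])
    logdet_om = 2.0 * float(np.sum(np.log(np.diag(L))))

    years = design.years
    year_idx = np.searchsorted(years, obs["year"].to_numpy())
    obs_by_year = [np.where(year_idx == t)[0] for t in range(len(years))]

    A_eps = None
    if spec.st_mode == "none":
        Q = Q_om
        logdet = logdet_om
    else:
        mp_eps = MaternParams(range_km=nat["range_eps"], sigma=nat["sigma_eps"])
        st = st_joint_structure(knots, len(years), spec.st_mode,
                                phi=nat.get("phi", 0.0), params=mp_eps)
        if spec.share_range and abs(nat["range_eps"] - nat["range_omega"]) < 1e-12:
            A_eps = A_om  # same correlation structure -> same kriging weights
        else:
            C_kk_e = matern_cov(dist_kk, mp_eps)
            fe, je = chol_with_jitter(C_kk_e, mp_eps.sigma**2)
            A_eps = cho_solve(fe, matern_cov(dist_ok, mp_eps).T).T
        dim = k + len(years) * k
        Q = np.zeros((dim, dim))
        Q[:k, :k] = Q_om
        Q[k:, k:] = st.precision()
        logdet = logdet_om + st.logdet_cov()

    return Structures(
        y=obs["cpue_kg_km2"].to_numpy(dtype=float),
        X=design.X,
        A_om=A_om,
        A_eps=A_eps,
        year_idx=year_idx,
        obs_by_year=obs_by_year,
        Q=Q,
        logdet_cov=logdet,
        family=_make_family(spec, nat),
        n_knots=k,
        n_years=len(years),
        st_mode=spec.st_mode,
    )


# ---------------------------------------------------------------------------
# Inner problem


def inner_mode(
    b: np.ndarray,
    structures: Structures,
    u0: np.ndarray | None = None,
    tol: float = 1e-8,
    maxiter: int = 50,
):
    """Newton optimisation of the penalized log-likelihood over knot effects.

    Maximises ``sum_i l(y_i; eta_i) - u' Q u / 2`` with step-halving on
    non-increase.  Returns ``(u_hat, f_at_mode, Hpos_cho, converged)``
    where ``Hpos = Q - J' W J`` is the (positive-definite) negated Hessian
    at the mode, Cholesky-factorised.
    """
    s = structures
    u = np.zeros(s.dim) if u0 is None else u0.copy()
    eta = s.eta(b, u)
    ll = float(np.sum(s.family.loglik(s.y, eta)))
    f = ll - 0.5 * u @ (s.Q @ u)
    if not np.isfinite(f):
        raise FloatingPointError("non-finite penalized log-likelihood at start")
    converged = False
    Hc = None
    for _ in range(maxiter):
        d1, d2 = s.family.derivs(s.y, eta)
        grad = s.Jt_dot(d1) - s.Q @ u
        gmax = np.max(np.abs(grad)) if s.dim else 0.0
        Hpos = s.Q - s.JtWJ(d2)
        Hc = cho_factor(Hpos, lower=True)
        if gmax < tol:
            converged = True
            break
        step = cho_solve(Hc, grad)
        alpha = 1.0
        for _ in range(30):
            u_new = u + alpha * step
            eta_new = s.eta(b, u_new)
            with np.errstate(over="ignore"):
                f_new = float(np.sum(s.family.loglik(s.y, eta_new))) - 0.5 * u_new @ (
                    s.Q @ u_new
                )
            if np.isfinite(f_new) and f_new >= f - 1e-12:
                break
            alpha *= 0.5
        u, eta, f = u_new, eta_new, f_new
    return u, f, Hc, converged


def laplace_nll(
    b: np.ndarray,
    structures: Structures,
    u0: np.ndarray | None = None,
    tol: float = 1e-8,
    maxiter: int = 50,
):
    """Negative Laplace-approximate marginal log-likelihood.

    -log L = -[ l_data(u_hat) - u_hat' Q u_hat / 2 - log|Sigma|/2
                - log|Hpos|/2 ]

    (the 2*pi factors of the Gaussian prior and the Laplace integral
    cancel).  Returns ``(nll, u_hat, Hpos_cho, converged)``.
    """
    s = structures
    u, f, Hc, conv = inner_mode(b, s, u0=u0, tol=tol, maxiter=maxiter)
    logdet_H = 2.0 * float(np.sum(np.log(np.diag(Hc[0]))))
    nll = -(f - 0.5 * s.logdet_cov - 0.5 * logdet_H)
    return nll, u, Hc, conv


# ---------------------------------------------------------------------------
# Outer optimisation


@dataclass
class FitResult:
    """Everything prediction and uncertainty propagation need."""

    spec: ModelSpec
    design: DesignMatrix
    knots: KnotSet
    b: np.ndarray
    b_names: list[str]
    b_se: np.ndarray | None
    theta: dict  # natural scale
    theta_se: dict | None
    u_omega: np.ndarray  # (k,)
    u_eps: np.ndarray  # (T, k); empty when no spatiotemporal field
    nll: float
    loglik: float
    converged: bool
    n_obs: int
    param_names: list[str]
    param_cov: np.ndarray | None  # covariance of (b, theta_unconstrained)
    inner_hess_cho: tuple
    eta_hat: np.ndarray | None = None  # fitted linear predictor at the data
    message: str = ""

    @property
    def tweedie_params(self) -> TweedieParams | None:
        if self.spec.family != "tweedie":
            return None
        return TweedieParams(p=self.theta["p"], disp=self.theta["disp"])

    def summary(self) -> pd.DataFrame:
        rows = [
            {"param": n, "estimate": v,
             "se": (self.b_se[i] if self.b_se is not None else np.nan)}
            for i, (n, v) in enumerate(zip(self.b_names, self.b))
        ]
        for nme, v in self.theta.items():
            se = np.nan
            if self.theta_se is not None:
                se = self.theta_se.get(nme, np.nan)
            rows.append({"param": nme, "estimate": v, "se": se})
        return pd.DataFrame(rows)

    def modes_frame(self) -> pd.DataFrame:
        """Random-effect modes at the knots, one row per knot."""
        df = self.knots.to_frame()
        df["omega_mode"] = self.u_omega
        for t, year in enumerate(self.design.years):
            if self.u_eps.shape[1]:
                df[f"eps_mode_{year}"] = self.u_eps[t]
        return df

    def to_report(self) -> dict:
        return {
            "loglik": self.loglik,
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "fixed_effects": {
                n: {"estimate": float(v),
                    "se": (float(self.b_se[i]) if self.b_se is not None else None)}
                for i, (n, v) in enumerate(zip(self.b_names, self.b))
            },
            "theta": {k: float(v) for k, v in self.theta.items()},
            "theta_se": (
                {k: float(v) for k, v in self.theta_se.items()}
                if self.theta_se else None
            ),
            "message": self.message,
        }


def _init_values(obs: pd.DataFrame, design: DesignMatrix, spec: ModelSpec, tmap: ThetaMap):
    y = obs["cpue_kg_km2"].to_numpy(dtype=float)
    b0 = np.zeros(design.X.shape[1])
    year_means = {}
    for i, yr in enumerate(design.years):
        m = y[obs["year"].to_numpy() == yr].mean()
        year_means[yr] = max(m, 1e-3)
        b0[i] = math.log(year_means[yr]) if spec.family == "tweedie" else m
    coords = obs[["easting_km", "northing_km"]].to_numpy()
    span = np.ptp(coords, axis=0)
    range0 = max(5.0, 0.15 * float(np.max(span)))
    nat = {"range_omega": range0, "sigma_omega": 0.7}
    if spec.st_mode != "none":
        nat["sigma_eps"] = 0.4
        if not spec.share_range:
            nat["range_eps"] = range0
    if spec.st_mode == "ar1":
        nat["phi"] = 0.2
    if spec.family == "tweedie":
        mu0 = np.array([year_means[yr] for yr in obs["year"]])
        disp0 = float(np.mean((y - mu0) ** 2 / mu0**1.5))
        nat["p"] = 1.5
        nat["disp"] = min(max(disp0, 0.1), 50.0)
    nat = {k: v for k, v in nat.items()}
    for k_, v in tmap.fixed.items():
        nat[k_] = v
    return b0, nat


def fit(spec: ModelSpec, obs: pd.DataFrame, knots: KnotSet | None = None) -> FitResult:
    """Fit one candidate model by Laplace-approximate maximum likelihood.

    Outer quasi-Newton (L-BFGS-B) over fixed effects and transformed
    covariance parameters with forward-difference gradients (relative step
    1e-5), warm-started inner Newton, and ``spec.n_starts`` starting points
    (the extras perturb theta); the best final NLL wins.  Standard errors
    (optional) come from a central finite-difference Hessian at the
    optimum.

    ``knots`` overrides the default data-driven knot selection — e.g. to
    refit subsets of the data on the knot layout of the full survey, so
    the field keeps (prior-level) uncertainty where data were removed.
    """
    design = build_design(obs, include_depth=spec.include_depth)
    n = len(obs)
    n_fixed = design.X.shape[1]
    if n < 10 * n_fixed:
        warnings.warn(
            f"only {n} observations for {n_fixed} fixed effects", stacklevel=2
        )
    coords = obs[["easting_km", "northing_km"]].to_numpy()
    if knots is None:
        knots = select_knots(
            coords, min(spec.n_knots, np.unique(coords, axis=0).shape[0]),
            seed=spec.knot_seed,
        )
    dist_ok = cdist(coords, knots.coords)
    dist_kk = cdist(knots.coords, knots.coords)
    tmap = ThetaMap(spec)
    b0, nat0 = _init_values(obs, design, spec, tmap)
    th0 = tmap.to_unconstrained(nat0)
    x0 = np.concatenate([b0, th0])
    nb = len(b0)

    warm = {"u": None}
    # structures depend on theta only; finite-difference steps over the
    # fixed effects can reuse them
    s_cache: dict[bytes, Structures] = {}

    def structures_for(th: np.ndarray) -> Structures:
        key = th.tobytes()
        if key not in s_cache:
            if len(s_cache) > 8:
                s_cache.clear()
            s_cache[key] = build_structures(
                obs, design, knots, spec, tmap.to_natural(th),
                dist_ok=dist_ok, dist_kk=dist_kk,
            )
        return s_cache[key]

    def objective(x: np.ndarray) -> float:
        b, th = x[:nb], x[nb:]
        try:
            s = structures_for(th)
            nll, u, _, _ = laplace_nll(
                b, s, u0=warm["u"], tol=spec.inner_tol, maxiter=spec.inner_maxiter
            )
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            return 1e10
        if not np.isfinite(nll):
            return 1e10
        warm["u"] = u
        return float(nll)

    cache = {}

    def fun(x):
        key = x.tobytes()
        if key not in cache:
            if len(cache) > 4096:
                cache.clear()
            cache[key] = objective(x)
        return cache[key]

    def jac(x):
        f0 = fun(x)
        g = np.empty_like(x)
        for i in range(len(x)):
            h = 1e-5 * max(1.0, abs(x[i]))
            xp = x.copy()
            xp[i] += h
            g[i] = (fun(xp) - f0) / h
        return g

    rng = np.random.default_rng(spec.knot_seed + 17)
    best = None
    for start in range(spec.n_starts):
        xs = x0.copy()
        if start > 0:
            xs[nb:] = xs[nb:] + rng.normal(0.0, 0.3, size=len(th0))
        warm["u"] = None
        res = minimize(
            fun, xs, jac=jac, method="L-BFGS-B",
            options={"maxiter": spec.maxiter, "gtol": spec.gtol, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    x_hat = best.x
    nll_hat = float(best.fun)
    converged = bool(best.success) and nll_hat < 1e9
    message = str(best.message)

    b_hat, th_hat = x_hat[:nb], x_hat[nb:]
    nat_hat = tmap.to_natural(th_hat)
    s_hat = build_structures(obs, design, knots, spec, nat_hat,
                             dist_ok=dist_ok, dist_kk=dist_kk)
    _, u_hat, Hc, inner_conv = laplace_nll(
        b_hat, s_hat, u0=warm["u"], tol=spec.inner_tol, maxiter=spec.inner_maxiter
    )
    converged = converged and inner_conv
    k = s_hat.n_knots
    u_om = u_hat[:k]
    u_eps = (
        u_hat[k:].reshape(s_hat.n_years, k)
        if spec.st_mode != "none" else np.zeros((s_hat.n_years, 0))
    )

    b_se = theta_se = None
    param_cov = None
    if spec.compute_se:
        d = len(x_hat)
        H = np.empty((d, d))
        steps = 1e-4 * np.maximum(1.0, np.abs(x_hat))
        g_cache = {}

        def grad_at(x):
            key = x.tobytes()
            if key not in g_cache:
                g_cache[key] = jac(x)
            return g_cache[key]

        for i in range(d):
            xp = x_hat.copy(); xp[i] += steps[i]
            xm = x_hat.copy(); xm[i] -= steps[i]
            H[i] = (grad_at(xp) - grad_at(xm)) / (2 * steps[i])
        H = 0.5 * (H + H.T)
        try:
            param_cov = np.linalg.inv(H)
            dvar = np.diag(param_cov)
            if np.any(dvar <= 0):
                raise np.linalg.LinAlgError("non-PD outer Hessian")
            se_all = np.sqrt(dvar)
            b_se = se_all[:nb]
            th_se_t = se_all[nb:]
            jnat = tmap.natural_jacobian(th_hat)
            theta_se = dict(zip(tmap.names, np.abs(jnat) * th_se_t))
        except np.linalg.LinAlgError:
            warnings.warn("outer Hessian not positive definite; SEs unavailable",
                          stacklevel=2)
            b_se = theta_se = None
            param_cov = None

    return FitResult(
        spec=spec,
        design=design,
        knots=knots,
        b=b_hat,
        b_names=list(design.columns),
        b_se=b_se,
        theta=nat_hat,
        theta_se=theta_se,
        u_omega=u_om,
        u_eps=u_eps,
        nll=nll_hat,
        loglik=-nll_hat,
        converged=converged,
        n_obs=n,
        param_names=list(design.columns) + list(tmap.names),
        param_cov=param_cov,
        inner_hess_cho=Hc,
        eta_hat=s_hat.eta(b_hat, u_hat),
        message=message,
    )
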