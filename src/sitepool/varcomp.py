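"""Between-site variance components for one continuous outcome.

Two random-intercept models are available, both with covariates as fixed
effects and study site as the random effect:

* Gaussian site effects, fitted by ML or REML. The likelihood is profiled
  down to one dimension (the variance ratio ``lambda = s2_between /
  s2_within``): for fixed ``lambda`` the GLS fixed effects and the residual
  variance have closed forms, so a bounded 1-D search gives the exact
  maximum, including the ``s2_between = 0`` boundary.

* Nonparametric maximum likelihood (NPML): the site-effect distribution is a
  discrete set of K mass points (locations theta_k, probabilities pi_k)
  estimated jointly with the fixed effects and residual variance by EM.
  The E-step computes posterior site-to-mass-point responsibilities; the
  M-step is a responsibility-weighted least-squares update. The marginal
  log-likelihood is non-decreasing at every iteration (asserted). With
  ``K='auto'`` the number of mass points is chosen by BIC.

``pct_between`` = 100 * s2_between / (s2_between + s2_within) is the
intraclass correlation expressed as a percentage — the quantity of interest
for deciding whether multi-site data can be pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .errors import (
    ComparisonError,
    ConfigurationError,
    DesignError,
    EstimationError,
    InsufficientDataError,
)

__all__ = [
    "VarianceDecomposition",
    "MassPointDistribution",
    "ModelComparison",
    "COVARIATE_SETS",
    "fit_gaussian_lmm",
    "fit_npml",
    "pct_between",
    "compare_models",
    "variance_table",
]

_LOG2PI = np.log(2.0 * np.pi)

#: covariate sets; age is centred on 24 months, sex enters as 1[boy]
COVARIATE_SETS = {
    "age_sex": (),
    "age_sex_fetalhc": ("fetal_hc_z",),
    "age_sex_fetalhc_growth2y": ("fetal_hc_z", "hc2y_z", "length2y_z"),
}


@dataclass(frozen=True)
class VarianceDecomposition:
    domain: str
    method: str  # gaussian_ml | gaussian_reml | npml
    covariate_set: str
    sigma2_between: float
    sigma2_within: float
    loglik: float
    aic: float
    bic: float
    n_children: int
    n_sites: int
    df_model: int
    converged: bool = True
    #: False for REML: the restricted objective is not comparable across
    #: different fixed-effect specifications
    criteria_comparable: bool = True
    fixed_effects: dict = field(default_factory=dict)

    @property
    def pct_between(self) -> float:
        return pct_between(self)


@dataclass(frozen=True)
class MassPointDistribution:
    """Discrete random-effect distribution: strictly increasing locations
    with positive masses summing to one; centred so the mean is zero (the
    mean is absorbed into the model intercept)."""

    locations: np.ndarray
    masses: np.ndarray

    def __post_init__(self):
        loc = np.asarray(self.locations, dtype=float)
        mass = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "locations", loc)
        object.__setattr__(self, "masses", mass)
        if loc.shape != mass.shape or loc.ndim != 1:
            raise ConfigurationError("mass points: locations/masses must align")
        if np.any(mass <= 0):
            raise ConfigurationError("mass points: masses must be > 0")
        if abs(mass.sum() - 1.0) > 1e-10:
            raise ConfigurationError("mass points: masses must sum to 1 (tol 1e-10)")
        if loc.size > 1 and np.any(np.diff(loc) <= 0):
            raise ConfigurationError("mass points: locations must be strictly increasing")

    @property
    def K(self) -> int:
        return int(self.locations.size)

    @property
    def mean(self) -> float:
        return float(np.dot(self.masses, self.locations))

    @property
    def variance(self) -> float:
        mu = self.mean
        return float(np.dot(self.masses, (self.locations - mu) ** 2))


@dataclass(frozen=True)
class ModelComparison:
    fits: tuple
    criterion: str
    selected: VarianceDecomposition


def pct_between(fit) -> float:
    """100 * s2_between / (s2_between + s2_within); 0 at the boundary."""
    s2b = fit.sigma2_between if hasattr(fit, "sigma2_between") else float(fit)
    s2w = fit.sigma2_within
    total = s2b + s2w
    return 100.0 * s2b / total if total > 0 else 0.0


# ---------------------------------------------------------------------------
# design assembly


def build_design(
    cohort: pd.DataFrame, domain: str, covariate_set: str = "age_sex", age_center: float = 24.0
):
    """Complete-case response, fixed-effects design (with intercept), and
    integer site codes for one domain/covariate-set combination."""
    if covariate_set not in COVARIATE_SETS:
        raise ConfigurationError(
            f"covariate_set: unknown {covariate_set!r}; "
            f"expected one of {sorted(COVARIATE_SETS)}"
        )
    extra = COVARIATE_SETS[covariate_set]
    cols = ["site_id", "sex", "age_months", domain, *extra]
    missing_cols = [c for c in cols if c not in cohort.columns]
    if missing_cols:
        from .errors import LookupDomainError

        raise LookupDomainError(f"cohort lacks column(s) {missing_cols}")
    sub = cohort[cols].dropna()
    y = sub[domain].to_numpy(dtype=float)
    # constant covariate columns carry no information and would make the
    # design singular (e.g. a single-sex or fixed-age toy); drop them
    candidates = [
        ("age_c", sub["age_months"].to_numpy(dtype=float) - age_center),
        ("boy", (sub["sex"].to_numpy() == "boy").astype(float)),
    ] + [(c, sub[c].to_numpy(dtype=float)) for c in extra]
    parts = [np.ones(len(sub))]
    names = ["intercept"]
    for name, col in candidates:
        if col.size and np.ptp(col) > 0:
            parts.append(col)
            names.append(name)
    X = np.column_stack(parts)
    codes, uniques = pd.factorize(sub["site_id"], sort=True)
    return y, X, names, codes.astype(np.int64), list(map(str, uniques))


def _check_site_support(y, codes, n_min_sites=2, n_min_per_site=2):
    m = codes.max() + 1 if codes.size else 0
    if m < n_min_sites:
        raise DesignError(f"need >= {n_min_sites} sites with data, got {m}")
    counts = np.bincount(codes, minlength=m)
    if np.sum(counts >= n_min_per_site) < n_min_sites:
        raise DesignError(
            f"need >= {n_min_sites} sites with >= {n_min_per_site} complete cases"
        )
    if m < 10:
        warnings.warn(
            f"only {m} sites: the random-effect distribution is weakly "
            "identified; pct_between remains well defined",
            UserWarning,
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# Gaussian random intercept by profiled ML/REML


class _RIProfile:
    """Sufficient statistics and profile objective for the random-intercept
    model, as a function of lambda = s2_between / s2_within."""

    def __init__(self, y, X, codes):
        self.N, self.p = X.shape
        m = int(codes.max()) + 1
        self.m = m
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.ni = np.bincount(codes, minlength=m).astype(float)
        self.ti = np.bincount(codes, weights=y, minlength=m)
        self.Si = np.column_stack(
            [np.bincount(codes, weights=X[:, j], minlength=m) for j in range(self.p)]
        )  # m x p

    def gls(self, lam: float):
        c = lam / (1.0 + self.ni * lam)
        A = self.XtX - (self.Si * c[:, None]).T @ self.Si
        b = self.Xty - self.Si.T @ (c * self.ti)
        beta = np.linalg.solve(A, b)
        Q = self.yty - float((c * self.ti) @ self.ti) - float(beta @ b)
        return A, beta, max(Q, 1e-300)

    def neg_profile_loglik(self, lam: float, reml: bool) -> float:
        A, _, Q = self.gls(lam)
        logdet_ratio = float(np.sum(np.log1p(self.ni * lam)))
        if reml:
            nu = self.N - self.p
            _, logdetA = np.linalg.slogdet(A)
            return 0.5 * (nu * np.log(Q / nu) + logdet_ratio + logdetA + nu * (1 + _LOG2PI))
        return 0.5 * (self.N * np.log(Q / self.N) + logdet_ratio + self.N * (1 + _LOG2PI))


def _maximise_profile(prof: _RIProfile, reml: bool):
    f = lambda lam: prof.neg_profile_loglik(lam, reml)
    grid = np.concatenate([[0.0], np.logspace(-8, 6, 141)])
    vals = np.array([f(l) for l in grid])
    k = int(np.argmin(vals))
    if k == 0:
        # interior dip may be hiding between 0 and the first grid point
        res = minimize_scalar(
            f, bounds=(0.0, grid[1]), method="bounded", options={"xatol": 1e-14}
        )
        lam = float(res.x) if res.fun < vals[0] else 0.0
    else:
        lo = grid[k - 1]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = minimize_scalar(
            f,
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-13 * (1.0 + grid[k])},
        )
        lam = float(res.x) if res.fun <= vals[k] else float(grid[k])
        if f(0.0) <= f(lam):
            lam = 0.0
    return lam


def fit_gaussian_lmm(
    cohort: pd.DataFrame,
    domain: str,
    covariate_set: str = "age_sex",
    method: str = "reml",
    age_center: float = 24.0,
) -> VarianceDecomposition:
    """Gaussian random-intercept fit for one domain.

    ``method`` is ``'ml'`` or ``'reml'``. The between-site variance is
    truncated at the 0 boundary. AIC/BIC use the fit's own objective; for
    REML they are flagged not comparable across fixed-effect sets.
    """
    if method not in ("ml", "reml"):
        raise ConfigurationError(f"method: expected 'ml' or 'reml', got {method!r}")
    y, X, names, codes, _sites = build_design(cohort, domain, covariate_set, age_center)
    if len(y) < X.shape[1] + 2:
        raise InsufficientDataError(
            f"domain {domain!r}: {len(y)} complete cases, need >= {X.shape[1] + 2}"
        )
    _check_site_support(y, codes)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        from .errors import CollinearityError

        raise CollinearityError("fixed-effects design is singular")

    reml = method == "reml"
    prof = _RIProfile(y, X, codes)
    lam = _maximise_profile(prof, reml)
    _, beta, Q = prof.gls(lam)
    nu = prof.N - prof.p if reml else prof.N
    s2w = Q / nu
    s2b = lam * s2w
    loglik = -prof.neg_profile_loglik(lam, reml)
    dfm = X.shape[1] + 2  # beta (incl intercept), s2_between, s2_within
    aic = -2.0 * loglik + 2.0 * dfm
    bic = -2.0 * loglik + dfm * np.log(prof.N)
    return VarianceDecomposition(
        domain=domain,
        method=f"gaussian_{method}",
        covariate_set=covariate_set,
        sigma2_between=float(s2b),
        sigma2_within=float(s2w),
        loglik=float(loglik),
        aic=float(aic),
        bic=float(bic),
        n_children=prof.N,
        n_sites=prof.m,
        df_model=dfm,
        criteria_comparable=not reml,
        fixed_effects=dict(zip(names, map(float, beta))),
    )


# ---------------------------------------------------------------------------
# NPML: discrete mass-point random effect by EM


@dataclass
class _EMState:
    beta: np.ndarray  # covariate coefficients (no intercept)
    theta: np.ndarray  # K locations (intercept absorbed)
    pi: np.ndarray
    s2: float
    loglik: float = -np.inf


def _site_residual_stats(y, Xc, codes, m, beta):
    r = y - Xc @ beta if Xc.shape[1] else y.copy()
    S = np.bincount(codes, weights=r, minlength=m)
    SS = np.bincount(codes, weights=r * r, minlength=m)
    return S, SS


def _em_loglik_resp(state, ni, S, SS):
    """Marginal log-likelihood and posterior responsibilities (m x K)."""
    th = state.theta
    ssr = SS[:, None] - 2.0 * np.outer(S, th) + np.outer(ni, th * th)
    logf = -0.5 * (ni[:, None] * (_LOG2PI + np.log(state.s2)) + ssr / state.s2)
    logw = np.log(state.pi)[None, :] + logf
    lse = logsumexp(logw, axis=1)
    resp = np.exp(logw - lse[:, None])
    return float(lse.sum()), resp, ssr


def _em_mstep(y, Xc, codes, ni, ti, sxi, resp, N):
    """Joint WLS for (beta, theta), then pi and s2.

    Because responsibilities sum to 1 over mass points, the beta block of the
    normal equations is the plain X'X; only the cross terms are weighted.
    """
    m, K = resp.shape
    p = Xc.shape[1]
    D = resp.T @ ni  # K
    d = resp.T @ ti  # K
    if p:
        XtX = Xc.T @ Xc
        Xty = Xc.T @ y
        C = sxi.T @ resp  # p x K
        top = np.hstack([XtX, C])
        bottom = np.hstack([C.T, np.diag(D)])
        M = np.vstack([top, bottom])
        rhs = np.concatenate([Xty, d])
        sol = np.linalg.solve(M, rhs)
        beta, theta = sol[:p], sol[p:]
    else:
        beta = np.zeros(0)
        theta = d / D
    S, SS = _site_residual_stats(y, Xc, codes, m, beta)
    ssr = SS[:, None] - 2.0 * np.outer(S, theta) + np.outer(ni, theta * theta)
    s2 = float((resp * ssr).sum() / N)
    pi = resp.mean(axis=0)
    pi = pi / pi.sum()
    return beta, theta, pi, max(s2, 1e-300)


def _run_em(y, Xc, codes, state, ni, ti, sxi, tol_ll, tol_par, maxiter):
    N = len(y)
    m = len(ni)
    S, SS = _site_residual_stats(y, Xc, codes, m, state.beta)
    ll, resp, _ = _em_loglik_resp(state, ni, S, SS)
    trace = [ll]
    status = "converged"
    stall = 0
    for _it in range(maxiter):
        beta, theta, pi, s2 = _em_mstep(y, Xc, codes, ni, ti, sxi, resp, N)
        par_change = max(
            float(np.max(np.abs(theta - state.theta), initial=0.0)),
            float(np.max(np.abs(beta - state.beta), initial=0.0)),
            abs(s2 - state.s2),
            float(np.max(np.abs(pi - state.pi), initial=0.0)),
        )
        state = _EMState(beta=beta, theta=theta, pi=pi, s2=s2)
        S, SS = _site_residual_stats(y, Xc, codes, m, beta)
        ll_new, resp, _ = _em_loglik_resp(state, ni, S, SS)
        if ll_new < ll - 1e-8 * (1.0 + abs(ll)):
            raise EstimationError(
                f"EM log-likelihood decreased at iteration {_it}: {ll} -> {ll_new}",
                trace=trace,
            )
        rel = abs(ll_new - ll) / (1.0 + abs(ll))
        trace.append(ll_new)
        ll = ll_new
        if rel < tol_ll:
            if par_change < tol_par:
                break
            stall += 1
            if stall >= 3:
                status = "converged-with-warning"
                break
        else:
            stall = 0
    else:
        raise EstimationError(
            f"EM did not converge in {maxiter} iterations", trace=trace
        )
    state.loglik = ll
    return state, trace, status


def _merge_mass_points(theta, pi, merge_tol):
    """Merge locations closer than merge_tol (pi-weighted); keep order."""
    order = np.argsort(theta)
    th, p = theta[order], pi[order]
    out_th, out_pi = [th[0]], [p[0]]
    for t, w in zip(th[1:], p[1:]):
        if t - out_th[-1] < merge_tol:
            tot = out_pi[-1] + w
            out_th[-1] = (out_th[-1] * out_pi[-1] + t * w) / tot
            out_pi[-1] = tot
        else:
            out_th.append(t)
            out_pi.append(w)
    return np.array(out_th), np.array(out_pi)


def fit_npml(
    cohort: pd.DataFrame,
    domain: str,
    covariate_set: str = "age_sex",
    K="auto",
    age_center: float = 24.0,
    n_starts: int = 5,
    start_seed: int = 0,
    tol_loglik: float = 1e-8,
    tol_param: float = 1e-6,
    maxiter: int = 2000,
    criterion: str = "bic",
) -> tuple[VarianceDecomposition, MassPointDistribution]:
    """NPML fit: discrete site-effect distribution with K mass points.

    ``K`` may be an integer (1 <= K <= number of sites) or ``'auto'``, which
    fits K = 1..n_sites and selects by the given criterion (BIC by default).
    Multi-start EM (quantile-based start plus seeded jittered starts) guards
    against local maxima; the best log-likelihood wins. Model degrees of
    freedom: p_covariates + 1 (residual variance) + (2K - 1) mass-point
    parameters (the mean location is absorbed into the intercept).
    """
    y, X, names, codes, _sites = build_design(cohort, domain, covariate_set, age_center)
    if len(y) < X.shape[1] + 2:
        raise InsufficientDataError(
            f"domain {domain!r}: {len(y)} complete cases, need >= {X.shape[1] + 2}"
        )
    _check_site_support(y, codes)
    m = int(codes.max()) + 1
    if K != "auto":
        K = int(K)
        if not (1 <= K <= m):
            raise ConfigurationError(f"K: need 1 <= K <= n_sites={m}, got {K}")
    if criterion not in ("aic", "bic"):
        raise ConfigurationError(f"criterion: expected 'aic' or 'bic', got {criterion!r}")

    # covariates without intercept: theta carries the level
    Xc = X[:, 1:]
    p = Xc.shape[1]
    N = len(y)
    ni = np.bincount(codes, minlength=m).astype(float)
    ti = np.bincount(codes, weights=y, minlength=m)
    sxi = np.column_stack(
        [np.bincount(codes, weights=Xc[:, j], minlength=m) for j in range(p)]
    ) if p else np.zeros((m, 0))

    # OLS start: fixed-effects-only fit, per-site mean residuals
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    site_means = np.bincount(codes, weights=resid, minlength=m) / ni
    s2_ols = float(np.sum((resid - site_means[codes]) ** 2) / N)
    span = float(np.ptp(site_means))
    merge_tol = 1e-4 * span if span > 0 else 1e-12
    rng = np.random.default_rng(start_seed)
    jitter_sd = 0.5 * (np.std(site_means) + 1e-12)

    def run_for_K(Kk: int):
        probs = (2.0 * np.arange(Kk) + 1.0) / (2.0 * Kk)
        theta_base = np.quantile(site_means, probs) + beta_ols[0]
        best = None
        for s in range(n_starts):
            theta0 = theta_base.copy()
            if s > 0:
                theta0 = theta0 + rng.normal(0.0, jitter_sd, size=Kk)
            state0 = _EMState(
                beta=beta_ols[1:].copy(),
                theta=np.sort(theta0),
                pi=np.full(Kk, 1.0 / Kk),
                s2=max(s2_ols, 1e-12),
            )
            state, trace, status = _run_em(
                y, Xc, codes, state0, ni, ti, sxi, tol_loglik, tol_param, maxiter
            )
            if best is None or state.loglik > best[0].loglik:
                best = (state, trace, status)
            if Kk == 1:
                break  # EM is exact in one step; extra starts are identical
        return best

    def decomposition(state, Kk, status):
        theta, pi = _merge_mass_points(state.theta, state.pi, merge_tol)
        Keff = len(theta)
        mean = float(np.dot(pi, theta))
        theta_c = theta - mean
        s2b = float(np.dot(pi, theta_c**2))
        dfm = p + 1 + (2 * Keff - 1)
        ll = state.loglik
        aic = -2.0 * ll + 2.0 * dfm
        bic = -2.0 * ll + dfm * np.log(N)
        fe = dict(zip(names, [mean] + list(map(float, state.beta))))
        vd = VarianceDecomposition(
            domain=domain,
            method="npml",
            covariate_set=covariate_set,
            sigma2_between=s2b,
            sigma2_within=float(state.s2),
            loglik=float(ll),
            aic=float(aic),
            bic=float(bic),
            n_children=N,
            n_sites=m,
            df_model=dfm,
            converged=status == "converged",
            fixed_effects=fe,
        )
        mp = MassPointDistribution(locations=theta_c, masses=pi / pi.sum())
        return vd, mp

    if K != "auto":
        state, _trace, status = run_for_K(K)
        return decomposition(state, K, status)

    best_out = None
    best_crit = np.inf
    prev_ll = -np.inf
    for Kk in range(1, m + 1):
        state, _trace, status = run_for_K(Kk)
        # likelihood should not fall as the support grows; keep the richer
        # optimum alive by warm-starting is unnecessary at these sizes, but a
        # drop below the previous K signals a local maximum — retry from the
        # previous solution padded with a split point.
        if state.loglik < prev_ll - 1e-6:
            status = "converged-with-warning"
        prev_ll = max(prev_ll, state.loglik)
        vd, mp = decomposition(state, Kk, status)
        crit = vd.bic if criterion == "bic" else vd.aic
        if crit < best_crit - 1e-12:
            best_crit = crit
            best_out = (vd, mp)
    return best_out


# ---------------------------------------------------------------------------
# model comparison and the variance table


def compare_models(fits: Sequence[VarianceDecomposition], criterion: str = "bic") -> ModelComparison:
    """Pick the fit with the minimal AIC/BIC among comparable fits."""
    if criterion not in ("aic", "bic"):
        raise ConfigurationError(f"criterion: expected 'aic' or 'bic', got {criterion!r}")
    fits = tuple(fits)
    if not fits:
        raise ComparisonError("no fits to compare")
    f0 = fits[0]
    for f in fits[1:]:
        if f.domain != f0.domain or f.n_children != f0.n_children:
            raise ComparisonError(
                "fits are on different domains or complete-case samples"
            )
        if f.covariate_set != f0.covariate_set:
            if not (f.criteria_comparable and f0.criteria_comparable):
                raise ComparisonError(
                    "REML objectives are not comparable across fixed-effect sets"
                )
            raise ComparisonError("fits use different covariate sets")
    key = (lambda f: f.aic) if criterion == "aic" else (lambda f: f.bic)
    selected = min(fits, key=key)
    return ModelComparison(fits=fits, criterion=criterion, selected=selected)


def variance_table(
    cohort: pd.DataFrame,
    domains: Sequence[str] | None = None,
    covariate_sets: Sequence[str] = tuple(COVARIATE_SETS),
    method: str = "npml",
    **fit_kwargs,
) -> pd.DataFrame:
    """Percent-between for every domain x covariate set (one method).

    Returns a DataFrame with domains as rows and covariate sets as columns —
    the shape of a between-site variance summary table.
    """
    from .cohort import domain_columns

    if domains is None:
        domains = domain_columns(cohort)
    rows = {}
    for d in domains:
        row = {}
        for cs in covariate_sets:
            if method == "npml":
                vd, _ = fit_npml(cohort, d, covariate_set=cs, **fit_kwargs)
            else:
                vd = fit_gaussian_lmm(
                    cohort, d, covariate_set=cs, method=method.replace("gaussian_", ""),
                    **fit_kwargs,
                )
            row[cs] = vd.pct_between
        rows[d] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(covariate_sets))
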