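"""Binomial mixed models for photoperiodic reaction norms.

The response is the binary diapause outcome; the linear predictor on the
logit scale carries one intercept per population (no global intercept, so a
population's critical daylength reads directly off its coefficient), a
shared daylength slope, optionally a warm-treatment offset, and optional
population interactions. Non-independence of siblings is absorbed by a
family-level Normal random intercept whose marginal likelihood is computed
by adaptive Gauss–Hermite quadrature.

Inference follows the standard mixed-model workflow for this design:
Type-II likelihood-ratio tests for the fixed terms, single-step (Tukey-type)
multiplicity adjustment for all pairwise population contrasts based on the
joint normal distribution of the estimates, and a boundary-corrected
(halved-p) likelihood-ratio test for the random-effect variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp
from numpy.polynomial.hermite import hermgauss

#: Terms allowed in a model specification.
FIXED_TERMS = (
    "daylength",
    "population",
    "temperature",
    "daylength:population",
    "temperature:population",
)

_INTERACTION_PARENTS = {
    "daylength:population": ("daylength", "population"),
    "temperature:population": ("temperature", "population"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed terms enter the model, and whether family is a random effect."""

    fixed_terms: frozenset = frozenset({"daylength", "population"})
    random_intercept: bool = True
    reference_population: str | None = None

    def __post_init__(self) -> None:
        terms = frozenset(self.fixed_terms)
        unknown = terms - set(FIXED_TERMS)
        if unknown:
            raise ValueError(f"unknown model terms: {sorted(unknown)}")
        for inter, parents in _INTERACTION_PARENTS.items():
            if inter in terms and not all(p in terms for p in parents):
                raise ValueError(f"{inter} requires both main effects {parents}")
        object.__setattr__(self, "fixed_terms", terms)

    def drop(self, term: str) -> "ModelSpec":
        return ModelSpec(
            fixed_terms=self.fixed_terms - {term},
            random_intercept=self.random_intercept,
            reference_population=self.reference_population,
        )


@dataclass
class GlmmFit:
    """A fitted reaction-norm model."""

    spec: ModelSpec
    populations: list[str]
    coef_names: list[str]
    beta: np.ndarray
    vcov: np.ndarray
    sigma_f: float
    loglik: float
    n_obs: int
    n_families: int
    converged: bool
    grad_norm: float
    separation: dict[str, bool]
    n_quad: int = 15

    @property
    def separation_flag(self) -> bool:
        return any(self.separation.values())

    def coef(self, name: str) -> float:
        return float(self.beta[self.coef_names.index(name)])

    def intercept_of(self, population: str) -> float:
        return self.coef(f"pop[{population}]")

    def summary_frame(self) -> pd.DataFrame:
        se = np.sqrt(np.clip(np.diag(self.vcov), 0, None))
        return pd.DataFrame(
            {"term": self.coef_names, "estimate": self.beta, "se": se}
        )


@dataclass(frozen=True)
class TermTest:
    term: str
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class PairwiseContrast:
    pair: tuple[str, str]
    estimate: float
    se: float
    z: float
    p_raw: float
    p_adjusted: float


# ---------------------------------------------------------------------------
# design matrix


def build_design(scored: pd.DataFrame, spec: ModelSpec):
    """Design matrix, response, family codes and coefficient names."""
    pops = sorted(scored["population"].unique())
    ref = spec.reference_population or pops[0]
    if ref not in pops:
        raise ValueError(f"reference population {ref!r} not present in the data")
    terms = spec.fixed_terms
    n = len(scored)
    cols: list[np.ndarray] = []
    names: list[str] = []
    pop_arr = scored["population"].to_numpy()
    day = scored["daylength_h"].to_numpy(float)
    warm = (scored["temperature"].to_numpy() == "warm").astype(float)

    if "population" in terms:
        for p in pops:
            cols.append((pop_arr == p).astype(float))
            names.append(f"pop[{p}]")
    else:
        cols.append(np.ones(n))
        names.append("intercept")
    if "daylength" in terms:
        cols.append(day)
        names.append("daylength")
    if "daylength:population" in terms:
        for p in pops:
            if p == ref:
                continue
            cols.append(day * (pop_arr == p))
            names.append(f"daylength:pop[{p}]")
    if "temperature" in terms:
        cols.append(warm)
        names.append("temp[warm]")
    if "temperature:population" in terms:
        for p in pops:
            if p == ref:
                continue
            cols.append(warm * (pop_arr == p))
            names.append(f"temp[warm]:pop[{p}]")

    X = np.column_stack(cols)
    y = scored["diapause"].to_numpy(float)
    fam_codes, fam_idx = np.unique(scored["family_id"].to_numpy(), return_inverse=True)
    return X, y, fam_idx, len(fam_codes), names, pops


def detect_separation(scored: pd.DataFrame) -> dict[str, bool]:
    """Per-population complete separation of outcome by daylength.

    A population is flagged when its outcomes are perfectly predicted by
    daylength — all diapausers at strictly shorter days than all direct
    developers (or it shows only one outcome class at all), so the
    population's reaction-norm slope or intercept is unbounded.
    """
    flags: dict[str, bool] = {}
    for pop, sub in scored.groupby("population"):
        d1 = sub.loc[sub["diapause"] == 1, "daylength_h"]
        d0 = sub.loc[sub["diapause"] == 0, "daylength_h"]
        if len(d1) == 0 or len(d0) == 0:
            flags[pop] = True
        else:
            flags[pop] = bool(d1.max() < d0.min() or d0.max() < d1.min())
    return flags


# ---------------------------------------------------------------------------
# likelihood


def _bernoulli_loglik_terms(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    # y*eta - log(1 + e^eta), numerically stable
    return y * eta - np.logaddexp(0.0, eta)


def glmm_loglik(
    beta: np.ndarray,
    sigma_f: float,
    X: np.ndarray,
    y: np.ndarray,
    fam_idx: np.ndarray,
    n_families: int,
    n_quad: int = 15,
) -> float:
    """Marginal log-likelihood with the family intercept integrated out.

    Uses adaptive Gauss–Hermite quadrature with ``n_quad`` nodes: per
    family the integrand is re-centred on its mode and re-scaled by its
    curvature before applying the Hermite rule. With ``sigma_f == 0`` the
    integral collapses and the plain Bernoulli log-likelihood is returned
    exactly.
    """
    beta = np.asarray(beta, float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("non-finite coefficients")
    if sigma_f < 0:
        raise ValueError("sigma_f must be >= 0")
    if n_quad < 1:
        raise ValueError("n_quad must be >= 1")
    eta0 = X @ beta
    if sigma_f == 0.0:
        return float(_bernoulli_loglik_terms(eta0, y).sum())

    s2 = sigma_f * sigma_f
    # inner Newton for the per-family posterior mode of the random intercept
    u = np.zeros(n_families)
    for _ in range(200):
        p = 1.0 / (1.0 + np.exp(-(eta0 + u[fam_idx])))
        grad = np.bincount(fam_idx, weights=y - p, minlength=n_families) - u / s2
        curv = np.bincount(fam_idx, weights=p * (1 - p), minlength=n_families) + 1.0 / s2
        step = grad / curv
        u += np.clip(step, -10.0, 10.0)
        if np.max(np.abs(grad)) < 1e-12:
            break
    p = 1.0 / (1.0 + np.exp(-(eta0 + u[fam_idx])))
    curv = np.bincount(fam_idx, weights=p * (1 - p), minlength=n_families) + 1.0 / s2
    scale = 1.0 / np.sqrt(curv)  # per-family adaptive scale

    z, w = hermgauss(n_quad)
    # u_fq = mode_f + sqrt(2) * scale_f * z_q ; h includes the N(0, s2) prior
    u_q = u[:, None] + np.sqrt(2.0) * scale[:, None] * z[None, :]
    eta_q = eta0[:, None] + u_q[fam_idx]
    ll_obs = y[:, None] * eta_q - np.logaddexp(0.0, eta_q)
    h = np.zeros((n_families, n_quad))
    for q in range(n_quad):
        h[:, q] = np.bincount(fam_idx, weights=ll_obs[:, q], minlength=n_families)
    h += -0.5 * u_q**2 / s2 - 0.5 * np.log(2 * np.pi * s2)
    log_lf = logsumexp(np.log(w)[None, :] + z[None, :] ** 2 + h, axis=1)
    log_lf += 0.5 * np.log(2.0) + np.log(scale)
    return float(log_lf.sum())


def glmm_loglik_frame(
    beta,
    sigma_f: float,
    scored: pd.DataFrame,
    spec: ModelSpec | None = None,
    n_quad: int = 15,
) -> float:
    """Marginal log-likelihood evaluated on a scored table (convenience)."""
    spec = spec or ModelSpec()
    X, y, fam_idx, n_fam, _, _ = build_design(scored, spec)
    return glmm_loglik(np.asarray(beta, float), sigma_f, X, y, fam_idx, n_fam, n_quad)


# ---------------------------------------------------------------------------
# plain logistic (IRLS) — the sigma_f = 0 backbone, also used by the bootstrap


def fit_logistic_irls(
    X: np.ndarray,
    successes: np.ndarray,
    trials: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-12,
):
    """Binomial logistic ML fit by iteratively reweighted least squares.

    ``successes``/``trials`` allow aggregated (grouped) data; with
    ``trials=None`` the response is Bernoulli 0/1. Returns
    ``(beta, loglik, vcov, converged)``.
    """
    X = np.asarray(X, float)
    k = np.asarray(successes, float)
    n = np.ones_like(k) if trials is None else np.asarray(trials, float)
    p_dim = X.shape[1]
    beta = np.zeros(p_dim)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = n * mu * (1 - mu)
        grad = X.T @ (k - n * mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p_dim), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # damp huge steps (near-separation)
        norm = np.max(np.abs(step))
        if norm > 10.0:
            step *= 10.0 / norm
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(k * eta - n * np.logaddexp(0.0, eta)))
    w = n * mu * (1 - mu)
    H = (X * w[:, None]).T @ X
    try:
        vcov = np.linalg.inv(H + 1e-12 * np.eye(p_dim))
    except np.linalg.LinAlgError:
        vcov = np.full((p_dim, p_dim), np.nan)
    return beta, ll, vcov, converged


# ---------------------------------------------------------------------------
# fitting


_LOG_SIGMA_MIN = np.log(1e-8)
_LOG_SIGMA_MAX = np.log(50.0)
#: sigma_f below this is reported as a zero variance estimate (boundary).
SIGMA_ZERO_TOL = 1e-6


def fit_glmm(scored: pd.DataFrame, spec: ModelSpec | None = None, n_quad: int = 15) -> GlmmFit:
    """Maximum-likelihood fit of the reaction-norm model.

    Starts from a plain logistic fit (and sigma_f = 0.1), maximises the
    adaptive-quadrature marginal likelihood over ``(beta, log sigma_f)`` by
    quasi-Newton, and takes the fixed-effect covariance from the observed
    information at the optimum. Complete separation is flagged per
    population; the fit is still returned so callers can inspect it, but
    critical-daylength extraction refuses flagged fits.
    """
    spec = spec or ModelSpec()
    if scored["daylength_h"].nunique() < 2:
        raise ValueError("need at least two distinct daylengths to fit a reaction norm")
    X, y, fam_idx, n_fam, names, pops = build_design(scored, spec)
    separation = detect_separation(scored)

    beta0, ll0, vcov0, _ = fit_logistic_irls(X, y)
    if np.any(np.abs(beta0) > 50.0):
        # diverging plain fit is itself evidence of separation
        for p in pops:
            separation.setdefault(p, False)

    if not spec.random_intercept:
        grad = X.T @ (y - 1.0 / (1.0 + np.exp(-(X @ beta0))))
        gnorm = float(np.max(np.abs(grad)))
        return GlmmFit(
            spec, pops, names, beta0, vcov0, 0.0, ll0, len(y), n_fam,
            converged=gnorm < 1e-3, grad_norm=gnorm, separation=separation,
            n_quad=n_quad,
        )

    def objective(theta: np.ndarray) -> float:
        beta = theta[:-1]
        sigma = float(np.exp(theta[-1]))
        return -glmm_loglik(beta, sigma, X, y, fam_idx, n_fam, n_quad)

    theta0 = np.append(beta0, np.log(0.1))
    # intercepts scale as |slope| x CDL (tens of hours), so the box must sit
    # far beyond the |slope| > 50 separation cap
    bounds = [(-2000.0, 2000.0)] * len(beta0) + [(_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)]
    res = optimize.minimize(
        objective,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9},
    )
    theta = res.x
    beta = theta[:-1]
    sigma = float(np.exp(theta[-1]))
    loglik = -objective(theta)

    # boundary polish: if freeing the variance does not improve on the plain
    # logistic likelihood beyond numerical noise, the MLE sits on sigma = 0
    at_boundary = sigma < SIGMA_ZERO_TOL or loglik - ll0 < 1e-7
    if at_boundary and ll0 >= loglik - 1e-7:
        beta, loglik, sigma = beta0, ll0, 0.0

    gnorm = _grad_sup_norm(objective, np.append(beta, np.log(max(sigma, 1e-8))))
    vcov = _observed_info_vcov(
        lambda b: -glmm_loglik(b, sigma, X, y, fam_idx, n_fam, n_quad), beta
    )
    sigma_out = 0.0 if sigma < SIGMA_ZERO_TOL else sigma
    return GlmmFit(
        spec, pops, names, beta, vcov, sigma_out, loglik, len(y), n_fam,
        converged=bool(gnorm < 1e-3 and np.all(np.isfinite(vcov))),
        grad_norm=gnorm, separation=separation, n_quad=n_quad,
    )


def _grad_sup_norm(fun, x: np.ndarray, h: float = 1e-6) -> float:
    g = np.zeros_like(x)
    for i in range(len(x)):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (fun(x + e) - fun(x - e)) / (2 * h)
    return float(np.max(np.abs(g)))


def _observed_info_vcov(nll, beta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Covariance of fixed effects from the numeric observed information."""
    p = len(beta)
    H = np.zeros((p, p))
    f0 = nll(beta)
    for i in range(p):
        ei = np.zeros(p); ei[i] = h
        for j in range(i, p):
            ej = np.zeros(p); ej[j] = h
            if i == j:
                H[i, i] = (nll(beta + ei) - 2 * f0 + nll(beta - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    nll(beta + ei + ej) - nll(beta + ei - ej)
                    - nll(beta - ei + ej) + nll(beta - ei - ej)
                ) / (4 * h**2)
    try:
        V = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full((p, p), np.nan)
    return 0.5 * (V + V.T)


# ---------------------------------------------------------------------------
# tests


def lrt_type2(scored: pd.DataFrame, spec: ModelSpec, n_quad: int = 15) -> list[TermTest]:
    """Type-II likelihood-ratio tests for every fixed term in ``spec``.

    A main effect is tested against the model holding all other terms but
    no interactions involving the tested term; an interaction is tested
    against the full model minus that interaction.
    """
    tests: list[TermTest] = []
    fits: dict[frozenset, GlmmFit] = {}

    def fit_for(terms: frozenset) -> GlmmFit:
        if terms not in fits:
            sub = ModelSpec(terms, spec.random_intercept, spec.reference_population)
            fits[terms] = fit_glmm(scored, sub, n_quad)
        return fits[terms]

    for term in sorted(spec.fixed_terms):
        if term in _INTERACTION_PARENTS:
            base_terms = spec.fixed_terms
        else:
            involving = {
                it for it, parents in _INTERACTION_PARENTS.items()
                if term in parents and it in spec.fixed_terms
            }
            base_terms = spec.fixed_terms - involving
        reduced_terms = base_terms - {term}
        full = fit_for(frozenset(base_terms))
        red = fit_for(frozenset(reduced_terms))
        df = len(full.coef_names) - len(red.coef_names)
        if df < 1:
            raise ValueError(f"term {term!r} adds no coefficients; non-nested comparison")
        chi2 = max(0.0, 2.0 * (full.loglik - red.loglik))
        p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
        tests.append(TermTest(term, chi2, df, p))
    return tests


def tukey_pairwise(
    fit: GlmmFit, mc_draws: int = 100_000, seed: int = 0
) -> list[PairwiseContrast]:
    """All pairwise population contrasts with single-step adjustment.

    Contrast estimates are differences of the population intercepts of an
    additive (no-interaction) model, i.e. the logit difference at any fixed
    daylength. The familywise-adjusted p-value is the probability that the
    maximum absolute component of a zero-mean multivariate normal vector
    with the contrasts' correlation matrix exceeds the observed |z|,
    estimated by Monte-Carlo with a fixed seed.
    """
    if any(t in _INTERACTION_PARENTS for t in fit.spec.fixed_terms):
        raise ValueError("pairwise population contrasts require a model without interactions")
    if "population" not in fit.spec.fixed_terms:
        raise ValueError("model has no population term")
    pops = fit.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    idx = [fit.coef_names.index(f"pop[{p}]") for p in pops]
    pairs = [(pops[i], pops[j]) for i in range(len(pops)) for j in range(i + 1, len(pops))]
    C = np.zeros((len(pairs), len(fit.beta)))
    for r, (a, b) in enumerate(pairs):
        C[r, idx[pops.index(a)]] = 1.0
        C[r, idx[pops.index(b)]] = -1.0
    est = C @ fit.beta
    V = C @ fit.vcov @ C.T
    se = np.sqrt(np.diag(V))
    z = est / se
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    corr = V / np.outer(se, se)
    # MC estimate of the max-|Z| distribution under the contrast correlation
    rng = np.random.default_rng(seed)
    corr_j = corr + 1e-10 * np.eye(len(pairs))
    L = np.linalg.cholesky(corr_j)
    draws = rng.standard_normal((mc_draws, len(pairs))) @ L.T
    maxabs = np.max(np.abs(draws), axis=1)
    p_adj = np.array([np.mean(maxabs >= abs(zi)) for zi in z])
    p_adj = np.minimum(1.0, np.maximum(p_adj, p_raw))
    return [
        PairwiseContrast(pairs[r], float(est[r]), float(se[r]), float(z[r]),
                         float(p_raw[r]), float(p_adj[r]))
        for r in range(len(pairs))
    ]


def test_random_effect(
    scored: pd.DataFrame, spec: ModelSpec, n_quad: int = 15
) -> tuple[float, float]:
    """Boundary-corrected LRT for the family random-intercept variance.

    Compares the free-variance fit against the sigma_f = 0 fit; because the
    null value lies on the parameter-space boundary, the chi-square(1)
    p-value is halved. A zero variance estimate gives adjusted p = 0.50
    exactly. Returns ``(variance_estimate, p_adjusted)``.
    """
    if not spec.random_intercept:
        raise ValueError("spec does not include the family random intercept")
    free = fit_glmm(scored, spec, n_quad)
    null = fit_glmm(
        scored,
        ModelSpec(spec.fixed_terms, False, spec.reference_population),
        n_quad,
    )
    if free.sigma_f <= SIGMA_ZERO_TOL:
        return 0.0, 0.5
    lr = max(0.0, 2.0 * (free.loglik - null.loglik))
    p_adj = 0.5 * float(stats.chi2.sf(lr, 1))
    return free.sigma_f**2, p_adj
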