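"""Random-effects meta-regression of critical daylength on latitude.

Each critical-daylength estimate carries a known sampling variance (its
bootstrap variance). The latitudinal cline is modelled as

    theta_i = alpha + gamma * x_i + delta_i + eps_i,
    eps_i ~ N(0, v_i),   delta_i ~ N(0, tau^2),

with the between-estimate heterogeneity tau^2 estimated by REML and the
coefficients by weighted least squares with weights 1/(v_i + tau^2) — the
classic mixed-effects meta-regression. The pseudo-R² compares the residual
heterogeneity of the moderated model against the intercept-only model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class ClineModel:
    """Meta-regression fit: CDL (hours) against latitude (°N)."""

    intercept: float
    slope: float
    se_slope: float
    z: float
    p: float
    tau2: float
    tau2_null: float
    r2: float | None
    k: int
    cov_beta: np.ndarray
    x_weighted_mean: float


def _wls(X: np.ndarray, y: np.ndarray, s: np.ndarray):
    """Weighted LS with weights 1/s; uniform weights when all s vanish."""
    if np.max(s) < 1e-12:
        w = np.ones_like(s)
    else:
        w = 1.0 / np.maximum(s, 1e-300)
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    beta = cov @ (XtW @ y)
    return beta, cov, w


def _reml_nll(tau2: float, X: np.ndarray, y: np.ndarray, v: np.ndarray) -> float:
    s = v + tau2
    if np.min(s) <= 0:
        return np.inf
    beta, _, _ = _wls(X, y, s)
    r = y - X @ beta
    _, logdet = np.linalg.slogdet((X.T * (1.0 / s)) @ X)
    return 0.5 * (np.sum(np.log(s)) + logdet + np.sum(r * r / s))


def _estimate_tau2(X: np.ndarray, y: np.ndarray, v: np.ndarray) -> float:
    """REML heterogeneity variance, profiled to high precision, floored at 0."""
    beta0, _, _ = _wls(X, y, np.maximum(v, 0.0) + max(np.mean(v), 1e-8))
    resid = y - X @ beta0
    if np.max(np.abs(resid)) < 1e-10 or np.allclose(resid, 0, atol=1e-10):
        return 0.0
    scale = float(np.var(y)) + float(np.max(v)) + 1e-8
    upper = 10.0 * scale
    res = optimize.minimize_scalar(
        _reml_nll, args=(X, y, v), bounds=(1e-12, upper), method="bounded",
        options={"xatol": 1e-10},
    )
    tau2 = float(res.x)
    # compare against the boundary when the variances allow evaluating it
    if np.min(v) > 0 and _reml_nll(0.0, X, y, v) <= res.fun:
        tau2 = 0.0
    if tau2 < 1e-8:
        tau2 = 0.0
    return tau2


def fit_meta_regression(
    theta: np.ndarray, v: np.ndarray, x: np.ndarray, method: str = "REML"
) -> ClineModel:
    """Fit the mixed-effects meta-regression of ``theta`` on ``x``.

    ``v`` holds the known sampling variances (>= 0). ``method`` is fixed to
    REML. Raises on fewer than three estimates or a constant moderator.
    """
    if method != "REML":
        raise ValueError("only REML is implemented")
    theta = np.asarray(theta, float)
    v = np.asarray(v, float)
    x = np.asarray(x, float)
    k = len(theta)
    if k < 3:
        raise ValueError("need at least three estimates for a slope with an SE")
    if np.any(v < 0):
        raise ValueError("sampling variances must be >= 0")
    if np.ptp(x) == 0:
        raise ValueError("latitude moderator is constant; slope is unidentified")

    X = np.column_stack([np.ones(k), x])
    tau2 = _estimate_tau2(X, theta, v)
    beta, cov, w = _wls(X, theta, v + tau2)
    se_slope = float(np.sqrt(cov[1, 1]))
    z = float(beta[1] / se_slope)
    p = 2.0 * float(stats.norm.sf(abs(z)))

    X0 = np.ones((k, 1))
    tau2_null = _estimate_tau2(X0, theta, v)
    r2 = None if tau2_null <= 0 else max(0.0, (tau2_null - tau2) / tau2_null)
    return ClineModel(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        se_slope=se_slope,
        z=z,
        p=p,
        tau2=tau2,
        tau2_null=tau2_null,
        r2=r2,
        k=k,
        cov_beta=cov,
        x_weighted_mean=float(np.sum(w * x) / np.sum(w)),
    )


def reference_differences(
    estimates: pd.DataFrame, reference_population: str
) -> pd.DataFrame:
    """Express each CDL as a difference from a reference population.

    ``estimates`` needs columns ``population, experiment, cdl_h, boot_var``
    (plus any carried metadata, e.g. latitude). Within each experiment batch
    the reference CDL is subtracted and — treating estimates as independent
    — its bootstrap variance added; the reference rows are removed.
    """
    out_parts = []
    for exp, sub in estimates.groupby("experiment"):
        ref_rows = sub[sub["population"] == reference_population]
        if len(ref_rows) == 0:
            raise ValueError(
                f"reference population {reference_population!r} missing from "
                f"experiment batch {exp!r}"
            )
        ref = ref_rows.iloc[0]
        rest = sub[sub["population"] != reference_population].copy()
        rest["cdl_h"] = rest["cdl_h"] - ref["cdl_h"]
        rest["boot_var"] = rest["boot_var"] + ref["boot_var"]
        out_parts.append(rest)
    return pd.concat(out_parts, ignore_index=True)


def predict_with_band(model: ClineModel, x_grid: np.ndarray) -> pd.DataFrame:
    """Fitted line and pointwise 95% confidence band over ``x_grid``."""
    x_grid = np.asarray(x_grid, float)
    Xg = np.column_stack([np.ones(len(x_grid)), x_grid])
    fit = Xg @ np.array([model.intercept, model.slope])
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xg, model.cov_beta, Xg))
    return pd.DataFrame(
        {
            "x": x_grid,
            "fit": fit,
            "lower": fit - 1.96 * se,
            "upper": fit + 1.96 * se,
        }
    )
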