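"""Critical-daylength estimation with bootstrap confidence intervals.

The critical daylength (CDL) of a population is the photoperiod at which
half of its caterpillars enter diapause. On the logit scale the reaction
norm is ``b0_p + b1 * D``, so the CDL is the inverse prediction
``b0_p / (-b1)`` — the population intercept divided by the additive inverse
of the shared daylength slope. CDLs are estimated from per-temperature
models containing only daylength and population.

Uncertainty comes from a nonparametric bootstrap: individuals are resampled
with replacement within each population × daylength cell (preserving the
experimental design), each resample is refit as a fixed-effects logistic
model (the family variance was estimated at ~0, so the random term is
dropped for speed and stability), and percentile intervals are read off the
replicate CDLs. A family-level resampling scheme is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reaction_norm import GlmmFit, ModelSpec, fit_glmm, fit_logistic_irls


@dataclass(frozen=True)
class CdlEstimate:
    """A population × temperature critical daylength with bootstrap spread."""

    population: str
    temperature_label: str
    cdl: float
    ci_low: float
    ci_high: float
    boot_var: float
    B: int
    seed: int
    n_failed: int = 0


def estimate_cdl(fit: GlmmFit, population: str) -> float:
    """CDL in hours from a fitted additive model: intercept / (-slope)."""
    if fit.separation_flag:
        raise ValueError("refusing CDL from a fit with complete separation")
    if not fit.converged:
        raise ValueError("refusing CDL from an unconverged fit")
    slope = fit.coef("daylength")
    if slope >= 0:
        raise ValueError("non-decreasing reaction norm: daylength slope must be negative")
    return fit.intercept_of(population) / (-slope)


def _refit_cdls_cells(
    X_agg: np.ndarray,
    k: np.ndarray,
    n: np.ndarray,
    cell_pop: np.ndarray,
    n_pops: int,
) -> np.ndarray | None:
    """Fixed-effects logistic refit on aggregated cells; None on failure.

    ``X_agg`` has one row per population × daylength cell (population
    indicators followed by the daylength column); ``k``/``n`` are the
    resampled successes/trials per cell.
    """
    # separation: every population needs both outcomes somewhere
    for p in range(n_pops):
        sel = (cell_pop == p) & (n > 0)
        if not sel.any() or k[sel].sum() == 0 or k[sel].sum() == n[sel].sum():
            return None
    beta, _, _, converged = fit_logistic_irls(X_agg, k, n)
    slope = beta[-1]
    if not converged or slope >= 0 or np.any(np.abs(beta) > 1e4) or abs(slope) > 50:
        return None
    return beta[:n_pops] / (-slope)


def bootstrap_cdl_table(
    scored: pd.DataFrame,
    spec: ModelSpec | None = None,
    B: int = 1000,
    seed: int = 0,
    scheme: str = "individuals",
    max_failed_fraction: float = 0.10,
) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Bootstrap CDLs for every population of one temperature treatment.

    Returns ``(point_estimates, replicate_matrix, n_failed)`` where the
    replicate matrix has one column per population (in sorted order) and
    one row per successful resample.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for percentile intervals")
    if scheme not in ("individuals", "families"):
        raise ValueError("scheme must be 'individuals' or 'families'")
    if scored["temperature"].nunique() != 1:
        raise ValueError("bootstrap operates on a single temperature treatment")
    spec = spec or ModelSpec(frozenset({"daylength", "population"}))
    scored = scored.reset_index(drop=True)

    pops = sorted(scored["population"].unique())
    point_fit = fit_glmm(scored, spec)
    point = {p: estimate_cdl(point_fit, p) for p in pops}

    rng = np.random.default_rng(seed)
    # cell structure (population × daylength) is fixed across resamples
    pop_code = pd.Categorical(scored["population"], categories=pops).codes.astype(int)
    day = scored["daylength_h"].to_numpy(float)
    days = np.unique(day)
    day_code = np.searchsorted(days, day)
    cell_code = pop_code * len(days) + day_code
    m = len(pops) * len(days)
    cell_pop = np.arange(m) // len(days)
    cell_day = days[np.arange(m) % len(days)]
    X_agg = np.column_stack(
        [(cell_pop == p).astype(float) for p in range(len(pops))] + [cell_day]
    )
    y = scored["diapause"].to_numpy(float)

    if scheme == "individuals":
        cells = [np.flatnonzero(cell_code == c) for c in range(m)]
        cells = [c for c in cells if len(c)]
    else:
        fam_ids = scored["family_id"].to_numpy()
        fam_groups = []
        for p in range(len(pops)):
            rows = np.flatnonzero(pop_code == p)
            fam_groups.append(
                [rows[fam_ids[rows] == f] for f in np.unique(fam_ids[rows])]
            )

    reps = np.full((B, len(pops)), np.nan)
    n_failed = 0
    for b in range(B):
        if scheme == "individuals":
            take = np.concatenate(
                [cell[rng.integers(0, len(cell), size=len(cell))] for cell in cells]
            )
        else:
            parts = []
            for fams in fam_groups:
                pick = rng.integers(0, len(fams), size=len(fams))
                parts.extend(fams[i] for i in pick)
            take = np.concatenate(parts)
        codes = cell_code[take]
        k = np.bincount(codes, weights=y[take], minlength=m)
        n = np.bincount(codes, minlength=m).astype(float)
        cdls = _refit_cdls_cells(X_agg, k, n, cell_pop, len(pops))
        if cdls is None:
            n_failed += 1
            continue
        reps[b] = cdls

    if n_failed > max_failed_fraction * B:
        raise RuntimeError(
            f"{n_failed} of {B} bootstrap replicates failed (separation or "
            "non-convergence); data too sparse for percentile intervals"
        )
    reps = reps[~np.isnan(reps).any(axis=1)]
    point_df = pd.DataFrame(
        {"population": pops, "cdl_h": [point[p] for p in pops]}
    )
    return point_df, reps, n_failed


def bootstrap_cdl(
    scored: pd.DataFrame,
    spec: ModelSpec | None = None,
    population: str | None = None,
    B: int = 1000,
    seed: int = 0,
    scheme: str = "individuals",
) -> CdlEstimate:
    """Percentile-bootstrap CDL estimate for one population.

    ``scored`` must hold one temperature treatment; the refit includes all
    populations present (they share the slope), but the returned estimate
    is for ``population`` (default: the only population present).
    """
    pops = sorted(scored["population"].unique())
    if population is None:
        if len(pops) != 1:
            raise ValueError("population must be named when several are present")
        population = pops[0]
    if population not in pops:
        raise ValueError(f"population {population!r} not in the data")
    point_df, reps, n_failed = bootstrap_cdl_table(scored, spec, B, seed, scheme)
    col = pops.index(population)
    vals = reps[:, col]
    lo, hi = np.percentile(vals, [2.5, 97.5])
    label = scored["temperature"].iloc[0]
    return CdlEstimate(
        population=population,
        temperature_label=label,
        cdl=float(point_df.loc[point_df["population"] == population, "cdl_h"].iloc[0]),
        ci_low=float(lo),
        ci_high=float(hi),
        boot_var=float(np.var(vals, ddof=1)),
        B=B,
        seed=seed,
        n_failed=n_failed,
    )


def cdl_table(
    scored_by_temperature: pd.DataFrame,
    truth_latitudes: dict[str, float] | None = None,
    B: int = 1000,
    seed: int = 0,
    scheme: str = "individuals",
) -> pd.DataFrame:
    """CDL table over all temperature treatments present in a scored table.

    One row per population × temperature with point estimate, percentile CI,
    bootstrap variance and bookkeeping columns — the hand-off format for the
    latitude meta-regression.
    """
    rows = []
    for t_i, (label, sub) in enumerate(sorted(scored_by_temperature.groupby("temperature"))):
        sub = sub.reset_index(drop=True)
        pops = sorted(sub["population"].unique())
        sub_seed = seed + 1000 * t_i
        point_df, reps, n_failed = bootstrap_cdl_table(sub, B=B, seed=sub_seed, scheme=scheme)
        for col, pop in enumerate(pops):
            vals = reps[:, col]
            lo, hi = np.percentile(vals, [2.5, 97.5])
            rows.append(
                {
                    "population": pop,
                    "latitude": (truth_latitudes or {}).get(pop, np.nan),
                    "temperature": label,
                    "cdl_h": float(point_df.loc[point_df["population"] == pop, "cdl_h"].iloc[0]),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "boot_var": float(np.var(vals, ddof=1)),
                    "B": B,
                    "seed": sub_seed,
                    "n_failed": n_failed,
                }
            )
    return pd.DataFrame(rows)
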