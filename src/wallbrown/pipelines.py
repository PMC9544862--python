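"""Config-driven end-to-end pipelines.

Two drivers mirror the two halves of the study: ``run_experiment_pipeline``
takes a rearing table (real or simulated) through scoring, mixed-model
fitting, term tests, pairwise contrasts, bootstrap critical daylengths and
the latitudinal meta-regression; ``run_range_pipeline`` takes an occurrence
table through gridding, the recording-effort filter, margin selection and
the period-shift tests. Every output CSV carries the configuration hash and
the seed in a leading comment line, so a rerun with the same config is
verifiably the same analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cdl as cdl_mod
from . import cline as cline_mod
from . import range_grid as rg
from . import reaction_norm as rn
from . import scoring, synthetic

log = logging.getLogger("wallbrown")

EXPERIMENT_DEFAULTS: dict = {
    "experiment": "eastern",          # eastern | western (synthetic truth)
    "rearing_csv": None,              # path; overrides the simulator
    "seed": 1,
    "threshold_set": "default",       # default | early | late
    "bootstrap_B": 500,
    "bootstrap_scheme": "individuals",
    "meta_method": "REML",
    "n_quad": 15,
    "latitudes": None,                # {population: latitude}; needed with rearing_csv
}

RANGE_DEFAULTS: dict = {
    "occurrence_csv": None,
    "coastline_csv": None,
    "seed": 1,
    "cell": 20_000.0,
    "origin_x": 0.0,
    "origin_y": 0.0,
    "central_meridian": 15.0,
    "well_recorded_threshold": 100,
    "split_lon": 14.31,
    "k": 10,
    "target_species": "Lasiommata megera",
    "periods": [["1901-2000", 1901, 2000], ["2001-2010", 2001, 2010], ["2011-2020", 2011, 2020]],
}


def load_config(path_or_dict, defaults: dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    unknown = set(user) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**defaults, **user}
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, cfg_hash: str, seed) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# config_hash={cfg_hash} seed={seed}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - reraise with stage context
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


# ---------------------------------------------------------------------------
# experiment pipeline


def run_experiment_pipeline(config, out_dir) -> Path:
    """Scored table → fit report → term tests → contrasts → CDLs → cline.

    Writes six CSVs into ``out_dir`` and returns the directory.
    """
    cfg = load_config(config, EXPERIMENT_DEFAULTS)
    h = config_hash(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    truth = None
    if cfg["rearing_csv"]:
        records = scoring.read_rearing_table(cfg["rearing_csv"])
        latitudes = cfg["latitudes"] or {}
    else:
        truth = (
            synthetic.eastern_cline_truth()
            if cfg["experiment"] == "eastern"
            else synthetic.western_cline_truth()
        )
        records = synthetic.simulate_experiment(truth, seed=seed)
        latitudes = {p: truth.latitude_of(p) for p in truth.population_names}
    log.info("records: %d individuals", len(records))

    survivors, mortality = _stage("exclude_dead")(scoring.exclude_dead)(records)
    thresholds = scoring.THRESHOLD_SETS[cfg["threshold_set"]]
    scored = _stage("score_diapause")(scoring.score_diapause)(survivors, thresholds)
    log.info("mortality %.3f; %d survivors scored", mortality, len(scored))
    _write(scored, out / "scored.csv", h, seed)

    two_temps = scored["temperature"].nunique() > 1
    full_terms = {"daylength", "population", "daylength:population"}
    if two_temps:
        full_terms |= {"temperature", "temperature:population"}
    full_spec = rn.ModelSpec(frozenset(full_terms))
    additive_terms = {"daylength", "population"} | ({"temperature"} if two_temps else set())
    additive_spec = rn.ModelSpec(frozenset(additive_terms))

    fit = _stage("fit_glmm")(rn.fit_glmm)(scored, additive_spec, int(cfg["n_quad"]))
    report = fit.summary_frame()
    report.loc[len(report)] = ["sigma_f", fit.sigma_f, np.nan]
    report.loc[len(report)] = ["loglik", fit.loglik, np.nan]
    report.loc[len(report)] = ["converged", float(fit.converged), np.nan]
    report.loc[len(report)] = ["mortality_fraction", mortality, np.nan]
    _write(report, out / "fit_report.csv", h, seed)

    tests = _stage("lrt_type2")(rn.lrt_type2)(scored, full_spec, int(cfg["n_quad"]))
    var_f, p_boundary = _stage("test_random_effect")(rn.test_random_effect)(
        scored, additive_spec, int(cfg["n_quad"])
    )
    tt = pd.DataFrame([t.__dict__ for t in tests])
    tt.loc[len(tt)] = ["family_variance(boundary)", var_f, 1, p_boundary]
    _write(tt, out / "term_tests.csv", h, seed)

    contrasts = _stage("tukey_pairwise")(rn.tukey_pairwise)(fit, seed=seed)
    cdf = pd.DataFrame(
        [
            {
                "population_a": c.pair[0], "population_b": c.pair[1],
                "estimate": c.estimate, "se": c.se, "z": c.z,
                "p_raw": c.p_raw, "p_adjusted": c.p_adjusted,
            }
            for c in contrasts
        ]
    )
    _write(cdf, out / "pairwise_contrasts.csv", h, seed)

    cdls = _stage("bootstrap_cdl")(cdl_mod.cdl_table)(
        scored, latitudes, B=int(cfg["bootstrap_B"]), seed=seed,
        scheme=cfg["bootstrap_scheme"],
    )
    _write(cdls, out / "cdl_table.csv", h, seed)

    cold = cdls[cdls["temperature"] == "cold"]
    if len(cold) >= 3 and cold["latitude"].notna().all():
        model = _stage("fit_meta_regression")(cline_mod.fit_meta_regression)(
            cold["cdl_h"].to_numpy(), cold["boot_var"].to_numpy(),
            cold["latitude"].to_numpy(), method=cfg["meta_method"],
        )
        cm = pd.DataFrame(
            [{
                "intercept": model.intercept, "slope_h_per_deg": model.slope,
                "se_slope": model.se_slope, "z": model.z, "p": model.p,
                "tau2": model.tau2, "r2": np.nan if model.r2 is None else model.r2,
                "k": model.k,
            }]
        )
        _write(cm, out / "cline_model.csv", h, seed)
        grid = np.linspace(cold["latitude"].min(), cold["latitude"].max(), 50)
        _write(cline_mod.predict_with_band(model, grid), out / "cline_band.csv", h, seed)
    else:
        log.warning("skipping meta-regression: need >= 3 cold-treatment CDLs with latitudes")

    return out


# ---------------------------------------------------------------------------
# range pipeline


def default_coastline(cfg: dict) -> list[np.ndarray]:
    """Synthetic west/east coastlines flanking the default scenario grid."""
    y = np.linspace(6_150_000.0, 6_950_000.0, 81)
    west = np.column_stack([np.full_like(y, -210_000.0), y])
    east = np.column_stack([np.full_like(y, 210_000.0), y])
    return [west, east]


def run_range_pipeline(config, out_dir) -> Path:
    """Grid summary → margin selections per metric/region → shift tests."""
    cfg = load_config(config, RANGE_DEFAULTS)
    h = config_hash(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    if cfg["occurrence_csv"]:
        occ = synthetic.read_occurrence_table(cfg["occurrence_csv"])
    else:
        scenario = synthetic.default_scenario()
        occ = synthetic.simulate_occurrences(scenario, seed=seed)
    if cfg["coastline_csv"]:
        coastline = rg.read_coastline(cfg["coastline_csv"])
    else:
        coastline = default_coastline(cfg)

    periods = tuple((p[0], int(p[1]), int(p[2])) for p in cfg["periods"])
    grid = _stage("tabulate_squares")(rg.tabulate_squares)(
        occ, target_species=cfg["target_species"], periods=periods,
        origin=(float(cfg["origin_x"]), float(cfg["origin_y"])),
        cell=float(cfg["cell"]), central_meridian=float(cfg["central_meridian"]),
    )
    grid = rg.mark_well_recorded(grid, int(cfg["well_recorded_threshold"]))
    log.info(
        "%d squares, %d well-recorded, %d records outside periods dropped",
        len(grid.table), int(grid.table["well_recorded"].sum()), grid.n_dropped_years,
    )
    _write(grid.table, out / "grid_summary.csv", h, seed)

    analyses = [
        ("latitude", "east"),
        ("latitude", "west"),
        ("ln_inland_distance", "all"),
    ]
    sel_rows, test_rows, tukey_rows = [], [], []
    for metric, region in analyses:
        selections = _stage("margin_squares")(rg.margin_selections_by_period)(
            grid, metric=metric, k=int(cfg["k"]), region=region,
            split_lon=float(cfg["split_lon"]), coastline=coastline,
        )
        for s in selections:
            sub = s.squares.assign(metric=metric, region=region, period=s.period)
            sel_rows.append(sub[["metric", "region", "period", "ix", "iy",
                                 "centroid_lon", "centroid_lat", "value"]])
        test = _stage("period_shift_test")(rg.period_shift_test)(selections)
        test_rows.append({
            "metric": metric, "region": region, "F": test.F,
            "df1": test.df[0], "df2": test.df[1], "p": test.p,
        })
        tukey_rows.append(test.tukey.assign(metric=metric, region=region))

    _write(pd.concat(sel_rows, ignore_index=True), out / "margin_selection.csv", h, seed)
    _write(pd.DataFrame(test_rows), out / "shift_tests.csv", h, seed)
    _write(pd.concat(tukey_rows, ignore_index=True), out / "shift_tukey.csv", h, seed)
    return out
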