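"""Synthetic rearing experiments and occurrence scenarios with known truth.

The generator mirrors the structure of the common-garden diapause-induction
experiments: split-brood families divided over daylength × temperature
treatments, a logistic (logit-linear) reaction norm of diapause probability
on daylength with population-specific critical daylengths, a shared negative
daylength slope, a warm-treatment logit offset, a family-level random
intercept, and independent mortality censoring. Occurrence scenarios emulate
citizen-science recording: Poisson background records of many butterfly
species with spatially and temporally heterogeneous effort, and a target
species whose northern front advances between time periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .scoring import REARING_COLUMNS, ScoringThresholds

#: Canonical column order of an occurrence table (projected metres).
OCCURRENCE_COLUMNS = ["species", "x_m", "y_m", "year"]


@dataclass(frozen=True)
class ExperimentTruth:
    """Ground truth of a simulated diapause-induction experiment.

    ``populations`` holds ``(name, latitude °N, critical daylength h)``
    triples; the critical daylength (CDL) is defined at the cool reference
    temperature and offset 0, i.e. the population intercept on the logit
    scale is ``-slope_per_hour * cdl``.
    """

    populations: tuple[tuple[str, float, float], ...]
    slope_per_hour: float = -2.0
    temp_effect: float = -1.0
    family_sd: float = 0.0
    families_per_population: int = 10
    offspring_per_family_per_treatment: int = 2
    daylengths: tuple[float, ...] = (14.5, 15.5, 16.5, 17.5)
    temperatures: tuple[float, ...] = (16.0,)
    mortality_rate: float = 0.0
    direct_pupation_mean: dict = field(
        default_factory=lambda: {"cold": 40.0, "warm": 25.0}
    )
    direct_pupation_sd: dict = field(
        default_factory=lambda: {"cold": 5.0, "warm": 3.0}
    )

    def __post_init__(self) -> None:
        if len(self.populations) == 0:
            raise ValueError("at least one population is required")
        if self.slope_per_hour >= 0:
            raise ValueError("slope_per_hour must be negative (long days suppress diapause)")
        if not 0.0 <= self.mortality_rate < 1.0:
            raise ValueError("mortality_rate must be in [0, 1)")
        if self.family_sd < 0:
            raise ValueError("family_sd must be >= 0")
        dl = np.asarray(self.daylengths, float)
        if len(dl) < 1 or np.any(np.diff(dl) <= 0):
            raise ValueError("daylengths must be strictly increasing")
        if not 1 <= len(self.temperatures) <= 2:
            raise ValueError("one (cold) or two (cold, warm) temperatures are supported")

    @property
    def population_names(self) -> list[str]:
        return [p[0] for p in self.populations]

    def latitude_of(self, population: str) -> float:
        return self._lookup(population)[1]

    def cdl_of(self, population: str) -> float:
        return self._lookup(population)[2]

    def intercept_of(self, population: str) -> float:
        """Logit intercept implied by the population's CDL: -slope * CDL."""
        return -self.slope_per_hour * self.cdl_of(population)

    def temperature_label(self, temperature_c: float) -> str:
        """Map a nominal °C to the cold/warm treatment label."""
        temps = sorted(self.temperatures)
        if temperature_c not in temps:
            raise ValueError(f"unknown temperature {temperature_c!r}")
        return "cold" if temperature_c == temps[0] else "warm"

    def _lookup(self, population: str):
        for row in self.populations:
            if row[0] == population:
                return row
        raise KeyError(f"unknown population {population!r}")


def eastern_cline_truth() -> ExperimentTruth:
    """Default eastern-cline conditions: 4 populations, 4 daylengths × 2 temps."""
    return ExperimentTruth(
        populations=(
            ("Hassleholm", 56.16, 15.90),
            ("Vejbystrand", 56.32, 15.85),
            ("Katrineholm", 58.99, 16.40),
            ("Rindo", 59.40, 16.50),
        ),
        slope_per_hour=-2.0,
        temp_effect=-1.0,
        family_sd=0.0,
        families_per_population=10,
        offspring_per_family_per_treatment=2,
        daylengths=(14.5, 15.5, 16.5, 17.5),
        temperatures=(16.0, 22.0),
        mortality_rate=0.053,
    )


def western_cline_truth() -> ExperimentTruth:
    """Default western-cline conditions: 5 populations, 5 daylengths, 16 °C only."""
    return ExperimentTruth(
        populations=(
            ("Hassleholm", 56.16, 16.10),
            ("Vejbystrand", 56.32, 16.00),
            ("Kungalv", 57.87, 16.45),
            ("Luro", 58.80, 16.35),
            ("Stromstad", 58.94, 16.70),
        ),
        slope_per_hour=-2.0,
        temp_effect=-1.0,
        family_sd=0.0,
        families_per_population=10,
        offspring_per_family_per_treatment=2,
        daylengths=(14.5, 15.5, 16.0, 16.5, 17.5),
        temperatures=(16.0,),
        mortality_rate=0.118,
    )


def truth_probability(
    truth: ExperimentTruth,
    population: str,
    daylength: float,
    temperature_label: str = "cold",
    family_offset: float = 0.0,
) -> float:
    """True diapause probability under the generating logistic model.

    ``logistic(b0_p + b1*D + bT*1[warm] + family_offset)``; by construction
    equals 0.5 at ``D = CDL_p`` in the cold treatment at offset 0.
    """
    if temperature_label not in ("cold", "warm"):
        raise ValueError(f"unknown temperature label {temperature_label!r}")
    eta = (
        truth.intercept_of(population)
        + truth.slope_per_hour * daylength
        + (truth.temp_effect if temperature_label == "warm" else 0.0)
        + family_offset
    )
    return float(expit(eta))


def simulate_experiment(
    truth: ExperimentTruth,
    seed: int,
    thresholds: ScoringThresholds | None = None,
) -> pd.DataFrame:
    """Simulate one rearing experiment as a table of individual records.

    Each family draws a single Normal(0, family_sd²) logit offset shared by
    all its offspring regardless of treatment (split-brood design). Each
    individual's diapause outcome is Bernoulli with the true probability;
    non-diapausers get a rounded-Normal pupation day truncated strictly
    below the scoring threshold of their temperature; diapausers never
    pupate. Each individual independently dies with ``mortality_rate``;
    dead individuals carry no outcome. Deterministic given ``seed``.
    """
    thresholds = thresholds or ScoringThresholds()
    for temp in truth.temperatures:
        lab = truth.temperature_label(temp)
        if truth.direct_pupation_mean[lab] >= thresholds.for_label(lab):
            raise ValueError(
                f"direct_pupation_mean for {lab!r} "
                f"({truth.direct_pupation_mean[lab]}) is not below the scoring "
                f"threshold ({thresholds.for_label(lab)}); generator would "
                "contradict the scoring rule"
            )

    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    counter = 0
    for name, _lat, _cdl in truth.populations:
        for fam in range(1, truth.families_per_population + 1):
            family_id = f"{name}_F{fam:02d}"
            offset = rng.normal(0.0, truth.family_sd) if truth.family_sd > 0 else 0.0
            for temp in truth.temperatures:
                lab = truth.temperature_label(temp)
                thr = thresholds.for_label(lab)
                mu = truth.direct_pupation_mean[lab]
                sd = truth.direct_pupation_sd[lab]
                for dl in truth.daylengths:
                    p = truth_probability(truth, name, dl, lab, offset)
                    for _ in range(truth.offspring_per_family_per_treatment):
                        counter += 1
                        died = rng.random() < truth.mortality_rate
                        if died:
                            day = pd.NA
                        elif rng.random() < p:
                            day = pd.NA  # diapause: no pupation
                        else:
                            day = _truncated_day(rng, mu, sd, thr)
                        rows.append(
                            (f"ind{counter:05d}", name, family_id, dl, lab, day, died)
                        )
    df = pd.DataFrame(rows, columns=REARING_COLUMNS)
    df["pupation_day"] = df["pupation_day"].astype("Int64")
    df["died"] = df["died"].astype(bool)
    return df


def _truncated_day(rng: np.random.Generator, mu: float, sd: float, threshold: int) -> int:
    """Rounded-Normal pupation day constrained to [1, threshold - 1]."""
    for _ in range(1000):
        day = int(round(rng.normal(mu, sd)))
        if 1 <= day < threshold:
            return day
    raise RuntimeError("could not draw a pupation day below the scoring threshold")


@dataclass(frozen=True)
class OccurrenceScenario:
    """A gridded citizen-science recording scenario with an advancing front.

    ``effort`` is the expected number of background (non-target) records per
    square per period: a scalar, a per-period vector, or a full
    ``(n_periods, ny, nx)`` array. ``front_y`` is the target species'
    northern occupancy limit (metres) per period and must be non-decreasing.
    """

    x_range: tuple[float, float] = (-200_000.0, 200_000.0)
    y_range: tuple[float, float] = (6_200_000.0, 6_900_000.0)
    cell: float = 20_000.0
    periods: tuple[tuple[str, int, int], ...] = (
        ("1901-2000", 1901, 2000),
        ("2001-2010", 2001, 2010),
        ("2011-2020", 2011, 2020),
    )
    background_species: int = 40
    effort: object = 120.0
    front_y: tuple[float, ...] = (6_400_000.0, 6_500_000.0, 6_600_000.0)
    target_density: float = 3.0
    target_species: str = "Lasiommata megera"

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("empty grid: ranges must span at least one cell")
        if len(self.front_y) != len(self.periods):
            raise ValueError("front_y needs one entry per period")
        if np.any(np.diff(self.front_y) < 0):
            raise ValueError("front_y must be non-decreasing across periods")
        years = [(p[1], p[2]) for p in self.periods]
        for (s, e) in years:
            if e < s:
                raise ValueError("period end before start")
        for (_, e0), (s1, _) in zip(years[:-1], years[1:]):
            if s1 <= e0:
                raise ValueError("periods must be ordered and non-overlapping")
        if np.any(self.effort_array() < 0):
            raise ValueError("effort must be >= 0")
        if self.target_density < 0:
            raise ValueError("target_density must be >= 0")

    @property
    def nx(self) -> int:
        return int(np.floor((self.x_range[1] - self.x_range[0]) / self.cell))

    @property
    def ny(self) -> int:
        return int(np.floor((self.y_range[1] - self.y_range[0]) / self.cell))

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centre coordinates: arrays of shape (nx,) and (ny,)."""
        cx = self.x_range[0] + (np.arange(self.nx) + 0.5) * self.cell
        cy = self.y_range[0] + (np.arange(self.ny) + 0.5) * self.cell
        return cx, cy

    def effort_array(self) -> np.ndarray:
        """Effort broadcast to shape (n_periods, ny, nx)."""
        shape = (len(self.periods), self.ny, self.nx)
        return np.broadcast_to(np.asarray(self.effort, float), shape)


def heterogeneous_effort(
    scenario_shape: tuple[int, int, int],
    base_median: float = 80.0,
    spatial_sd_log: float = 1.0,
    period_multipliers: tuple[float, ...] = (0.8, 2.5, 4.0),
    seed: int = 0,
) -> np.ndarray:
    """Log-normal spatial effort field with per-period recording multipliers.

    Emulates how citizen-science recording intensity varies between squares
    (popular versus remote places) and grows over time. The construction
    seed is part of the scenario definition, not of the simulation draw.
    """
    n_periods, ny, nx = scenario_shape
    if len(period_multipliers) != n_periods:
        raise ValueError("need one period multiplier per period")
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(np.log(base_median), spatial_sd_log, size=(ny, nx)))
    return np.asarray(period_multipliers, float)[:, None, None] * base[None, :, :]


def default_scenario(effort_seed: int = 0) -> OccurrenceScenario:
    """Advancing-front scenario with heterogeneous effort (front +100 km/period)."""
    proto = OccurrenceScenario()
    effort = heterogeneous_effort(
        (len(proto.periods), proto.ny, proto.nx), seed=effort_seed
    )
    return OccurrenceScenario(effort=effort)


def simulate_occurrences(scenario: OccurrenceScenario, seed: int) -> pd.DataFrame:
    """Draw one occurrence table (species, x_m, y_m, year) from a scenario.

    Background records are Poisson(effort) per square/period with species
    uniform over the background pool; target records are Poisson(density)
    only in squares whose centroid lies at or below the period's front.
    Coordinates are uniform within squares; years uniform within periods.
    """
    rng = np.random.default_rng(seed)
    effort = scenario.effort_array()
    cx, cy = scenario.centroids()
    half = scenario.cell / 2.0
    species_pool = np.array(
        [f"sp{i:03d}" for i in range(1, scenario.background_species + 1)]
    )
    parts: list[pd.DataFrame] = []
    for p, (label, y0, y1) in enumerate(scenario.periods):
        n_bg = rng.poisson(effort[p])  # (ny, nx)
        occupied = cy[:, None] <= scenario.front_y[p]
        n_tg = rng.poisson(
            np.where(occupied, scenario.target_density, 0.0), size=(scenario.ny, scenario.nx)
        )
        for counts, is_target in ((n_bg, False), (n_tg, True)):
            total = int(counts.sum())
            if total == 0:
                continue
            iy, ix = np.nonzero(counts)
            reps = counts[iy, ix]
            iy = np.repeat(iy, reps)
            ix = np.repeat(ix, reps)
            xs = cx[ix] + rng.uniform(-half, half, size=total)
            ys = cy[iy] + rng.uniform(-half, half, size=total)
            years = rng.integers(y0, y1 + 1, size=total)
            if is_target:
                sp = np.full(total, scenario.target_species)
            elif scenario.background_species == 0:
                continue
            else:
                sp = species_pool[rng.integers(0, len(species_pool), size=total)]
            parts.append(
                pd.DataFrame({"species": sp, "x_m": xs, "y_m": ys, "year": years})
            )
    if not parts:
        return pd.DataFrame(columns=OCCURRENCE_COLUMNS).astype(
            {"x_m": float, "y_m": float, "year": int}
        )
    out = pd.concat(parts, ignore_index=True)
    return out[OCCURRENCE_COLUMNS]


def write_occurrence_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, columns=OCCURRENCE_COLUMNS)


def read_occurrence_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence table is missing column(s): {', '.join(missing)}")
    return df[OCCURRENCE_COLUMNS]
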