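"""Diapause scoring from pupation-day thresholds.

A reared caterpillar either pupates (direct development) or sits out the
season as a larva (diapause). The binary outcome is read off the pupation
day: an individual that has not pupated before the threshold day of its
temperature treatment is scored as diapausing. The default thresholds are
day 55 in the cool (16 °C) treatments and day 33 in the warm (22 °C)
treatments; ``early`` and ``late`` alternative sets probe the sensitivity of
downstream results to the choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical column order of a rearing table.
REARING_COLUMNS = [
    "individual_id",
    "population",
    "family_id",
    "daylength_h",
    "temperature",
    "pupation_day",
    "died",
]

#: Recognised temperature treatment labels.
TEMPERATURE_LABELS = ("cold", "warm")


@dataclass(frozen=True)
class ScoringThresholds:
    """Pupation-day thresholds separating direct development from diapause.

    An individual counts as a direct developer iff its pupation day is
    *strictly before* the threshold for its temperature treatment; pupation
    on the threshold day or later, or no pupation at all, means diapause.
    """

    threshold_cold: int = 55
    threshold_warm: int = 33

    def __post_init__(self) -> None:
        if self.threshold_cold < 2 or self.threshold_warm < 2:
            raise ValueError("scoring thresholds must be >= 2 days")

    def for_label(self, temperature_label: str) -> int:
        if temperature_label == "cold":
            return self.threshold_cold
        if temperature_label == "warm":
            return self.threshold_warm
        raise ValueError(
            f"unknown temperature label {temperature_label!r}; "
            f"expected one of {TEMPERATURE_LABELS}"
        )


#: Named threshold sets: the default plus the two sensitivity alternatives.
THRESHOLD_SETS = {
    "default": ScoringThresholds(55, 33),
    "early": ScoringThresholds(49, 29),
    "late": ScoringThresholds(61, 37),
}


def read_rearing_table(path) -> pd.DataFrame:
    """Read a rearing-experiment CSV into a typed table.

    Required columns are those of :data:`REARING_COLUMNS`. ``pupation_day``
    may be blank (diapausing or dead individuals); it is carried as a
    nullable integer. Lines starting with ``#`` are treated as comments.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REARING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rearing table is missing column(s): {', '.join(missing)}")
    daylength = pd.to_numeric(df["daylength_h"], errors="coerce")
    bad = daylength.isna() & df["daylength_h"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"non-numeric daylength_h {df['daylength_h'].iloc[row]!r} at data row {row}"
        )
    out = df.copy()
    out["daylength_h"] = daylength.astype(float)
    out["pupation_day"] = pd.to_numeric(out["pupation_day"], errors="coerce").astype("Int64")
    out["died"] = out["died"].astype(bool)
    if (out["pupation_day"].dropna() < 1).any():
        raise ValueError("pupation_day must be >= 1")
    if (out["died"] & out["pupation_day"].notna()).any():
        raise ValueError("a record cannot both have a pupation day and be dead")
    return out[REARING_COLUMNS]


def write_rearing_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a rearing table with the canonical columns and stable formatting."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, columns=REARING_COLUMNS)


def exclude_dead(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Drop individuals that died during rearing.

    Returns the surviving records and the mortality fraction (dead/total).
    An empty input is an error: mortality is undefined with no individuals.
    """
    if len(records) == 0:
        raise ValueError("cannot compute mortality of an empty rearing table")
    dead = records["died"].astype(bool)
    survivors = records.loc[~dead].reset_index(drop=True)
    return survivors, float(dead.sum()) / float(len(records))


def score_diapause(
    survivors: pd.DataFrame, thresholds: ScoringThresholds | str = "default"
) -> pd.DataFrame:
    """Classify each survivor as diapausing (1) or directly developing (0).

    Diapause iff the pupation day is absent or on/after the threshold for
    the record's temperature treatment. Input must contain survivors only.
    """
    if isinstance(thresholds, str):
        thresholds = THRESHOLD_SETS[thresholds]
    if survivors["died"].astype(bool).any():
        raise ValueError("score_diapause expects survivors only; call exclude_dead first")
    thr = survivors["temperature"].map(
        lambda lab: thresholds.for_label(lab)
    )
    day = survivors["pupation_day"]
    diapause = day.isna() | (day >= thr)
    scored = survivors.copy()
    scored["diapause"] = diapause.astype(int)
    return scored


def summarize_proportions(scored: pd.DataFrame) -> pd.DataFrame:
    """Per population × temperature × daylength diapause proportions.

    The groups partition the scored records, so the ``n`` column sums to the
    input size.
    """
    if len(scored) == 0:
        raise ValueError("no scored records to summarise")
    grouped = (
        scored.groupby(["population", "temperature", "daylength_h"], sort=True)["diapause"]
        .agg(n="size", n_diapause="sum")
        .reset_index()
    )
    grouped["proportion"] = grouped["n_diapause"] / grouped["n"]
    return grouped
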