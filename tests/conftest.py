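import numpy as np
import pandas as pd
import pytest

from wallbrown import scoring, synthetic
from wallbrown.reaction_norm import ModelSpec


def simulate_scored(truth, seed, thresholds=None):
    """Simulate → exclude dead → score, the standard preprocessing chain."""
    records = synthetic.simulate_experiment(truth, seed=seed, thresholds=thresholds)
    survivors, _ = scoring.exclude_dead(records)
    return scoring.score_diapause(survivors, thresholds or scoring.ScoringThresholds())


@pytest.fixture(scope="session")
def eastern_scored():
    return simulate_scored(synthetic.eastern_cline_truth(), seed=7)


@pytest.fixture(scope="session")
def western_scored():
    return simulate_scored(synthetic.western_cline_truth(), seed=7)


@pytest.fixture(scope="session")
def single_pop_truth():
    """One population, CDL 16.0 h, slope -2/h, 15 individuals per cell."""
    return synthetic.ExperimentTruth(
        populations=(("P", 57.0, 16.0),),
        slope_per_hour=-2.0,
        family_sd=0.0,
        families_per_population=5,
        offspring_per_family_per_treatment=3,
        daylengths=(14.5, 15.5, 16.0, 16.5, 17.5),
        mortality_rate=0.0,
    )


@pytest.fixture
def additive_spec():
    return ModelSpec(frozenset({"daylength", "population"}))


def scored_frame(rows):
    """Build a small scored table from (pop, family, daylength, temp, diapause) rows."""
    df = pd.DataFrame(rows, columns=["population", "family_id", "daylength_h",
                                     "temperature", "diapause"])
    df.insert(0, "individual_id", [f"i{n}" for n in range(len(df))])
    df["pupation_day"] = pd.array(
        [pd.NA if d else 20 for d in df["diapause"]], dtype="Int64"
    )
    df["died"] = False
    return df
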