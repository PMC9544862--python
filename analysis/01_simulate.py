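"""Generate the synthetic study inputs.

Writes the two rearing experiments (eastern cline: 4 populations, 4
daylengths x 2 temperatures; western cline: 5 populations, 5 daylengths at
16 C) and the citizen-science occurrence table (advancing front, effort
growing over time) to scratch/data/. Everything downstream reads these
files, so the whole analysis is reproducible from this one script.
"""

from pathlib import Path

from wallbrown import scoring, synthetic

SEED = 2026
DATA = Path(__file__).resolve().parent.parent / "scratch" / "data"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)

    east = synthetic.simulate_experiment(synthetic.eastern_cline_truth(), seed=SEED)
    scoring.write_rearing_table(east, DATA / "rearing_east.csv",
                                header_comment=f"eastern cline, seed={SEED}")
    west = synthetic.simulate_experiment(synthetic.western_cline_truth(), seed=SEED + 1)
    scoring.write_rearing_table(west, DATA / "rearing_west.csv",
                                header_comment=f"western cline, seed={SEED + 1}")
    print(f"eastern cline: {len(east)} individuals, "
          f"{east['family_id'].nunique()} families, "
          f"{east['died'].mean():.1%} mortality")
    print(f"western cline: {len(west)} individuals, "
          f"{west['family_id'].nunique()} families, "
          f"{west['died'].mean():.1%} mortality")

    occ = synthetic.simulate_occurrences(synthetic.default_scenario(), seed=SEED + 2)
    synthetic.write_occurrence_table(occ, DATA / "occurrences.csv",
                                     header_comment=f"seed={SEED + 2}")
    n_target = (occ["species"] == "Lasiommata megera").sum()
    print(f"occurrences: {len(occ)} records over three periods, "
          f"{n_target} of the target species")


if __name__ == "__main__":
    main()
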