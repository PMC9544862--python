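"""Estimate critical daylengths with bootstrap confidence intervals.

For each experiment and temperature treatment, fits the per-temperature
model (daylength + population, family random intercept), reads the critical
daylength of each population off the coefficients (intercept divided by the
additive inverse of the slope), and attaches percentile-bootstrap 95%
intervals (B = 1000 resamples of individuals within population x daylength
cells). Writes results/cdl/cdl_{east,west}.csv.
"""

from pathlib import Path

import pandas as pd

from wallbrown.cdl import cdl_table
from wallbrown.synthetic import eastern_cline_truth, western_cline_truth

SEED = 2026
ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"
OUT = ROOT / "results" / "cdl"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truths = {"east": eastern_cline_truth(), "west": western_cline_truth()}
    for tag, truth in truths.items():
        scored = pd.read_csv(DATA / f"scored_{tag}.csv")
        lats = {p: truth.latitude_of(p) for p in truth.population_names}
        table = cdl_table(scored, lats, B=1000, seed=SEED + 7)
        table.insert(0, "experiment", tag)
        table.to_csv(OUT / f"cdl_{tag}.csv", index=False)
        cold = table[table["temperature"] == "cold"]
        print(f"\n=== {tag} cline, 16 C critical daylengths ===")
        for _, r in cold.sort_values("latitude").iterrows():
            true_cdl = truth.cdl_of(r["population"])
            print(f"  {r['population']:<12s} lat {r['latitude']:5.2f}  "
                  f"CDL {r['cdl_h']:.2f} h [{r['ci_low']:.2f}, {r['ci_high']:.2f}]"
                  f"  (generator truth {true_cdl:.2f})")


if __name__ == "__main__":
    main()
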