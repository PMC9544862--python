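"""Meta-regression of critical daylength on latitude.

Pools the 16 C critical daylengths of both experiments and regresses them
on latitude with a random-effects meta-regression that weights each
estimate by its bootstrap variance. Two variants mirror the two ways of
presenting the cline: absolute critical daylengths, and differences from
the southernmost population within each experiment (which removes the
between-experiment offset). Writes results/cline/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from wallbrown.cline import fit_meta_regression, predict_with_band, reference_differences

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "cline"
REFERENCE = "Hassleholm"  # southernmost population, present in both experiments


def report(name: str, data: pd.DataFrame) -> None:
    m = fit_meta_regression(
        data["cdl_h"].to_numpy(), data["boot_var"].to_numpy(),
        data["latitude"].to_numpy(),
    )
    r2 = "n/a" if m.r2 is None else f"{m.r2:.2f}"
    print(f"{name}: slope {m.slope * 60:.1f} min/degree latitude, "
          f"Z = {m.z:.2f}, p = {m.p:.3g}, tau2 = {m.tau2:.4f}, R2 = {r2}")
    row = pd.DataFrame([{
        "variant": name, "intercept": m.intercept, "slope_h_per_deg": m.slope,
        "se_slope": m.se_slope, "z": m.z, "p": m.p, "tau2": m.tau2,
        "r2": np.nan if m.r2 is None else m.r2, "k": m.k,
    }])
    row.to_csv(OUT / f"model_{name}.csv", index=False)
    grid = np.linspace(data["latitude"].min() - 0.3, data["latitude"].max() + 0.3, 60)
    predict_with_band(m, grid).to_csv(OUT / f"band_{name}.csv", index=False)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cdls = pd.concat(
        [pd.read_csv(ROOT / "results" / "cdl" / f"cdl_{t}.csv") for t in ("east", "west")],
        ignore_index=True,
    )
    cold = cdls[cdls["temperature"] == "cold"].reset_index(drop=True)
    report("absolute", cold)
    diffs = reference_differences(cold, REFERENCE)
    report("difference_from_south", diffs)


if __name__ == "__main__":
    main()
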