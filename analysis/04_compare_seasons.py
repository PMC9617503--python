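#!/usr/bin/env python
"""Compare winter and summer rhythms.

Runs the paired per-participant comparison of MESOR, amplitude and
(circular) acrophase for every parameter with Holm adjustment, renders
the population acrophases as clock times with the seasonal-change column,
and reports the AL-ChT phase relationship in each season.  Writes
results/seasons.csv and results/report_clock.csv.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from oculorhythm import population
from oculorhythm.cosinor import fit_from_row
from oculorhythm.reports import clock_time_table
from oculorhythm.season import compare_seasons, phase_relation

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    fits_path = RESULTS / "fits.csv"
    if not fits_path.exists():
        raise SystemExit("run analysis/02_fit_rhythms.py first")
    fits = pd.read_csv(fits_path)
    ind = fits[fits["scope"] == "individual"]
    comparison = compare_seasons(ind[ind["season"] == "W1"], ind[ind["season"] == "S"])
    comparison.to_csv(RESULTS / "seasons.csv", index=False)

    pop = fits[fits["scope"] == "population"]
    est = {param: {row["season"]: fit_from_row(row) for _, row in grp.iterrows()}
           for param, grp in pop.groupby("parameter")}
    clock = clock_time_table(est, population.HST_ANCHOR_H)
    clock.to_csv(RESULTS / "report_clock.csv", index=False)

    print("acrophases as standard clock time (change in minutes, - = advance):")
    print(clock.round(3).to_string(index=False))
    print("\npaired seasonal changes (Holm-adjusted):")
    acro = comparison[comparison["quantity"] == "acrophase"]
    print(acro.round(4).to_string(index=False))
    for season in ("W1", "S"):
        rel = phase_relation(est["ChT"][season], est["AL"][season])
        print(f"\nAL-ChT acrophase separation in {season}: "
              f"{rel.inphase_distance:.2f} h "
              f"(antiphase distance {rel.antiphase_distance:.2f} h)")


if __name__ == "__main__":
    main()
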