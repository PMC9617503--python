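#!/usr/bin/env python
"""Fit the 24-h sinusoids and test for diurnal variation.

Fits the population (mixed-model) and per-participant cosinors for every
parameter and season of the simulated cohort, runs the subject-blocked
diurnal-variation F-test, and writes results/fits.csv and
results/diurnal.csv.  Prints the population rhythm table (MESOR,
amplitude, acrophase relative to habitual sleep time).
"""

import pathlib
import sys
import warnings

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from oculorhythm.cosinor import diurnal_variation_test
from oculorhythm.io_model import read_cohort
from oculorhythm.pipeline import fit_cohort

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    cohort_dir = RESULTS / "cohort"
    if not cohort_dir.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    cohort = read_cohort(str(cohort_dir))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fits = fit_cohort(cohort, seasons=("W1", "S"))
    fits.to_csv(RESULTS / "fits.csv", index=False)

    rows = []
    for (param, season), _ in fits.groupby(["parameter", "season"]):
        res = diurnal_variation_test(cohort.slice(param, season),
                                     log_scale=(param == "MEL"),
                                     parameter=param, season=season)
        rows.append({"parameter": param, "season": season, "F": round(res.statistic, 2),
                     "df": f"{res.df_num},{res.df_den}",
                     "p": f"{res.p_value:.2g}"})
    diurnal = pd.DataFrame(rows)
    diurnal.to_csv(RESULTS / "diurnal.csv", index=False)

    pop = fits[fits["scope"] == "population"]
    table = pop[["parameter", "season", "mesor", "amplitude", "acrophase", "method"]]
    print("population rhythm estimates (acrophase in h relative to HST):")
    print(table.round(3).to_string(index=False))
    print("\ndiurnal-variation tests (epoch F-test, subject-blocked):")
    print(diurnal.to_string(index=False))
    n_sig = (pd.to_numeric(diurnal["p"]) < 0.05).sum()
    print(f"\n{n_sig}/{len(diurnal)} parameter-season slices show significant "
          "diurnal variation, as in the emulated cohort")


if __name__ == "__main__":
    main()
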