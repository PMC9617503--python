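#!/usr/bin/env python
"""Estimate dim-light melatonin onset (DLMO).

Computes the analytic 3 pg/mL threshold crossing from each fitted
log-melatonin sinusoid (population and per participant, both seasons),
renders onsets as standard clock times, and writes results/dlmo.csv.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from oculorhythm import population
from oculorhythm.cosinor import fit_from_row
from oculorhythm.dlmo import dlmo_relative

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    fits_path = RESULTS / "fits.csv"
    if not fits_path.exists():
        raise SystemExit("run analysis/02_fit_rhythms.py first")
    fits = pd.read_csv(fits_path)
    participants = pd.read_csv(RESULTS / "cohort" / "participants.csv",
                               dtype={"id": str})
    hst = dict(zip(participants["id"], participants["hst_clock"]))

    rows = []
    for _, row in fits[fits["parameter"] == "MEL"].iterrows():
        fit = fit_from_row(row)
        res = dlmo_relative(fit, threshold=population.DLMO_THRESHOLD_PG_ML)
        anchor = (population.HST_ANCHOR_H if fit.scope == "population"
                  else hst[str(fit.participant_id)])
        rows.append({
            "scope": fit.scope, "participant_id": fit.participant_id,
            "season": row["season"], "dlmo_rel_h": res.dlmo_rel,
            "defined": res.defined,
            "dlmo_clock": res.clock(anchor) if res.defined else "",
        })
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "dlmo.csv", index=False)
    pop_rows = table[table["scope"] == "population"]
    print("population melatonin onset:")
    print(pop_rows.round(3).to_string(index=False))
    defined = table[(table["scope"] == "individual") & table["defined"]]
    print(f"\nindividual onsets defined for {len(defined)} of "
          f"{len(table) - len(pop_rows)} participant-season fits; "
          f"mean onset {defined['dlmo_rel_h'].mean():+.2f} h relative to HST")


if __name__ == "__main__":
    main()
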