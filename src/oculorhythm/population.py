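"""Reported population rhythm estimates used as reference inputs.

These are the published nonlinear mixed-effects population estimates for a
young-adult cohort (n = 24 measured in both winter and summer at 60°N):
MESOR, amplitude and acrophase of the fixed-period 24-h sinusoid for each
ocular parameter and for salivary melatonin (melatonin on the natural-log
pg/mL scale).  Acrophases are hours relative to habitual sleep time (HST).

They serve two roles here: as the default "truth" that the synthetic cohort
generator emulates, and as inputs to the worked seasonal-change, clock-time
and melatonin-onset arithmetic that the analysis scripts reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_model import parse_clock


@dataclass(frozen=True)
class RhythmEstimate:
    """Population MESOR / amplitude / acrophase for one parameter-season."""

    mesor: float
    amplitude: float
    acrophase: float  # hours relative to HST, in (-12, 12]


#: parameter -> season -> population estimate.  Units: MEL log(pg/mL);
#: IOP mm Hg; ACD/LT/VCD/AL mm; RT/ChT um.  Seasons: W1 = winter, S = summer.
POPULATION_ESTIMATES: dict[str, dict[str, RhythmEstimate]] = {
    "MEL": {"W1": RhythmEstimate(0.87, 3.155, 3.99), "S": RhythmEstimate(1.04, 2.952, 3.14)},
    "IOP": {"W1": RhythmEstimate(13.36, 2.810, -10.10), "S": RhythmEstimate(13.09, 2.760, -10.27)},
    "ACD": {"W1": RhythmEstimate(3.73, 0.019, 2.44), "S": RhythmEstimate(3.74, 0.026, 1.64)},
    "LT": {"W1": RhythmEstimate(3.55, 0.015, 2.64), "S": RhythmEstimate(3.56, 0.013, 3.18)},
    "VCD": {"W1": RhythmEstimate(16.41, 0.055, -9.00), "S": RhythmEstimate(16.44, 0.063, -9.53)},
    "AL": {"W1": RhythmEstimate(23.92, 0.019, -8.79), "S": RhythmEstimate(23.96, 0.022, -9.81)},
    "RT": {"W1": RhythmEstimate(261.0, 2.0, -9.47), "S": RhythmEstimate(263.0, 2.0, -11.32)},
    "ChT": {"W1": RhythmEstimate(354.0, 2.0, 3.10), "S": RhythmEstimate(343.0, 4.0, 3.42)},
}

#: Salivary melatonin onset threshold in pg/mL.
DLMO_THRESHOLD_PG_ML = 3.0

#: Group HST anchor for rendering HST-relative times as standard clock time.
#: Recovered from the published melatonin row: its acrophase (3.99 h after
#: HST) was printed as 04:07 standard time, so HST itself fell at
#: 04:07 - 3.99 h = 00:07.6.  HST did not differ between seasons.
HST_ANCHOR_H: float = parse_clock("04:07") - POPULATION_ESTIMATES["MEL"]["W1"].acrophase

#: Expected two-year-cohort annual axial-length growth band (mm/12 months):
#: coordinated growth is 0.030 < dAL <= 0.089 mm per year.
ANNUAL_GROWTH_BOUNDS_MM = (0.030, 0.089)

#: Published per-participant axial-length growth table for the ten
#: participants measured in two consecutive winters (W1, W2) and the summer
#: (S) in between.  Columns: baseline AL (mm), interval AL changes (mm),
#: baseline spherical equivalent refraction (D) and its annual change.
GROWTH_TABLE = pd.DataFrame(
    [
        (1, 22.427, -0.011, -0.051, -0.062, -0.48, -0.17),
        (2, 22.968, 0.068, -0.045, 0.023, -0.23, -0.18),
        (3, 25.003, 0.050, -0.023, 0.027, 0.22, -0.14),
        (4, 23.596, 0.021, 0.010, 0.031, -0.91, -0.22),
        (5, 23.746, 0.044, -0.009, 0.035, 1.06, -0.19),
        (6, 24.892, 0.067, -0.015, 0.052, 0.20, -0.05),
        (7, 23.325, 0.049, 0.010, 0.059, 0.67, -0.54),
        (8, 21.938, 0.046, 0.022, 0.068, 0.25, -0.25),
        (9, 24.898, 0.125, 0.020, 0.145, -4.08, -0.04),
        (10, 24.879, 0.110, 0.105, 0.215, -0.92, -0.58),
    ],
    columns=["participant", "al_w1", "dal_w1_s", "dal_s_w2", "dal_w1_w2", "ser_w1", "dser_w1_w2"],
)


def estimates_frame() -> pd.DataFrame:
    """The population estimates as a tidy frame (parameter, season, M, A, acrophase)."""
    rows = [
        (param, season, est.mesor, est.amplitude, est.acrophase)
        for param, by_season in POPULATION_ESTIMATES.items()
        for season, est in by_season.items()
    ]
    return pd.DataFrame(rows, columns=["parameter", "season", "mesor", "amplitude", "acrophase"])
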