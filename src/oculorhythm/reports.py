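"""Report tables: clock-time rendering and seasonal-change summaries.

These helpers turn fitted (or published) population rhythm estimates into
the standard presentation: acrophase per parameter and season as clock
time given an HST anchor, the seasonal acrophase change in minutes
(negative = phase advance), and melatonin-onset clock times.
"""

from __future__ import annotations

import pandas as pd

from .cosinor import CosinorFit
from .dlmo import dlmo_clock, dlmo_relative
from .io_model import parse_clock, to_clock_time
from .population import RhythmEstimate
from .season import circular_diff


def _acro(est) -> float:
    if isinstance(est, (CosinorFit, RhythmEstimate)):
        return est.acrophase
    return float(est)


def seasonal_change_minutes(acro_first, acro_second) -> int:
    """Seasonal acrophase change in whole minutes (second minus first,
    circularly wrapped; negative = advance), rounded to the nearest minute."""
    delta_h = float(circular_diff(_acro(acro_second), _acro(acro_first)))
    return int(round(delta_h * 60.0))


def clock_time_table(estimates: dict[str, dict[str, "RhythmEstimate | CosinorFit"]],
                     hst_anchor: str | float,
                     seasons: tuple[str, str] = ("W1", "S")) -> pd.DataFrame:
    """Acrophases as standard clock time with a seasonal-change column.

    ``estimates`` maps parameter -> season -> estimate (anything with an
    ``acrophase`` attribute, or a bare acrophase in hours).  The anchor is
    the group HST clock time.
    """
    anchor = parse_clock(hst_anchor)
    s0, s1 = seasons
    rows = []
    for param, by_season in estimates.items():
        a0, a1 = _acro(by_season[s0]), _acro(by_season[s1])
        rows.append({
            "parameter": param,
            f"acrophase_{s0}": a0,
            f"acrophase_{s1}": a1,
            f"clock_{s0}": to_clock_time(a0, anchor),
            f"clock_{s1}": to_clock_time(a1, anchor),
            "change_min": seasonal_change_minutes(a0, a1),
        })
    return pd.DataFrame(rows)


def dlmo_table(mel_fits: dict[str, CosinorFit], hst_anchor: str | float,
               threshold: float = 3.0) -> pd.DataFrame:
    """Melatonin onset per season, relative to HST and as clock time."""
    rows = []
    for season, fit in mel_fits.items():
        res = dlmo_relative(fit, threshold=threshold)
        rows.append({
            "season": season,
            "dlmo_rel_h": res.dlmo_rel,
            "defined": res.defined,
            "dlmo_clock": dlmo_clock(res, hst_anchor) if res.defined else "",
        })
    return pd.DataFrame(rows)


def population_table(fits: list[CosinorFit]) -> pd.DataFrame:
    """Population MESOR/amplitude/acrophase per parameter and season, with
    bootstrap CIs where available."""
    rows = []
    for f in fits:
        row = {
            "parameter": f.parameter, "season": f.season,
            "mesor": f.mesor, "amplitude": f.amplitude, "acrophase": f.acrophase,
            "method": f.method,
        }
        for q in ("mesor", "amplitude", "acrophase"):
            lo_hi = f.ci.get(q)
            row[f"{q}_lo"], row[f"{q}_hi"] = lo_hi if lo_hi else (None, None)
        rows.append(row)
    return pd.DataFrame(rows)
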