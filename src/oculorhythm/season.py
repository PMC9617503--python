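"""Cross-season rhythm comparison.

Seasonal contrasts are per-participant paired differences of the individual
cosinor parameters (MESOR, amplitude, acrophase).  Acrophases live on a
24-h circle, so their differences are wrapped into (-12, 12]; by the
convention used throughout, a negative acrophase change is a phase advance
(the rhythm peaks earlier in the second season) and a positive change a
delay.  Observed acrophase spreads are far below the 12-h wrap radius, so
wrapped differences are compared with ordinary paired tests rather than
full circular statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cosinor import CosinorFit, wrap_half_day

QUANTITIES = ("mesor", "amplitude", "acrophase")


def circular_diff(a, b):
    """Signed circular difference a - b in hours, wrapped into (-12, 12]."""
    return wrap_half_day(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


@dataclass
class PhaseRelation:
    """Phase relationship between two rhythms in one season."""

    pair: tuple[str, str]
    acrophase_separation: float  # signed hours in (-12, 12]
    inphase_distance: float  # |separation|, 0 = in phase
    antiphase_distance: float  # 12 - |separation|, 0 = exact antiphase


def phase_relation(fit1: CosinorFit | float, fit2: CosinorFit | float) -> PhaseRelation:
    """Acrophase separation and in-/antiphase distances for two fits."""
    a1 = fit1.acrophase if isinstance(fit1, CosinorFit) else float(fit1)
    a2 = fit2.acrophase if isinstance(fit2, CosinorFit) else float(fit2)
    name1 = fit1.parameter if isinstance(fit1, CosinorFit) else "a"
    name2 = fit2.parameter if isinstance(fit2, CosinorFit) else "b"
    sep = float(circular_diff(a1, a2))
    inphase = abs(sep)
    return PhaseRelation(
        pair=(name1 or "a", name2 or "b"),
        acrophase_separation=sep,
        inphase_distance=inphase,
        antiphase_distance=12.0 - inphase,
    )


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


def _paired_test(diffs: np.ndarray) -> tuple[float, str, bool]:
    """Paired test of mean zero on the per-participant differences.

    Uses a one-sample t-test; falls back to the Wilcoxon signed-rank test
    when Shapiro-Wilk rejects normality (alpha = 0.05).  Degenerate inputs
    (all differences identical, e.g. all zero) return p = 1 with a flag.
    """
    diffs = np.asarray(diffs, dtype=float)
    if np.allclose(diffs, diffs[0]) and abs(diffs[0]) < 1e-12:
        return 1.0, "degenerate", True
    method = "t"
    if len(diffs) >= 3 and np.ptp(diffs) > 0:
        try:
            if stats.shapiro(diffs).pvalue < 0.05:
                method = "wilcoxon"
        except ValueError:
            pass
    if method == "wilcoxon":
        nonzero = diffs[diffs != 0]  # standard signed-rank zero handling
        if len(nonzero) == 0:
            return 1.0, "degenerate", True
        p = float(stats.wilcoxon(nonzero).pvalue)
    else:
        p = float(stats.ttest_1samp(diffs, 0.0).pvalue)
    if np.isnan(p):
        return 1.0, "degenerate", True
    return p, method, False


def compare_seasons(fits_a: pd.DataFrame, fits_b: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter seasonal change from paired individual fits.

    Inputs are individual-fit tables (as written by
    :func:`oculorhythm.cosinor.fits_frame`) for the two seasons.  For every
    parameter present in both, participants are paired on id and the mean
    paired difference of MESOR, amplitude and (circularly wrapped)
    acrophase is tested against zero; p-values are Holm-adjusted across
    parameters within each quantity.

    Returns one row per (parameter, quantity) with the mean delta, raw and
    adjusted p, the test used and the number of pairs.
    """
    rows = []
    params = sorted(set(fits_a["parameter"]) & set(fits_b["parameter"]))
    if not params:
        raise ValueError("no common parameters between the two seasons")
    per_quantity: dict[str, list[dict]] = {q: [] for q in QUANTITIES}
    for param in params:
        a = fits_a[fits_a["parameter"] == param].set_index("participant_id")
        b = fits_b[fits_b["parameter"] == param].set_index("participant_id")
        common = a.index.intersection(b.index)
        if len(common) < 3:
            raise ValueError(f"{param}: need >= 3 paired participants, got {len(common)}")
        a, b = a.loc[common], b.loc[common]
        for quantity in QUANTITIES:
            if quantity == "acrophase":
                diffs = np.asarray(circular_diff(b[quantity], a[quantity]))
            else:
                diffs = b[quantity].to_numpy(float) - a[quantity].to_numpy(float)
            p, method, degenerate = _paired_test(diffs)
            per_quantity[quantity].append({
                "parameter": param, "quantity": quantity,
                "delta": float(np.mean(diffs)), "sd": float(np.std(diffs, ddof=1)),
                "n_pairs": int(len(diffs)), "p_raw": p, "test": method,
                "degenerate": degenerate,
            })
    for quantity in QUANTITIES:
        entries = per_quantity[quantity]
        adj = holm_adjust([e["p_raw"] for e in entries])
        for e, pa in zip(entries, adj):
            e["p_holm"] = float(pa)
            rows.append(e)
    out = pd.DataFrame(rows)
    return out[["parameter", "quantity", "delta", "sd", "n_pairs",
                "p_raw", "p_holm", "test", "degenerate"]]
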