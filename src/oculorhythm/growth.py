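"""Axial-length growth: time-matched deltas, classification, associations.

Interval changes in axial length (dAL) are computed from each season's
fitted sinusoid evaluated at a common set of reference times relative to
habitual sleep time ("time-matched" AL), which removes the diurnal
component from between-season differences.  Participants are classified
against the expected coordinated-growth band — axial elongation without
refractive change, 0.030 < dAL <= 0.089 mm over 12 months — rescaled to
the interval length in months.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cosinor import CosinorFit, evaluate_sinusoid
from .season import circular_diff

#: Default reference times (hours relative to HST) for time-matched AL:
#: the six evening epochs, averaged.
DEFAULT_T_REF = (-4.0, -3.0, -2.0, -1.0, 0.0, 1.0)

ANNUAL_BOUNDS = (0.030, 0.089)

SEVEN_MONTH_CATEGORIES = ("decelerated", "coordinated", "accelerated")
ANNUAL_CATEGORIES = ("shortening", "no_growth", "coordinated", "accelerated")


@dataclass(frozen=True)
class GrowthThresholds:
    """Coordinated-growth band (mm) for a given interval length in months."""

    scheme: str  # {seven_month, annual}
    bounds: tuple[float, float]
    months: float

    def __post_init__(self) -> None:
        if self.scheme not in ("seven_month", "annual"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not self.bounds[0] < self.bounds[1]:
            raise ValueError("bounds must be strictly increasing")


def _quantize_mm(x: float, places: int = 3) -> float:
    # Reported growth bounds carry 3 decimals with exact halves rounded
    # down (0.0175 -> 0.017), so rescaled bounds match the published band.
    q = decimal.Decimal(1).scaleb(-places)
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_DOWN))


def scale_thresholds(annual_bounds: tuple[float, float] = ANNUAL_BOUNDS,
                     months: float = 7.0) -> GrowthThresholds:
    """Rescale the annual coordinated-growth band to an interval of
    ``months`` months, quantized to 3 decimals (mm)."""
    if not 0 < months <= 24:
        raise ValueError("months must lie in (0, 24]")
    if months == 12.0:
        return GrowthThresholds(scheme="annual",
                                bounds=tuple(float(b) for b in annual_bounds),
                                months=months)
    bounds = tuple(_quantize_mm(b * months / 12.0) for b in annual_bounds)
    return GrowthThresholds(scheme="seven_month", bounds=bounds, months=months)


def classify_growth(delta_al: float, thresholds: GrowthThresholds) -> str:
    """Growth category for an interval AL change (mm).

    Seven-month scheme (three categories, used for the winter-to-summer
    interval): decelerated dAL < lower; coordinated lower <= dAL < upper;
    accelerated dAL >= upper.  Annual scheme (four categories):
    shortening dAL <= 0; no growth 0 < dAL <= lower; coordinated
    lower < dAL <= upper; accelerated dAL > upper.
    """
    lo, hi = thresholds.bounds
    if thresholds.scheme == "seven_month":
        if delta_al < lo:
            return "decelerated"
        if delta_al < hi:
            return "coordinated"
        return "accelerated"
    if delta_al <= 0.0:
        return "shortening"
    if delta_al <= lo:
        return "no_growth"
    if delta_al <= hi:
        return "coordinated"
    return "accelerated"


def model_al_at(fit: CosinorFit, t_ref=DEFAULT_T_REF) -> float:
    """Time-matched model AL (mm): the fitted sinusoid evaluated at the
    reference time(s); an iterable of times is averaged."""
    vals = evaluate_sinusoid(fit, np.atleast_1d(np.asarray(t_ref, dtype=float)))
    return float(np.mean(vals))


INTERVALS = {"W1-S": ("W1", "S"), "S-W2": ("S", "W2"), "W1-W2": ("W1", "W2")}


@dataclass
class GrowthRecord:
    participant_id: str
    interval: str
    delta_al: float  # mm
    delta_cht: float = float("nan")  # um, MESOR difference
    al_phase_shift: float = float("nan")  # hours, circular
    category: str | None = None
    extra: dict = field(default_factory=dict)


def interval_deltas(
    al_fits: dict[str, dict[str, CosinorFit]],
    cht_fits: dict[str, dict[str, CosinorFit]] | None = None,
    intervals: tuple[str, ...] = ("W1-S",),
    t_ref=DEFAULT_T_REF,
    thresholds: GrowthThresholds | None = None,
) -> pd.DataFrame:
    """Per-participant interval deltas from season-wise individual fits.

    ``al_fits`` maps season -> participant_id -> AL CosinorFit (and
    similarly for ``cht_fits``).  For each requested interval: dAL is the
    difference of time-matched AL, the AL phase shift the circular
    acrophase difference, and dChT the ChT MESOR difference.  Participants
    missing a season are skipped with a warning.  A thresholds object adds
    a growth category per record.
    """
    records = []
    for interval in intervals:
        s0, s1 = INTERVALS[interval]
        if s0 not in al_fits or s1 not in al_fits:
            raise ValueError(f"interval {interval}: missing season fits")
        for pid in sorted(al_fits[s0]):
            if pid not in al_fits[s1]:
                warnings.warn(f"participant {pid}: no {s1} AL fit; skipped")
                continue
            f0, f1 = al_fits[s0][pid], al_fits[s1][pid]
            delta_al = model_al_at(f1, t_ref) - model_al_at(f0, t_ref)
            shift = float(circular_diff(f1.acrophase, f0.acrophase))
            delta_cht = float("nan")
            if cht_fits and pid in cht_fits.get(s0, {}) and pid in cht_fits.get(s1, {}):
                delta_cht = cht_fits[s1][pid].mesor - cht_fits[s0][pid].mesor
            rec = {
                "participant_id": pid, "interval": interval,
                "delta_al": float(delta_al), "delta_cht": delta_cht,
                "al_phase_shift": shift,
            }
            if thresholds is not None:
                rec["category"] = classify_growth(delta_al, thresholds)
            records.append(rec)
    return pd.DataFrame(records)


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r2: float
    f_stat: float
    df: tuple[int, int]
    p_value: float


def _simple_regression(x: np.ndarray, y: np.ndarray) -> RegressionSummary:
    import statsmodels.api as sm

    X = sm.add_constant(np.asarray(x, dtype=float))
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return RegressionSummary(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        r2=float(res.rsquared), f_stat=float(res.fvalue),
        df=(int(res.df_model), int(res.df_resid)), p_value=float(res.f_pvalue),
    )


def association_stats(records: pd.DataFrame) -> dict:
    """Association analyses on a growth-record table.

    Returns simple linear regressions of dAL on dChT and on the AL phase
    shift (slope, intercept, R², F, p) and — when a ``category`` column
    with at least two populated groups is present — a one-way ANOVA of dAL
    across growth categories with Tukey HSD pairwise comparisons.
    """
    if len(records) < 4:
        raise ValueError("need >= 4 growth records")
    out: dict = {}
    if records["delta_cht"].notna().all():
        out["al_on_cht"] = _simple_regression(records["delta_cht"], records["delta_al"])
    if records["al_phase_shift"].notna().all():
        out["al_on_phase_shift"] = _simple_regression(
            records["al_phase_shift"], records["delta_al"])
    if "category" in records.columns:
        groups = [g["delta_al"].to_numpy(float)
                  for _, g in records.groupby("category") if len(g) > 0]
        sizes = [len(g) for g in groups]
        if len(groups) >= 2 and min(sizes) >= 2:
            F, p = stats.f_oneway(*groups)
            out["anova"] = {
                "f_stat": float(F),
                "df": (len(groups) - 1, int(sum(sizes) - len(groups))),
                "p_value": float(p),
            }
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            tk = pairwise_tukeyhsd(records["delta_al"].to_numpy(float),
                                   records["category"].to_numpy(), alpha=0.05)
            out["tukey"] = pd.DataFrame(
                tk.summary().data[1:], columns=tk.summary().data[0])
        else:
            out["anova"] = {"degenerate": True,
                            "reason": "a category has < 2 members"}
    return out
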