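"""Dim-light melatonin onset (DLMO) from a log-scale melatonin cosinor.

DLMO is the evening time at which salivary melatonin rises through a fixed
threshold (3 pg/mL by convention).  Given the fitted sinusoid on the
natural-log concentration scale,

    log y(t) = M + A * sin(2*pi*(t + phi)/24),

the onset is the rising solution of log y(t) = log(threshold):

    DLMO = (24 / 2*pi) * asin((log(threshold) - M) / A) - phi,

in hours relative to habitual sleep time.  The principal asin branch keeps
the solution on the rising limb, in the half-period before the acrophase.
Natural logarithms are used throughout, consistent with the log-scale fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cosinor import OMEGA, CosinorFit, evaluate_sinusoid
from .io_model import to_clock_time


@dataclass
class DlmoResult:
    """Threshold-crossing melatonin onset relative to HST."""

    dlmo_rel: float  # hours relative to HST; nan when undefined
    threshold: float = 3.0  # pg/mL
    defined: bool = True
    reason: str = ""

    def clock(self, hst_clock) -> str:
        return dlmo_clock(self, hst_clock)


def dlmo_relative(fit: CosinorFit, threshold: float = 3.0) -> DlmoResult:
    """Melatonin onset time relative to HST from a log-scale melatonin fit.

    Undefined when the fitted curve never crosses the threshold (entirely
    above or below it) or when the amplitude is zero.
    """
    if not fit.log_scale:
        raise ValueError("DLMO requires a cosinor fitted on the log-melatonin scale")
    if threshold <= 0:
        raise ValueError("threshold must be positive (pg/mL)")
    if fit.amplitude <= 0 or fit.degenerate:
        return DlmoResult(math.nan, threshold, defined=False, reason="zero amplitude")
    x = (math.log(threshold) - fit.mesor) / fit.amplitude
    if abs(x) > 1.0:
        reason = ("always above threshold" if x < -1.0 else "never reaches threshold")
        return DlmoResult(math.nan, threshold, defined=False, reason=reason)
    dlmo_rel = math.asin(x) / OMEGA - fit.phi
    return DlmoResult(float(dlmo_rel), threshold, defined=True)


def dlmo_clock(result: DlmoResult, hst_clock) -> str:
    """Render a defined onset as standard clock time given the HST anchor."""
    if not result.defined:
        raise ValueError(f"DLMO undefined ({result.reason}); no clock time")
    return to_clock_time(result.dlmo_rel, hst_clock)


def dlmo_scan(fit: CosinorFit, threshold: float = 3.0, step: float = 1e-4) -> float:
    """Dense-scan reference estimate of the rising threshold crossing.

    Scans the fitted log-scale curve over the half-period ending at the
    acrophase and returns the first time the curve rises through
    log(threshold), located by bisection between bracketing grid points.
    Exists as an independent cross-check of :func:`dlmo_relative`; returns
    nan when no crossing lies in the scanned window.
    """
    import numpy as np

    target = math.log(threshold)
    t0, t1 = fit.acrophase - 12.0, fit.acrophase
    grid = np.arange(t0, t1 + step, step)
    vals = evaluate_sinusoid(fit, grid) - target
    below = vals[:-1] <= 0
    above = vals[1:] > 0
    crossings = np.where(below & above)[0]
    if len(crossings) == 0:
        return math.nan
    lo, hi = grid[crossings[0]], grid[crossings[0] + 1]
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if evaluate_sinusoid(fit, mid) - target <= 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
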