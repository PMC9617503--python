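"""Fixed-period (24 h) cosinor fitting and diurnal-variation testing.

The model is

    y(t) = M + A * sin(2*pi*(t + phi) / 24)

with MESOR ``M``, amplitude ``A >= 0`` and phase parameter ``phi`` in hours;
``t`` is hours relative to habitual sleep time (HST).  The sinusoid peaks
where its argument is pi/2, i.e. at t = 6 - phi, so the acrophase (peak
time relative to HST, wrapped into (-12, 12]) is

    acrophase = wrap(6 - phi).

Because the period is fixed, the model is linear in the equivalent basis

    y(t) = M + b_s * sin(w t) + b_c * cos(w t),      w = 2*pi/24,

with A = hypot(b_s, b_c) and phi = atan2(b_c, b_s) / w.  Individual fits are
ordinary least squares on this basis; the population fit is a linear mixed
model on the same basis with per-subject random effects, whose fixed effects
are transformed back to polar (M, A, acrophase) form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

OMEGA = 2.0 * math.pi / 24.0

#: Amplitudes below this (in value units) are treated as rhythm-free; the
#: acrophase is then undefined and reported as the conventional 6 h.
DEGENERATE_AMPLITUDE = 1e-12


def wrap_half_day(x):
    """Wrap hours into the half-open interval (-12, 12]."""
    r = np.asarray(x, dtype=float)
    out = (r + 12.0) % 24.0 - 12.0
    out = np.where(out == -12.0, 12.0, out)
    return float(out) if np.isscalar(x) or out.ndim == 0 else out


def coeffs_to_polar(beta_sin: float, beta_cos: float) -> tuple[float, float]:
    """(amplitude, acrophase) from linearized sin/cos coefficients.

    The acrophase is the peak time relative to HST in (-12, 12]; for a
    degenerate amplitude it is reported as 6 by convention.
    """
    amplitude = math.hypot(beta_sin, beta_cos)
    if amplitude < DEGENERATE_AMPLITUDE:
        return 0.0, 6.0
    phi = math.atan2(beta_cos, beta_sin) / OMEGA
    return amplitude, wrap_half_day(6.0 - phi)


def polar_to_coeffs(amplitude: float, acrophase: float) -> tuple[float, float]:
    """Inverse of :func:`coeffs_to_polar`."""
    phi = 6.0 - acrophase
    return amplitude * math.cos(OMEGA * phi), amplitude * math.sin(OMEGA * phi)


@dataclass
class CosinorFit:
    """A fitted 24-h sinusoid for one parameter / fitting scope / season."""

    mesor: float
    amplitude: float
    acrophase: float
    beta_sin: float
    beta_cos: float
    scope: str = "individual"  # {individual, population}
    parameter: str | None = None
    season: str | None = None
    participant_id: str | None = None
    log_scale: bool = False
    resid_sd: float = float("nan")
    n_obs: int = 0
    degenerate: bool = False
    method: str = "ols"  # {ols, lmm, two_stage}
    converged: bool = True
    ci: dict = field(default_factory=dict)

    @property
    def phi(self) -> float:
        """Phase parameter of the sine form, phi = 6 - acrophase (hours)."""
        return 6.0 - self.acrophase

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")


def evaluate_sinusoid(fit: CosinorFit, t) -> np.ndarray | float:
    """Model value at time(s) ``t`` (hours relative to HST).

    For a log-scale melatonin fit the returned value is on the natural-log
    scale, matching the scale the model was fitted on.
    """
    t = np.asarray(t, dtype=float)
    out = fit.mesor + fit.amplitude * np.sin(OMEGA * (t + fit.phi))
    return float(out) if out.ndim == 0 else out


def design_matrix(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.column_stack([np.ones_like(t), np.sin(OMEGA * t), np.cos(OMEGA * t)])


def _check_series(t: np.ndarray, y: np.ndarray) -> None:
    if len(t) != len(y):
        raise ValueError("t and y must have equal length")
    if len(t) < 4:
        raise ValueError(f"need >= 4 observations, got {len(t)}")
    distinct = np.unique(np.round(np.asarray(t, dtype=float) % 24.0, 9))
    if len(distinct) < 3:
        raise ValueError(
            f"need >= 3 distinct times mod 24 h, got {len(distinct)} (rank-deficient)"
        )


def fit_individual(t, y, log_scale: bool = False, **meta) -> CosinorFit:
    """Least-squares cosinor fit of a single series.

    ``log_scale=True`` fits the natural log of the values (required for
    melatonin, whose secretion profile is log-sinusoidal); the returned
    MESOR/amplitude are then on the log scale.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_series(t, y)
    if log_scale:
        if np.any(y <= 0):
            raise ValueError("log-scale fit requires strictly positive values")
        y = np.log(y)
    X = design_matrix(t)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - 3
    resid_sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else float("nan")
    mesor, beta_sin, beta_cos = (float(b) for b in beta)
    amplitude, acrophase = coeffs_to_polar(beta_sin, beta_cos)
    return CosinorFit(
        mesor=mesor, amplitude=amplitude, acrophase=acrophase,
        beta_sin=beta_sin, beta_cos=beta_cos, log_scale=log_scale,
        resid_sd=resid_sd, n_obs=len(y),
        degenerate=amplitude < DEGENERATE_AMPLITUDE, method="ols", **meta,
    )


def fit_individual_batch(t, Y) -> np.ndarray:
    """Cosinor coefficients for many series sharing one time vector.

    ``Y`` has one series per column; returns an array of shape (3, n_series)
    with rows (mesor, beta_sin, beta_cos).  Used by the simulation studies,
    where thousands of per-subject fits share the epoch schedule.
    """
    X = design_matrix(np.asarray(t, dtype=float))
    beta, _, _, _ = np.linalg.lstsq(X, np.asarray(Y, dtype=float), rcond=None)
    return beta


def _two_stage(individuals: list[CosinorFit]) -> tuple[float, float, float]:
    """Mean of individual linearized coefficients (the two-stage estimator)."""
    mesor = float(np.mean([f.mesor for f in individuals]))
    bs = float(np.mean([f.beta_sin for f in individuals]))
    bc = float(np.mean([f.beta_cos for f in individuals]))
    return mesor, bs, bc


def fit_population(
    data: pd.DataFrame,
    log_scale: bool = False,
    ci: bool = False,
    n_boot: int = 1000,
    seed: int | None = None,
    **meta,
) -> tuple[CosinorFit, list[CosinorFit]]:
    """Population cosinor for one parameter-season slice.

    ``data`` needs columns ``participant_id``, ``t_rel`` and ``value``.  The
    estimate is a linear mixed model on the sin/cos basis with independent
    per-subject random effects on intercept, sin and cos coefficients
    (REML); fixed effects are transformed to polar form.  If the mixed model
    fails to converge, or the data are noise-free (zero residual variance,
    where REML is ill-posed), the two-stage estimator — the mean of the
    individual coefficient vectors — is used and flagged.

    Confidence intervals, when requested, are percentile bootstrap over
    participants of the two-stage estimator (acrophase deviations wrapped
    around the point estimate before taking percentiles).

    Returns the population fit and the per-participant individual fits.
    """
    groups = [g for _, g in data.groupby("participant_id", sort=True)]
    individuals = []
    for g in groups:
        f = fit_individual(
            g["t_rel"].to_numpy(), g["value"].to_numpy(), log_scale=log_scale,
            participant_id=str(g["participant_id"].iloc[0]), **meta,
        )
        individuals.append(f)
    if not individuals:
        raise ValueError("no fit-eligible participants")
    if len(individuals) == 1:
        pop = replace(individuals[0], scope="population", method="degenerate_single")
        return pop, individuals

    y = data["value"].to_numpy(dtype=float)
    if log_scale:
        y = np.log(y)
    t = data["t_rel"].to_numpy(dtype=float)
    X = design_matrix(t)
    codes = pd.factorize(data["participant_id"])[0]

    mesor = bs = bc = None
    method, converged, resid_sd = "lmm", True, float("nan")
    pooled_resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    if float(np.std(pooled_resid)) < 1e-10:
        # noise-free data: REML variance components are ill-posed
        mesor, bs, bc = _two_stage(individuals)
        method, resid_sd = "two_stage", 0.0
    else:
        try:
            from statsmodels.regression.mixed_linear_model import MixedLM

            frame = pd.DataFrame(
                {"y": y, "s": X[:, 1], "c": X[:, 2], "g": codes}
            )
            model = MixedLM.from_formula(
                "y ~ s + c", groups="g", re_formula="1",
                vc_formula={"s": "0 + s", "c": "0 + c"}, data=frame,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = model.fit(reml=True, method="lbfgs")
            if not result.converged or not np.all(np.isfinite(result.fe_params)):
                raise RuntimeError("mixed model did not converge")
            mesor, bs, bc = (float(v) for v in result.fe_params)
            resid_sd = float(np.sqrt(result.scale))
        except Exception:
            mesor, bs, bc = _two_stage(individuals)
            method, converged = "two_stage", False
            warnings.warn("mixed-model cosinor fell back to two-stage estimate")

    amplitude, acrophase = coeffs_to_polar(bs, bc)
    pop = CosinorFit(
        mesor=mesor, amplitude=amplitude, acrophase=acrophase,
        beta_sin=bs, beta_cos=bc, scope="population", log_scale=log_scale,
        resid_sd=resid_sd, n_obs=len(y),
        degenerate=amplitude < DEGENERATE_AMPLITUDE,
        method=method, converged=converged, **meta,
    )
    if ci:
        pop.ci = _bootstrap_ci(individuals, pop, n_boot=n_boot, seed=seed)
    return pop, individuals


def _bootstrap_ci(
    individuals: list[CosinorFit], pop: CosinorFit, n_boot: int, seed: int | None,
    level: float = 0.95,
) -> dict:
    rng = np.random.default_rng(seed)
    coef = np.array([[f.mesor, f.beta_sin, f.beta_cos] for f in individuals])
    n = len(coef)
    idx = rng.integers(0, n, size=(n_boot, n))
    means = coef[idx].mean(axis=1)  # n_boot x 3
    amp = np.hypot(means[:, 1], means[:, 2])
    phi = np.arctan2(means[:, 2], means[:, 1]) / OMEGA
    acro = wrap_half_day(6.0 - phi)
    # wrap acrophase deviations around the point estimate before percentiles
    acro = pop.acrophase + wrap_half_day(acro - pop.acrophase)
    lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
    out = {}
    for name, vals in (("mesor", means[:, 0]), ("amplitude", amp), ("acrophase", acro)):
        out[name] = (float(np.percentile(vals, lo)), float(np.percentile(vals, hi)))
    return out


@dataclass
class DiurnalTestResult:
    """F-test for an epoch effect in a subject-blocked layout."""

    statistic: float
    df_num: int
    df_den: int
    p_value: float
    method: str = "blocked_anova"
    p_permutation: float | None = None
    parameter: str | None = None
    season: str | None = None


def _epoch_f(y: np.ndarray, subj: np.ndarray, epoch: np.ndarray,
             n_subj: int, n_epoch: int) -> tuple[float, int, int]:
    """F for the epoch factor given subject blocks, via RSS comparison of
    the dummy-coded linear models with and without epoch."""
    n = len(y)
    Xs = np.zeros((n, n_subj))
    Xs[np.arange(n), subj] = 1.0
    Xe = np.zeros((n, n_epoch - 1))
    mask = epoch > 0
    Xe[np.where(mask)[0], epoch[mask] - 1] = 1.0
    X0 = Xs
    X1 = np.column_stack([Xs, Xe])
    rss0 = float(np.sum((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]) ** 2))
    rss1 = float(np.sum((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2))
    df_num = n_epoch - 1
    df_den = n - n_subj - df_num
    if df_den <= 0 or rss1 <= 0:
        raise ValueError("insufficient residual degrees of freedom for the epoch F-test")
    F = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    return F, df_num, df_den


def diurnal_variation_test(
    data: pd.DataFrame,
    log_scale: bool = False,
    n_perm: int = 0,
    seed: int | None = None,
    **meta,
) -> DiurnalTestResult:
    """Test for significant diurnal variation of one parameter-season slice.

    Fits a subject-blocked two-way layout (subject as block, measurement
    epoch as fixed repeated factor) and returns the F statistic for the
    epoch factor with its analytic p-value.  With ``n_perm > 0`` a
    permutation p-value is added, permuting epoch labels within subject.
    """
    subj_codes, subj_levels = pd.factorize(data["participant_id"])
    epoch_codes, epoch_levels = pd.factorize(data["epoch_label"])
    if len(subj_levels) < 2:
        raise ValueError("need >= 2 participants")
    if len(epoch_levels) < 3:
        raise ValueError("need >= 3 epochs")
    counts = pd.crosstab(subj_codes, epoch_codes)
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("an epoch has no observations")
    y = data["value"].to_numpy(dtype=float)
    if log_scale:
        y = np.log(y)
    F, df1, df2 = _epoch_f(y, subj_codes, epoch_codes, len(subj_levels), len(epoch_levels))
    p = float(stats.f.sf(F, df1, df2))
    result = DiurnalTestResult(statistic=float(F), df_num=df1, df_den=df2,
                               p_value=p, **meta)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        perm_epoch = epoch_codes.copy()
        order = np.argsort(subj_codes, kind="stable")
        for _ in range(n_perm):
            for s in range(len(subj_levels)):
                block = np.where(subj_codes == s)[0]
                perm_epoch[block] = rng.permutation(epoch_codes[block])
            Fp, _, _ = _epoch_f(y, subj_codes, perm_epoch, len(subj_levels), len(epoch_levels))
            exceed += Fp >= F
        result.p_permutation = (exceed + 1) / (n_perm + 1)
        result.method = "blocked_anova+permutation"
        del order
    return result


def normalize_to_mesor(values, fit: CosinorFit) -> np.ndarray:
    """Subtract the individual's fitted MESOR (units preserved).

    This is the normalization used to overlay individuals on a common
    baseline when plotting group rhythms; re-fitting the normalized series
    leaves amplitude and acrophase unchanged and moves the MESOR to 0.
    """
    return np.asarray(values, dtype=float) - fit.mesor


def fits_frame(fits: list[CosinorFit]) -> pd.DataFrame:
    """Tabulate fits (one row per fit), mirroring the CosinorFit fields."""
    rows = []
    for f in fits:
        rows.append({
            "scope": f.scope, "participant_id": f.participant_id,
            "parameter": f.parameter, "season": f.season,
            "mesor": f.mesor, "amplitude": f.amplitude, "acrophase": f.acrophase,
            "phi": f.phi, "beta_sin": f.beta_sin, "beta_cos": f.beta_cos,
            "log_scale": f.log_scale, "resid_sd": f.resid_sd, "n_obs": f.n_obs,
            "degenerate": f.degenerate, "method": f.method, "converged": f.converged,
        })
    return pd.DataFrame(rows)


def fit_from_row(row) -> CosinorFit:
    """Rebuild a CosinorFit from a row written by :func:`fits_frame`."""
    pid = row.get("participant_id")
    if pid is not None and (isinstance(pid, float) and math.isnan(pid)):
        pid = None
    return CosinorFit(
        mesor=float(row["mesor"]), amplitude=float(row["amplitude"]),
        acrophase=float(row["acrophase"]), beta_sin=float(row["beta_sin"]),
        beta_cos=float(row["beta_cos"]), scope=str(row["scope"]),
        parameter=row["parameter"], season=row["season"],
        participant_id=None if pid is None else str(pid),
        log_scale=bool(row["log_scale"]),
        resid_sd=float(row["resid_sd"]), n_obs=int(row["n_obs"]),
        degenerate=bool(row["degenerate"]), method=str(row["method"]),
    )
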