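"""Synthetic cohort generation.

Emulates the study design the analysis assumes: n of order 24-35 young
adults, each measured at eight epochs across one day (two morning epochs
anchored to habitual wake time, six evening epochs anchored to habitual
sleep time), in up to three seasons (winter W1, summer S, second winter
W2).  Every parameter follows a fixed-period 24-h sinusoid with
population-level MESOR/amplitude/acrophase plus independent normal
between-subject effects on each (amplitude truncated at zero, acrophase
wrapped on the circle) and i.i.d. normal residual noise; melatonin is
generated on the natural-log scale and exponentiated, so emitted
concentrations are strictly positive and log-sinusoidal.

Subject-level effects are drawn once per participant and shared across
seasons: chronotype-anchored sampling makes within-person rhythm traits
persistent, while seasonal change enters through the season-specific
population truth.  True per-subject parameters are emitted alongside the
data so downstream estimates can be scored against them.

All randomness flows from a single :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import population
from .cosinor import OMEGA, wrap_half_day
from .io_model import (CohortTable, epoch_labels_for, epoch_time, format_clock)


@dataclass
class ParamTruth:
    """True population rhythm and variability for one parameter-season."""

    mesor: float
    amplitude: float
    acrophase: float  # hours relative to HST, in (-12, 12]
    sd_mesor: float = 0.0
    sd_amplitude: float = 0.0
    sd_acrophase: float = 0.0  # hours
    resid_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        for name in ("sd_mesor", "sd_amplitude", "sd_acrophase", "resid_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (-12.0 < self.acrophase <= 12.0):
            raise ValueError("acrophase must lie in (-12, 12]")


#: Default variability: between-subject SDs on the MESOR are back-calculated
#: from the published population 95% CI half-widths (SE * sqrt(24), which
#: matches the printed cohort SDs, e.g. 1.4 mm for AL); between-subject
#: amplitude SDs use the same back-calculation capped at one-third of the
#: amplitude (the CI-implied value conflates estimation error with
#: heterogeneity, and larger values would leave an appreciable fraction of
#: subjects with no rhythm at all); the acrophase SD is 0.5 h for every
#: parameter (sampling anchored to each individual's habitual sleep time
#: removes chronotype differences, the dominant source of phase variance);
#: residual SDs are at instrument/assay repeatability scale.  Units as
#: stored (MEL on the log scale).
DEFAULT_VARIABILITY: dict[str, dict[str, float]] = {
    "MEL": dict(sd_mesor=0.51, sd_amplitude=0.59, sd_acrophase=0.5, resid_sd=0.35),
    "IOP": dict(sd_mesor=2.79, sd_amplitude=0.94, sd_acrophase=0.5, resid_sd=1.0),
    "ACD": dict(sd_mesor=0.27, sd_amplitude=0.0063, sd_acrophase=0.5, resid_sd=0.008),
    "LT": dict(sd_mesor=0.24, sd_amplitude=0.005, sd_acrophase=0.5, resid_sd=0.008),
    "VCD": dict(sd_mesor=1.40, sd_amplitude=0.018, sd_acrophase=0.5, resid_sd=0.012),
    "AL": dict(sd_mesor=1.37, sd_amplitude=0.0063, sd_acrophase=0.5, resid_sd=0.004),
    "RT": dict(sd_mesor=13.7, sd_amplitude=0.67, sd_acrophase=0.5, resid_sd=0.8),
    "ChT": dict(sd_mesor=108.0, sd_amplitude=0.67, sd_acrophase=0.5, resid_sd=2.0),
}


@dataclass
class SimulationTruth:
    """Complete specification of a synthetic cohort."""

    n_participants: int = 24
    seasons: tuple[str, ...] = ("W1", "S")
    params: dict[str, dict[str, ParamTruth]] = field(default_factory=dict)
    hst_mean: float = population.HST_ANCHOR_H  # clock hours
    hst_sd: float = 0.9
    wake_span_mean: float = 16.0  # hours awake, HWT to HST
    wake_span_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.seasons:
            raise ValueError("season set must be nonempty")
        unknown = set(self.seasons) - {"W1", "S", "W2"}
        if unknown:
            raise ValueError(f"unknown seasons {sorted(unknown)}")

    def to_yaml(self, path: str) -> None:
        payload = {
            "n_participants": self.n_participants,
            "seasons": list(self.seasons),
            "hst_mean": self.hst_mean, "hst_sd": self.hst_sd,
            "wake_span_mean": self.wake_span_mean, "wake_span_sd": self.wake_span_sd,
            "seed": self.seed,
            "params": {
                p: {s: vars(t).copy() for s, t in by_season.items()}
                for p, by_season in self.params.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationTruth":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        params = {
            p: {s: ParamTruth(**t) for s, t in by_season.items()}
            for p, by_season in payload.pop("params", {}).items()
        }
        payload["seasons"] = tuple(payload.get("seasons", ("W1", "S")))
        return cls(params=params, **payload)


def default_truth(parameters=None, seasons=("W1", "S"), n_participants: int = 24,
                  seed: int = 0) -> SimulationTruth:
    """Truth at the published population estimates with default variability."""
    parameters = list(parameters or population.POPULATION_ESTIMATES)
    params = {}
    for p in parameters:
        by_season = {}
        for s in seasons:
            est = population.POPULATION_ESTIMATES[p][s]
            by_season[s] = ParamTruth(
                mesor=est.mesor, amplitude=est.amplitude, acrophase=est.acrophase,
                **DEFAULT_VARIABILITY[p],
            )
        params[p] = by_season
    return SimulationTruth(n_participants=n_participants, seasons=tuple(seasons),
                           params=params, seed=seed)


def noise_free(truth: SimulationTruth) -> SimulationTruth:
    """Copy of a truth with every variance component set to zero."""
    params = {
        p: {s: replace(t, sd_mesor=0.0, sd_amplitude=0.0, sd_acrophase=0.0,
                       resid_sd=0.0)
            for s, t in by_season.items()}
        for p, by_season in truth.params.items()
    }
    return replace(truth, params=params, hst_sd=0.0, wake_span_sd=0.0)


def _draw_participants(truth: SimulationTruth, rng: np.random.Generator) -> pd.DataFrame:
    n = truth.n_participants
    hst = (truth.hst_mean + rng.normal(0.0, truth.hst_sd, n)) % 24.0
    span = np.clip(truth.wake_span_mean + rng.normal(0.0, truth.wake_span_sd, n), 12.0, 20.0)
    hwt = (hst - span) % 24.0
    sphere = np.round(rng.normal(-0.5, 2.2, n) * 4) / 4
    cylinder = -np.round(np.abs(rng.normal(0.0, 0.4, n)) * 4) / 4
    return pd.DataFrame({
        "id": [f"P{i + 1:02d}" for i in range(n)],
        "sex": [("F", "M")[i % 2] for i in range(n)],
        "age": np.round(rng.uniform(17.0, 25.0, n), 1),
        "hst_clock": [format_clock(h) for h in hst],
        "hwt_clock": [format_clock(h) for h in hwt],
        "sphere": sphere,
        "cylinder": cylinder,
    })


def _subject_rhythm(pt: ParamTruth, effects: tuple[float, float, float]):
    d_m, d_a, d_phi = effects
    return (pt.mesor + d_m * pt.sd_mesor,
            max(0.0, pt.amplitude + d_a * pt.sd_amplitude),
            float(wrap_half_day(pt.acrophase + d_phi * pt.sd_acrophase)))


def generate_cohort(truth: SimulationTruth,
                    rng: np.random.Generator | None = None
                    ) -> tuple[CohortTable, pd.DataFrame]:
    """Simulate a cohort; returns the table plus the per-subject truth.

    The truth frame has one row per (participant, season, parameter) with
    the subject-level MESOR, amplitude and acrophase actually used.
    """
    has_re = any(
        t.sd_mesor or t.sd_amplitude or t.sd_acrophase
        for by_season in truth.params.values() for t in by_season.values()
    )
    if truth.n_participants < 2 and has_re:
        raise ValueError("need n >= 2 when random effects are requested")
    if not truth.params:
        raise ValueError("no parameters to simulate")
    rng = rng or np.random.default_rng(truth.seed)
    participants = _draw_participants(truth, rng)
    meas_rows, truth_rows = [], []
    for _, prof in participants.iterrows():
        pid = prof["id"]
        for param in truth.params:
            effects = tuple(rng.normal(0.0, 1.0, 3))  # z-scores, shared across seasons
            labels = epoch_labels_for(param)
            times = np.array([epoch_time(lab, prof["hwt_clock"], prof["hst_clock"])
                              for lab in labels])
            for season in truth.seasons:
                pt = truth.params[param][season]
                m_i, a_i, acro_i = _subject_rhythm(pt, effects)
                signal = m_i + a_i * np.sin(OMEGA * (times + 6.0 - acro_i))
                values = signal + rng.normal(0.0, pt.resid_sd, len(times))
                if param == "MEL":
                    values = np.exp(values)
                for lab, t_rel, v in zip(labels, times, values):
                    meas_rows.append((pid, season, lab, float(t_rel), param, float(v)))
                truth_rows.append((pid, season, param, m_i, a_i, acro_i))
    measurements = pd.DataFrame(
        meas_rows,
        columns=["participant_id", "season", "epoch_label", "t_rel", "parameter", "value"])
    truth_df = pd.DataFrame(
        truth_rows,
        columns=["participant_id", "season", "parameter", "mesor", "amplitude", "acrophase"])
    return CohortTable(participants, measurements), truth_df


def noise_sd_for_r2(slope: float, sd_x: float, r2: float) -> float:
    """Residual SD that makes a simple regression with the given slope and
    predictor SD attain the target population R^2."""
    if not 0 < r2 < 1:
        raise ValueError("r2 must lie strictly between 0 and 1")
    return abs(slope) * sd_x * np.sqrt((1.0 - r2) / r2)


@dataclass
class GrowthTruth:
    """Truth for the growth cohort: per-interval AL change plus the
    regression structure linking winter-to-summer dAL to dChT and to the
    AL phase shift.

    Interval changes are additive by construction: the annual change is
    the sum of the two seasonal changes.  Slopes are in um/mm (dChT) and
    h/mm (phase shift); residual SDs default to the values that hit the
    published R^2 targets (0.54 and 0.81) at the default dAL spread.
    """

    n_participants: int = 24
    mean_dal_w1_s: float = 0.057  # mm over the 7-month winter-summer interval
    sd_dal_w1_s: float = 0.045
    mean_dal_s_w2: float = 0.002  # mm, summer to second winter
    sd_dal_s_w2: float = 0.040
    slope_cht: float = -170.0  # um of dChT per mm of dAL
    intercept_cht: float = 0.0
    r2_cht: float = 0.54
    slope_phase: float = 18.0  # h of AL phase shift per mm of dAL
    intercept_phase: float = -2.0
    r2_phase: float = 0.81
    noise_cht_sd: float | None = None  # explicit residual SDs override the
    noise_phase_sd: float | None = None  # R^2 targets when set
    seed: int = 0

    @property
    def noise_cht(self) -> float:
        if self.noise_cht_sd is not None:
            return self.noise_cht_sd
        return noise_sd_for_r2(self.slope_cht, self.sd_dal_w1_s, self.r2_cht)

    @property
    def noise_phase(self) -> float:
        if self.noise_phase_sd is not None:
            return self.noise_phase_sd
        return noise_sd_for_r2(self.slope_phase, self.sd_dal_w1_s, self.r2_phase)


def generate_growth_cohort(gtruth: GrowthTruth,
                           base: SimulationTruth | None = None
                           ) -> tuple[CohortTable, pd.DataFrame]:
    """Simulate AL and ChT across seasons with known growth structure.

    Per participant, the AL MESOR shifts from W1 to S by the true dAL and
    from S to W2 by the second-interval dAL; the AL acrophase shifts by the
    true phase shift from W1 to S; the ChT MESOR shifts by the true dChT.
    The emitted truth frame carries dAL per interval (exactly additive),
    dChT and the phase shift for scoring downstream estimates.
    """
    base = base or default_truth(parameters=("AL", "ChT"), seasons=("W1", "S"))
    needed = {"W1", "S"}
    if not needed <= set(base.seasons) | {"W2"}:
        raise ValueError("growth simulation needs at least seasons W1 and S")
    rng = np.random.default_rng(gtruth.seed)
    n = gtruth.n_participants
    dal1 = rng.normal(gtruth.mean_dal_w1_s, gtruth.sd_dal_w1_s, n)
    dal2 = rng.normal(gtruth.mean_dal_s_w2, gtruth.sd_dal_s_w2, n)
    dcht = (gtruth.intercept_cht + gtruth.slope_cht * dal1
            + rng.normal(0.0, gtruth.noise_cht, n))
    shift = (gtruth.intercept_phase + gtruth.slope_phase * dal1
             + rng.normal(0.0, gtruth.noise_phase, n))

    al_w1 = base.params["AL"]["W1"]
    cht_w1 = base.params["ChT"]["W1"]
    truth = SimulationTruth(
        n_participants=n, seasons=("W1",), params={},
        hst_mean=base.hst_mean, hst_sd=base.hst_sd,
        wake_span_mean=base.wake_span_mean, wake_span_sd=base.wake_span_sd,
        seed=gtruth.seed,
    )
    participants = _draw_participants(truth, rng)
    meas_rows, truth_rows = [], []
    for i, (_, prof) in enumerate(participants.iterrows()):
        pid = prof["id"]
        times = {lab: epoch_time(lab, prof["hwt_clock"], prof["hst_clock"])
                 for lab in epoch_labels_for("AL")}
        eff_al = tuple(rng.normal(0.0, 1.0, 3))
        eff_cht = tuple(rng.normal(0.0, 1.0, 3))
        m_al, a_al, acro_al = _subject_rhythm(al_w1, eff_al)
        m_cht, a_cht, acro_cht = _subject_rhythm(cht_w1, eff_cht)
        season_al = {
            "W1": (m_al, a_al, acro_al),
            "S": (m_al + dal1[i], a_al, float(wrap_half_day(acro_al + shift[i]))),
            "W2": (m_al + dal1[i] + dal2[i], a_al, acro_al),
        }
        season_cht = {
            "W1": (m_cht, a_cht, acro_cht),
            "S": (m_cht + dcht[i], a_cht, acro_cht),
        }
        for param, by_season, resid in (("AL", season_al, al_w1.resid_sd),
                                        ("ChT", season_cht, cht_w1.resid_sd)):
            for season, (m_i, a_i, acro_i) in by_season.items():
                tvec = np.array([times[lab] for lab in epoch_labels_for(param)])
                values = (m_i + a_i * np.sin(OMEGA * (tvec + 6.0 - acro_i))
                          + rng.normal(0.0, resid, len(tvec)))
                for lab, t_rel, v in zip(epoch_labels_for(param), tvec, values):
                    meas_rows.append((pid, season, lab, float(t_rel), param, float(v)))
        truth_rows.append((pid, dal1[i], dal2[i], dal1[i] + dal2[i], dcht[i], shift[i]))
    measurements = pd.DataFrame(
        meas_rows,
        columns=["participant_id", "season", "epoch_label", "t_rel", "parameter", "value"])
    truth_df = pd.DataFrame(
        truth_rows,
        columns=["participant_id", "dal_w1_s", "dal_s_w2", "dal_w1_w2",
                 "dcht_w1_s", "al_phase_shift"])
    return CohortTable(participants, measurements), truth_df
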