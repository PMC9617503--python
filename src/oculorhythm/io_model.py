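"""Data model, file I/O and time-coordinate conventions.

Measurements are stored long/tidy: one row per (participant, season, epoch,
parameter) observation, with time expressed in signed decimal hours relative
to the participant's habitual sleep time (HST).  Under this convention the
two morning epochs (one and four hours after habitual wake time, HWT) land
at large negative offsets (around -17 to -12 h) and the six evening epochs
run from -4 h to +1 h around sleep onset.

All clock times are 24-h ``HH:MM`` strings (fractional minutes accepted on
input); internally they are decimal hours in [0, 24).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

#: Measured parameters and their storage units.
PARAMETER_UNITS = {
    "MEL": "pg/mL",
    "IOP": "mm Hg",
    "ACD": "mm",
    "LT": "mm",
    "VCD": "mm",
    "AL": "mm",
    "RT": "um",
    "ChT": "um",
}
PARAMETERS = tuple(PARAMETER_UNITS)

SEASONS = ("W1", "S", "W2")

#: Epoch schedule: two morning epochs anchored to habitual wake time and six
#: evening epochs anchored to habitual sleep time.
MORNING_EPOCHS = {"HWT+1": 1.0, "HWT+4": 4.0}
EVENING_EPOCHS = {
    "HST-4": -4.0,
    "HST-3": -3.0,
    "HST-2": -2.0,
    "HST-1": -1.0,
    "HST+0": 0.0,
    "HST+1": 1.0,
}
EPOCH_LABELS = tuple(MORNING_EPOCHS) + tuple(EVENING_EPOCHS)

#: Saliva for melatonin is collected at HWT+1 and the six evening epochs only.
MEL_EPOCH_LABELS = ("HWT+1",) + tuple(EVENING_EPOCHS)


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the data contract."""


def _normalise_label(label: str) -> str:
    # tolerate the unicode minus that typeset tables use
    return label.replace("−", "-").strip()


def parse_clock(clock: str | float) -> float:
    """Parse a 24-h ``HH:MM`` clock time into decimal hours in [0, 24).

    Fractional minutes (``"00:07.6"``) are accepted.  A float input is
    interpreted as decimal hours and wrapped into [0, 24).
    """
    if isinstance(clock, (int, float)):
        return float(clock) % 24.0
    text = _normalise_label(str(clock))
    parts = text.split(":")
    if len(parts) != 2:
        raise ValueError(f"clock time must be HH:MM, got {clock!r}")
    hours = int(parts[0])
    minutes = float(parts[1])
    if not (0 <= hours < 24) or not (0.0 <= minutes < 60.0):
        raise ValueError(f"clock time out of range: {clock!r}")
    return hours + minutes / 60.0


def format_clock(hours: float) -> str:
    """Render decimal hours as ``HH:MM``, rounded to the nearest minute."""
    total_minutes = int(round((hours % 24.0) * 60.0)) % (24 * 60)
    return f"{total_minutes // 60:02d}:{total_minutes % 60:02d}"


def epoch_time(epoch_label: str, hwt_clock: str | float, hst_clock: str | float) -> float:
    """Hours relative to HST for a scheduled epoch.

    Evening labels encode their offset literally (``HST-4`` -> -4.0).
    Morning labels are anchored to habitual wake time: the wake clock time is
    wrapped into the waking day preceding sleep onset, so ``HWT+1`` with
    hwt=07:30 and hst=23:30 gives -15.0 h.
    """
    label = _normalise_label(epoch_label)
    if label in EVENING_EPOCHS:
        return EVENING_EPOCHS[label]
    if label not in MORNING_EPOCHS:
        raise ValueError(f"unknown epoch label: {epoch_label!r}")
    hwt = parse_clock(hwt_clock)
    hst = parse_clock(hst_clock)
    span = (hst - hwt) % 24.0  # wake-to-sleep span
    if span <= 0.0 or span >= 24.0 or math.isclose(span, 0.0):
        raise ValueError(
            f"habitual wake must precede sleep within one day (span={span:g} h)"
        )
    return -span + MORNING_EPOCHS[label]


def to_clock_time(t_rel: float, hst_clock: str | float) -> str:
    """Convert hours relative to HST into a standard ``HH:MM`` clock time."""
    if not math.isfinite(t_rel):
        raise ValueError("t_rel must be finite")
    return format_clock(parse_clock(hst_clock) + t_rel)


def derive_vcd(al: float, acd: float, lt: float, rt_um: float) -> float:
    """Vitreous chamber depth in mm: AL minus (ACD + LT + RT).

    Retinal thickness is supplied in micrometres, as stored, and converted
    to mm here.
    """
    vcd = al - (acd + lt + rt_um / 1000.0)
    if vcd <= 0:
        raise ValueError(
            f"implausible biometry: VCD = {vcd:.3f} mm from "
            f"AL={al}, ACD={acd}, LT={lt}, RT={rt_um} um"
        )
    return vcd


def compute_ser(sphere: float, cylinder: float) -> float:
    """Spherical equivalent refraction in diopters: sphere + cylinder / 2."""
    return sphere + cylinder / 2.0


def classify_ser(ser: float) -> str:
    """Refractive group: myopia (SER <= -0.50 D), hyperopia (>= +0.50 D),
    emmetropia in between."""
    if ser <= -0.50:
        return "myopia"
    if ser >= 0.50:
        return "hyperopia"
    return "emmetropia"


@dataclass
class ParticipantProfile:
    id: str
    sex: str = "unknown"  # {M, F, unknown}
    age: float = float("nan")
    hst_clock: str = "00:00"
    hwt_clock: str = "08:00"
    sphere: float = 0.0
    cylinder: float = 0.0

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F", "unknown"):
            raise ValueError(f"sex must be M/F/unknown, got {self.sex!r}")
        parse_clock(self.hst_clock)
        parse_clock(self.hwt_clock)
        if not (math.isnan(self.age) or self.age > 0):
            raise ValueError("age must be positive")

    @property
    def ser(self) -> float:
        return compute_ser(self.sphere, self.cylinder)


PARTICIPANT_COLUMNS = ["id", "sex", "age", "hst_clock", "hwt_clock", "sphere", "cylinder"]
MEASUREMENT_COLUMNS = ["participant_id", "season", "epoch_label", "t_rel", "parameter", "value"]
_KEY = ["participant_id", "season", "epoch_label", "parameter"]


@dataclass
class CohortTable:
    """Validated cohort: a participant table plus a tidy measurement table."""

    participants: pd.DataFrame
    measurements: pd.DataFrame
    validated: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if not self.validated:
            self.validate()

    def validate(self) -> "CohortTable":
        p, m = self.participants, self.measurements
        missing = set(PARTICIPANT_COLUMNS) - set(p.columns)
        if missing:
            raise CohortValidationError(f"participants table missing columns {sorted(missing)}")
        missing = set(MEASUREMENT_COLUMNS) - set(m.columns)
        if missing:
            raise CohortValidationError(f"measurements table missing columns {sorted(missing)}")
        if p["id"].duplicated().any():
            dup = p.loc[p["id"].duplicated(), "id"].iloc[0]
            raise CohortValidationError(f"duplicate participant id {dup!r}")
        for _, row in p.iterrows():
            ParticipantProfile(
                id=str(row["id"]), sex=str(row["sex"]), age=float(row["age"]),
                hst_clock=row["hst_clock"], hwt_clock=row["hwt_clock"],
                sphere=float(row["sphere"]), cylinder=float(row["cylinder"]),
            )
        m = m.copy()
        m["epoch_label"] = m["epoch_label"].map(_normalise_label)
        bad = ~m["parameter"].isin(PARAMETERS)
        if bad.any():
            i = m.index[bad][0]
            raise CohortValidationError(f"row {i}: unknown parameter {m.loc[i, 'parameter']!r}")
        bad = ~m["epoch_label"].isin(EPOCH_LABELS)
        if bad.any():
            i = m.index[bad][0]
            raise CohortValidationError(f"row {i}: unknown epoch label {m.loc[i, 'epoch_label']!r}")
        bad = ~m["season"].isin(SEASONS)
        if bad.any():
            i = m.index[bad][0]
            raise CohortValidationError(f"row {i}: unknown season {m.loc[i, 'season']!r}")
        orphan = ~m["participant_id"].isin(set(p["id"]))
        if orphan.any():
            i = m.index[orphan][0]
            raise CohortValidationError(
                f"row {i}: measurement references unknown participant "
                f"{m.loc[i, 'participant_id']!r}"
            )
        dup = m.duplicated(subset=_KEY)
        if dup.any():
            i = m.index[dup][0]
            raise CohortValidationError(
                f"row {i}: duplicate key {tuple(m.loc[i, _KEY])}"
            )
        t = m["t_rel"].astype(float)
        bad = (t < -24.0) | (t > 2.0) | ~t.map(math.isfinite)
        if bad.any():
            i = m.index[bad][0]
            raise CohortValidationError(f"row {i}: t_rel {m.loc[i, 't_rel']} outside [-24, +2]")
        evening = m["epoch_label"].isin(EVENING_EPOCHS)
        expected = m.loc[evening, "epoch_label"].map(EVENING_EPOCHS)
        mismatch = (t[evening] - expected).abs() > 1e-9
        if mismatch.any():
            i = mismatch.index[mismatch][0]
            raise CohortValidationError(
                f"row {i}: evening epoch {m.loc[i, 'epoch_label']} requires "
                f"t_rel {expected[i]}, got {m.loc[i, 't_rel']}"
            )
        mel = m["parameter"] == "MEL"
        if (m.loc[mel, "value"].astype(float) <= 0).any():
            i = m.index[mel & (m["value"].astype(float) <= 0)][0]
            raise CohortValidationError(f"row {i}: MEL value must be positive")
        self.measurements = m
        self.validated = True
        return self

    def slice(self, parameter: str, season: str) -> pd.DataFrame:
        """Measurements of one parameter in one season."""
        m = self.measurements
        return m[(m["parameter"] == parameter) & (m["season"] == season)].copy()


def _paths(path: str) -> tuple[str, str]:
    if os.path.isdir(path):
        return (os.path.join(path, "participants.csv"), os.path.join(path, "measurements.csv"))
    raise ValueError(f"{path!r} is not a directory")


def read_cohort(path: str) -> CohortTable:
    """Read and validate a cohort from ``participants.csv`` and
    ``measurements.csv`` in the given directory."""
    p_path, m_path = _paths(path)
    try:
        participants = pd.read_csv(p_path, dtype={"id": str, "hst_clock": str, "hwt_clock": str})
        measurements = pd.read_csv(m_path, dtype={"participant_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CohortValidationError(f"malformed CSV under {path}: {exc}") from exc
    return CohortTable(participants, measurements)


def write_cohort(cohort: CohortTable, path: str) -> None:
    """Write a cohort to ``participants.csv`` / ``measurements.csv``."""
    os.makedirs(path, exist_ok=True)
    cohort.participants[PARTICIPANT_COLUMNS].to_csv(
        os.path.join(path, "participants.csv"), index=False)
    cohort.measurements[MEASUREMENT_COLUMNS].to_csv(
        os.path.join(path, "measurements.csv"), index=False)


def epoch_labels_for(parameter: str) -> tuple[str, ...]:
    """The epochs at which a parameter is actually sampled."""
    return MEL_EPOCH_LABELS if parameter == "MEL" else EPOCH_LABELS


def epoch_schedule(profile: ParticipantProfile | None = None,
                   hwt_clock: str | float = "08:00",
                   hst_clock: str | float = "00:00") -> dict[str, float]:
    """Map every epoch label to its time relative to HST for one participant."""
    if profile is not None:
        hwt_clock, hst_clock = profile.hwt_clock, profile.hst_clock
    return {lab: epoch_time(lab, hwt_clock, hst_clock) for lab in EPOCH_LABELS}
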