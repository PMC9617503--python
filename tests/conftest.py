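import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from oculorhythm.cosinor import CosinorFit, polar_to_coeffs

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_fit(mesor: float, amplitude: float, acrophase: float,
             log_scale: bool = False, **meta) -> CosinorFit:
    """Construct a CosinorFit directly from polar parameters."""
    bs, bc = polar_to_coeffs(amplitude, acrophase)
    return CosinorFit(mesor=mesor, amplitude=amplitude, acrophase=acrophase,
                      beta_sin=bs, beta_cos=bc, log_scale=log_scale, **meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def tiny_cohort_frames():
    """Two participants, one season, two parameters; hand-written values."""
    participants = pd.DataFrame({
        "id": ["A", "B"],
        "sex": ["F", "M"],
        "age": [20.0, 22.0],
        "hst_clock": ["23:30", "00:15"],
        "hwt_clock": ["07:30", "08:15"],
        "sphere": [-1.0, 0.5],
        "cylinder": [-0.5, 0.0],
    })
    rows = []
    for pid in ("A", "B"):
        for lab, t in (("HST-4", -4.0), ("HST-2", -2.0), ("HST+0", 0.0), ("HST+1", 1.0)):
            rows.append((pid, "W1", lab, t, "AL", 23.9 + 0.01 * t))
            rows.append((pid, "W1", lab, t, "MEL", 5.0 + t + 5.0))
    measurements = pd.DataFrame(
        rows, columns=["participant_id", "season", "epoch_label", "t_rel",
                       "parameter", "value"])
    return participants, measurements
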