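import numpy as np
import pandas as pd
import pytest

from telebp import LightDarkSchedule, SimConfig, make_strain_preset
from telebp.beats import BeatSeries
from telebp.wavegen import StrainPreset

LIGHT_START = pd.Timestamp("2013-06-01 08:30:00")  # mid-light, no transitions nearby


@pytest.fixture
def wky() -> StrainPreset:
    return make_strain_preset("WKY")


@pytest.fixture
def quiet_preset() -> StrainPreset:
    """Deterministic preset: no oscillations, no noise, no circadian dip."""
    return StrainPreset(
        name="quiet",
        map_dark=100.0,
        map_light=100.0,
        hr_dark=360.0,
        hr_light=360.0,
        lf_amp=0.0,
        hf_amp=0.0,
        brg_true=0.0,
        noise_sd=0.0,
        pi_noise_sd=0.0,
        activity_coupling=0.0,
    )


@pytest.fixture
def light_config():
    """Config factory anchored mid-light period (stationary segment)."""

    def make(duration_hours=1.0, seed=0, **kw):
        return SimConfig(
            duration_hours=duration_hours, seed=seed, start=LIGHT_START, **kw
        )

    return make


def beats_from_arrays(sbp, pi_ms, dt_s=0.175, map_=None, dbp=None) -> BeatSeries:
    """Build a BeatSeries directly from SBP / pulse-interval arrays."""
    sbp = np.asarray(sbp, dtype=float)
    pi = np.asarray(pi_ms, dtype=float)
    n = sbp.size
    t = np.arange(n) * dt_s
    m = np.asarray(map_, dtype=float) if map_ is not None else sbp - 20.0
    d = np.asarray(dbp, dtype=float) if dbp is not None else sbp - 40.0
    return BeatSeries(
        pd.DataFrame(
            {
                "systolic_time_s": t,
                "sbp": sbp,
                "dbp": d,
                "map": m,
                "pulse_interval_ms": pi,
            }
        )
    )


@pytest.fixture
def schedule() -> LightDarkSchedule:
    return LightDarkSchedule()
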