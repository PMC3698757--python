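"""Synthetic arterial-pressure telemetry with known ground truth.

The generator emulates the signal a chronically implanted aortic catheter
produces in WKY, SHR and SHRcp rats: a pulsatile pressure wave whose per-beat
baseline follows the strain's circadian MAP profile, a low-frequency
"Mayer-wave" oscillation of systolic pressure inside 0.27-0.75 Hz, a
high-frequency respiratory oscillation inside 0.75-3.3 Hz, baroreflex coupling
of the pulse interval to systolic pressure with a settable gain (ms/mmHg),
locomotor-activity-linked noise, and an optional once-daily dose-escalating
drug effect.

Design of the beat model
------------------------
Each beat is an asymmetric raised-cosine pulse: a fast half-cosine upstroke of
fixed duration (50 ms) followed by a slow half-cosine decay filling the rest
of the pulse interval. Both halves average to ``MAP`` analytically, so the
per-beat mean pressure equals the injected baseline exactly, and the systolic
peak sits at a fixed offset from beat onset, so peak-to-peak intervals equal
the generated pulse intervals exactly. Systolic modulation (LF + HF sinusoids)
is carried by the pulse pressure, leaving the per-beat mean untouched:

    SBP_i = MAP_i + PP/2 + s_i,        s_i = LF_i + HF_i
    PI_i  = PI0(t) + G * (SBP_i - (MAP_base(t) + PP/2)) + e_i

where ``G`` is the true baroreflex gain in ms/mmHg (higher systolic pressure
-> longer interval, i.e. reflex bradycardia; the reported gain is positive)
and ``e_i`` a small residual pulse-interval noise. In the noise-free limit the
sequence method recovers ``G`` exactly.

The dark/light MAP levels of the three named presets are the published group
means for these strains; heart rates, pulse pressures, oscillation amplitudes,
gains and noise levels are free parameters of the generator (no published
values exist) and are documented as such in ``docs/methods.md``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace, asdict

import numba
import numpy as np
import pandas as pd

from .beats import BeatSeries, Waveform
from .errors import ConfigError, UnknownPresetError
from .schedule import LightDarkSchedule

log = logging.getLogger(__name__)

LF_BAND = (0.27, 0.75)
HF_BAND = (0.75, 3.3)

# Systolic upstroke duration (s). Kept short enough that the upstroke never
# exceeds a third of the pulse interval at physiologic rat heart rates, so the
# peak offset from beat onset stays constant and peak-to-peak intervals equal
# the generated pulse intervals exactly.
RISE_S = 0.050
TRANSITION_RAMP_S = 30.0 * 60.0  # half-cosine light<->dark ramp


# ----------------------------------------------------------------------
# presets
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class StrainPreset:
    """Generator parameters for one rat strain.

    ``map_dark``/``map_light`` for the named presets are the published 12-h
    group means; everything else is a generator free parameter.
    """

    name: str
    map_dark: float
    map_light: float
    pulse_pressure: float = 35.0
    hr_dark: float = 340.0
    hr_light: float = 310.0
    lf_amp: float = 3.0  # mmHg SBP oscillation amplitude
    lf_freq: float = 0.40  # Hz, inside the LF band
    hf_amp: float = 2.0
    hf_freq: float = 1.50  # Hz, inside the HF band
    brg_true: float = 1.6  # ms/mmHg
    noise_sd: float = 1.0  # mmHg beat-to-beat MAP noise
    pi_noise_sd: float = 0.5  # ms residual pulse-interval noise
    day_sd: float = 0.0  # mmHg day-to-day wander of each 12-h period mean
    activity_dark: float = 8.0  # counts per 5-min epoch
    activity_light: float = 3.0
    activity_coupling: float = 0.5  # mmHg extra noise SD per unit relative activity

    def __post_init__(self) -> None:
        if not LF_BAND[0] < self.lf_freq < LF_BAND[1]:
            raise ConfigError(f"lf_freq must lie strictly inside {LF_BAND}")
        if not HF_BAND[0] < self.hf_freq < HF_BAND[1]:
            raise ConfigError(f"hf_freq must lie strictly inside {HF_BAND}")
        for name in (
            "map_dark",
            "map_light",
            "pulse_pressure",
            "lf_amp",
            "hf_amp",
            "brg_true",
            "noise_sd",
            "pi_noise_sd",
            "day_sd",
            "activity_dark",
            "activity_light",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for hr in (self.hr_dark, self.hr_light):
            if not 200.0 <= hr <= 500.0:
                raise ConfigError("heart rate outside the physiologic 200-500 bpm range")


# Published 12-h dark/light MAP means (mmHg) for the three strains; all other
# fields are generator free parameters. SHRcp: lower baroreflex gain and
# higher LF amplitude than WKY (direction only is constrained by the study).
_PRESETS: dict[str, StrainPreset] = {
    "WKY": StrainPreset(
        name="WKY", map_dark=102.1, map_light=94.4, pulse_pressure=35.0,
        hr_dark=340.0, hr_light=310.0, lf_amp=3.0, brg_true=1.6,
        activity_dark=8.0, activity_light=3.0,
    ),
    "SHR": StrainPreset(
        name="SHR", map_dark=142.0, map_light=134.8, pulse_pressure=45.0,
        hr_dark=330.0, hr_light=300.0, lf_amp=3.5, brg_true=1.2,
        activity_dark=6.0, activity_light=2.5,
    ),
    "SHRcp": StrainPreset(
        name="SHRcp", map_dark=133.4, map_light=131.7, pulse_pressure=45.0,
        hr_dark=320.0, hr_light=295.0, lf_amp=5.0, brg_true=0.8,
        activity_dark=4.0, activity_light=2.5,
    ),
}


def register_preset(preset: StrainPreset) -> None:
    """Register a custom strain preset under ``preset.name``."""
    _PRESETS[preset.name] = preset


def make_strain_preset(name: str) -> StrainPreset:
    """Return the registered preset for ``name`` (WKY, SHR, SHRcp or custom)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise UnknownPresetError(
            f"unknown strain preset {name!r}; known: {sorted(_PRESETS)}"
        ) from None


# ----------------------------------------------------------------------
# drug schedule
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class DrugSchedule:
    """Once-daily oral dosing at dark onset with weekly dose escalation.

    ``dose_by_week`` maps treatment-week index (0-based) to dose in mg/kg;
    the default is the 0.1 / 0.3 / 1.0 mg/kg weekly ladder. Effects are free
    parameters: ``effect_map`` maps dose to (dark, light) MAP reduction in
    mmHg, ``effect_brg`` to an additive gain change in ms/mmHg and
    ``effect_lf`` to a multiplicative LF-amplitude factor. A zero dose has
    identically zero effect. The effect is a sustained constant offset from
    each dose to the next (``decay_tau_h`` switches on an optional
    exponential-decay mode).
    """

    dose_by_week: tuple = ((0, 0.1), (1, 0.3), (2, 1.0))
    dosing_clock_hour: float = 20.0
    treatment_start_day: int = 0
    effect_map: tuple = ((0.1, (2.0, 2.0)), (0.3, (6.0, 6.0)), (1.0, (15.0, 15.0)))
    effect_brg: tuple = ((0.1, 0.05), (0.3, 0.15), (1.0, 0.5))
    effect_lf: tuple = ((0.1, 0.95), (0.3, 0.85), (1.0, 0.65))
    washout_weeks: int = 0
    decay_tau_h: float | None = None

    def __post_init__(self) -> None:
        if any(d < 0 for _, d in self.dose_by_week):
            raise ConfigError("doses must be >= 0")

    def dose_on_day(self, day: int) -> float:
        """Dose (mg/kg) administered at the dark onset opening analysis day ``day``."""
        if day < self.treatment_start_day:
            return 0.0
        week = (day - self.treatment_start_day) // 7
        for w, dose in self.dose_by_week:
            if w == week:
                return dose
        return 0.0  # washout / beyond schedule

    def _lookup(self, table, dose, zero):
        if dose == 0.0:
            return zero
        for d, v in table:
            if d == dose:
                return v
        raise ConfigError(f"no effect registered for dose {dose}")

    def map_reduction(self, dose: float) -> tuple[float, float]:
        return self._lookup(self.effect_map, dose, (0.0, 0.0))

    def brg_change(self, dose: float) -> float:
        return self._lookup(self.effect_brg, dose, 0.0)

    def lf_factor(self, dose: float) -> float:
        return self._lookup(self.effect_lf, dose, 1.0)


# ----------------------------------------------------------------------
# simulation config / cohort jitter
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Acquisition settings for a simulated recording."""

    sample_rate: float = 200.0
    duration_hours: float = 24.0
    start: pd.Timestamp = pd.Timestamp("2013-06-01 20:00:00")
    schedule: LightDarkSchedule = field(default_factory=LightDarkSchedule)
    seed: int = 0
    n_animals: int = 1

    def __post_init__(self) -> None:
        if self.duration_hours < 1.0:
            raise ConfigError("duration must be at least 1 hour")
        if self.n_animals < 1:
            raise ConfigError("n_animals must be >= 1")
        object.__setattr__(self, "start", pd.Timestamp(self.start))

    def validate_against(self, preset: StrainPreset) -> None:
        if self.sample_rate < 4.0 * preset.hf_freq:
            raise ConfigError(
                f"sample_rate {self.sample_rate} Hz violates the Nyquist margin "
                f"(need >= 4 x hf_freq = {4 * preset.hf_freq} Hz)"
            )


@dataclass(frozen=True)
class CohortJitter:
    """Between-animal variability applied by :func:`simulate_cohort`.

    ``level_sd`` shifts an animal's dark and light MAP together (between-animal
    pressure level); ``period_sd`` perturbs each period mean independently, so
    it is the component that makes the dark-light dip vary between animals.
    ``hr_sd`` shifts both heart rates; ``gain_frac_sd`` scales the baroreflex
    gain multiplicatively; ``day_sd`` sets each animal's day-to-day wander of
    the 12-h period means. Defaults are small calibration-level values so a
    default cohort stays tight around the preset means.
    """

    level_sd: float = 0.5
    period_sd: float = 0.3
    hr_sd: float = 8.0
    gain_frac_sd: float = 0.05
    day_sd: float = 0.0


def sem_matched_jitter() -> CohortJitter:
    """Between-animal variability matched to the published group SEMs.

    The printed 12-h MAP SEMs (0.7-1.3 mmHg at n=5) imply per-animal SDs of
    roughly 1.6-2.9 mmHg. This profile decomposes that into a 1.0 mmHg shared
    level shift, a 1.0 mmHg period-specific animal component, and a 2.4 mmHg
    day-to-day wander of each 12-h period mean: over a multi-day recording the
    per-animal SD of a period mean is sqrt(1 + 1 + 2.4^2/days), i.e. ~1.8 at
    5 days, inside the published range. This is the realistic-variability
    condition used for the dipper-classification study.
    """
    return CohortJitter(
        level_sd=1.0, period_sd=1.0, hr_sd=12.0, gain_frac_sd=0.10, day_sd=2.4
    )


# ----------------------------------------------------------------------
# ground truth
# ----------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Everything needed to score recovery without re-reading the config.

    ``animals`` holds one record per animal: the realized preset parameters
    (after cohort jitter), the seed, and realized per-period target means of
    MAP and HR computed from the generated beat table.
    """

    animals: list = field(default_factory=list)
    config: dict = field(default_factory=dict)
    schedule_info: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "drug_schedule": self.schedule_info,
            "animals": self.animals,
        }

    def realized_period_mean(self, period: str, field_: str = "map") -> float:
        """Cohort mean of the realized per-animal period means."""
        vals = [a["realized"][f"{field_}_{period}"] for a in self.animals]
        return float(np.mean(vals))


# ----------------------------------------------------------------------
# beat-table generation
# ----------------------------------------------------------------------


def _activity_epochs(preset, config, rng):
    """Per-5-min locomotor activity counts (gamma-distributed around the period mean)."""
    n_epochs = int(np.ceil(config.duration_hours * 12)) + 1
    t_epoch = np.arange(n_epochs) * 300.0
    w = config.schedule.dark_weight(config.start, t_epoch)
    mean = preset.activity_light + (preset.activity_dark - preset.activity_light) * w
    shape = 2.0
    counts = rng.gamma(shape, np.maximum(mean, 1e-9) / shape)
    return counts


def _generate_beats(preset, config, schedule_drug, rng, delay_beats: int = 0):
    """Sequential beat-table generation.

    Beat onset times follow the exact recursion t[i+1] = t[i] + PI_i/1000,
    with every baseline and modulation evaluated at the realized onset times.
    All noise is drawn up front from ``rng`` (fixed per beat index), and the
    per-beat recursion runs in a compiled kernel.
    """
    config.validate_against(preset)
    sched = config.schedule
    dur_s = config.duration_hours * 3600.0
    pi_min_s = 60.0 / max(preset.hr_dark, preset.hr_light) * 0.8
    n_max = int(np.ceil(dur_s / pi_min_s)) + 8

    eps_map = rng.normal(0.0, 1.0, n_max)
    eps_act = rng.normal(0.0, 1.0, n_max)
    eps_pi = rng.normal(0.0, 1.0, n_max)
    activity = _activity_epochs(preset, config, rng)

    # day-to-day wander of each 12-h period mean (one offset per day x period)
    start_h = (config.start - config.start.normalize()).total_seconds() / 3600.0
    back_s = ((start_h - sched.dark_onset_hour) % 24.0) * 3600.0
    n_days = int(np.ceil((dur_s + back_s) / 86400.0)) + 1
    day_off_dark = rng.normal(0.0, preset.day_sd, n_days)
    day_off_light = rng.normal(0.0, preset.day_sd, n_days)

    # per-day drug effects (constant from each dose to the next)
    red_dark = np.zeros(n_days)
    red_light = np.zeros(n_days)
    lf_fac = np.ones(n_days)
    brg_add = np.zeros(n_days)
    decay_tau_s = 0.0
    if schedule_drug is not None:
        for day in range(n_days):
            dose = schedule_drug.dose_on_day(day)
            if dose == 0.0:
                continue
            red_dark[day], red_light[day] = schedule_drug.map_reduction(dose)
            lf_fac[day] = schedule_drug.lf_factor(dose)
            brg_add[day] = schedule_drug.brg_change(dose)
        if schedule_drug.decay_tau_h is not None:
            decay_tau_s = schedule_drug.decay_tau_h * 3600.0

    onset = np.empty(n_max)
    map_i = np.empty(n_max)
    sbp = np.empty(n_max)
    pi_ms = np.empty(n_max)
    map_base = np.empty(n_max)
    hr_base = np.empty(n_max)
    n = _beat_kernel(
        dur_s,
        back_s,
        sched.dark_hours * 3600.0,
        TRANSITION_RAMP_S,
        preset.map_dark, preset.map_light,
        preset.hr_dark, preset.hr_light,
        preset.pulse_pressure,
        preset.lf_amp, preset.lf_freq, preset.hf_amp, preset.hf_freq,
        preset.brg_true, preset.noise_sd, preset.pi_noise_sd,
        preset.activity_coupling, max(preset.activity_dark, 1e-9),
        int(delay_beats),
        eps_map, eps_act, eps_pi, activity,
        day_off_dark, day_off_light,
        red_dark, red_light, lf_fac, brg_add, decay_tau_s,
        onset, map_i, sbp, pi_ms, map_base, hr_base,
    )

    s_mod = sbp[:n] - map_i[:n] - preset.pulse_pressure / 2.0
    pp_i = preset.pulse_pressure + 2.0 * s_mod
    if np.any(pp_i <= 0):
        log.warning("clipping %d non-positive pulse pressures", int((pp_i <= 0).sum()))
        pp_i = np.maximum(pp_i, 1.0)
    table = pd.DataFrame(
        {
            "onset_s": onset[:n],
            "pulse_interval_ms": pi_ms[:n],
            "map": map_i[:n],
            "sbp": map_i[:n] + pp_i / 2.0,
            "dbp": map_i[:n] - pp_i / 2.0,
            "map_base": map_base[:n],
            "hr_base": hr_base[:n],
        }
    )
    table["systolic_time_s"] = table["onset_s"] + np.minimum(
        RISE_S, table["pulse_interval_ms"] / 1000.0 / 3.0
    )
    return table


@numba.njit(cache=False)
def _beat_kernel(
    dur_s, back_s, dark_s, ramp_s,
    map_dark, map_light, hr_dark, hr_light, pp,
    lf_amp, lf_freq, hf_amp, hf_freq,
    brg, noise_sd, pi_noise_sd, act_coupling, act_dark,
    delay,
    eps_map, eps_act, eps_pi, activity,
    day_off_dark, day_off_light,
    red_dark, red_light, lf_fac, brg_add, decay_tau_s,
    onset, map_i, sbp, pi_ms, map_base, hr_base,
):  # pragma: no cover - exercised through _generate_beats
    n_max = onset.shape[0]
    n_days = day_off_dark.shape[0]
    n_epochs = activity.shape[0]
    half = ramp_s / 2.0
    two_pi = 2.0 * np.pi
    t = 0.0
    i = 0
    while i < n_max:
        rel = (t + back_s) % 86400.0
        # dark weight with half-cosine ramps at both transitions
        w = 1.0 if rel < dark_s else 0.0
        d_on = rel if rel < 43200.0 else 86400.0 - rel
        if d_on < half:
            sgn = 1.0 if rel < 43200.0 else -1.0
            w = 0.5 * (1.0 + np.sin(np.pi * sgn * d_on / ramp_s))
        else:
            d_off = rel - dark_s if rel > dark_s else dark_s - rel
            if d_off < half:
                sgn = 1.0 if rel > dark_s else -1.0
                w = 0.5 * (1.0 - np.sin(np.pi * sgn * d_off / ramp_s))
        day = int((t + back_s) // 86400.0)
        if day >= n_days:
            day = n_days - 1
        red = w * red_dark[day] + (1.0 - w) * red_light[day]
        if decay_tau_s > 0.0 and red != 0.0:
            day_start = day * 86400.0 - back_s
            red *= np.exp(-(t - day_start) / decay_tau_s)
        m_b = (
            map_light
            + (map_dark - map_light) * w
            + w * day_off_dark[day]
            + (1.0 - w) * day_off_light[day]
            - red
        )
        h_b = hr_light + (hr_dark - hr_light) * w
        s = lf_amp * lf_fac[day] * np.sin(two_pi * lf_freq * t) + hf_amp * np.sin(
            two_pi * hf_freq * t
        )
        epoch = int(t // 300.0)
        if epoch >= n_epochs:
            epoch = n_epochs - 1
        act_sd = act_coupling * activity[epoch] / act_dark
        m = m_b + noise_sd * eps_map[i] + act_sd * eps_act[i]
        sb = m + pp / 2.0 + s
        j = i - delay
        drive = (sbp[j] - (map_base[j] + pp / 2.0)) if delay > 0 and j >= 0 else (
            sb - (m_b + pp / 2.0)
        )
        if delay > 0 and j < 0:
            drive = 0.0
        pi = 60000.0 / h_b + (brg + brg_add[day]) * drive + pi_noise_sd * eps_pi[i]
        if pi < 100.0:
            pi = 100.0
        if t + pi / 1000.0 > dur_s:
            break
        onset[i] = t
        map_i[i] = m
        sbp[i] = sb
        pi_ms[i] = pi
        map_base[i] = m_b
        hr_base[i] = h_b
        t += pi / 1000.0
        i += 1
    return i


def _realized_means(table, config):
    """Time-weighted per-period means of the injected beat MAP and HR."""
    periods = config.schedule.day_periods(config.start, config.duration_hours * 3600.0)
    t = table["systolic_time_s"].to_numpy()
    out = {}
    for period in ("dark", "light"):
        sel = np.zeros(t.size, dtype=bool)
        for _, row in periods.loc[periods["period"] == period].iterrows():
            sel |= (t >= row["start_s"]) & (t < row["end_s"])
        if sel.any():
            wgt = table["pulse_interval_ms"].to_numpy()[sel]
            out[f"map_{period}"] = float(
                np.average(table["map"].to_numpy()[sel], weights=wgt)
            )
            out[f"hr_{period}"] = float(
                60000.0 / np.average(table["pulse_interval_ms"].to_numpy()[sel])
            )
    return out


def _render_waveform(table, config, animal):
    """Render the beat table to a sampled pressure trace (chunked)."""
    fs = config.sample_rate
    n_samples = int(round(config.duration_hours * 3600.0 * fs))
    onset = table["onset_s"].to_numpy()
    pi_s = table["pulse_interval_ms"].to_numpy() / 1000.0
    dbp = table["dbp"].to_numpy()
    pp = (table["sbp"] - table["dbp"]).to_numpy()
    rise = np.minimum(RISE_S, pi_s / 3.0)

    samples = np.empty(n_samples)
    chunk = int(3600 * fs)  # 1-h blocks
    end_t = onset[-1] + pi_s[-1]
    for lo in range(0, n_samples, chunk):
        hi = min(lo + chunk, n_samples)
        ts = np.arange(lo, hi) / fs
        j = np.clip(np.searchsorted(onset, ts, side="right") - 1, 0, onset.size - 1)
        tau = ts - onset[j]
        tau = np.clip(tau, 0.0, pi_s[j])  # samples past the last beat hold its shape
        r = rise[j]
        up = 0.5 * (1.0 - np.cos(np.pi * np.minimum(tau, r) / r))
        down = 0.5 * (1.0 + np.cos(np.pi * (tau - r) / np.maximum(pi_s[j] - r, 1e-9)))
        p = dbp[j] + pp[j] * np.where(tau < r, up, down)
        p[ts >= end_t] = dbp[-1]
        samples[lo:hi] = p
    n_neg = int((samples < 0).sum())
    if n_neg:
        log.warning("clipping %d negative pressure samples", n_neg)
        np.clip(samples, 0.0, None, out=samples)
    return Waveform(
        samples,
        sample_rate=fs,
        start=config.start,
        schedule=config.schedule,
        animal=animal,
    )


def _truth_record(preset, config, table, seed, animal):
    return {
        "animal": animal,
        "seed": int(seed),
        "preset": asdict(preset),
        "realized": _realized_means(table, config),
        "n_beats": int(len(table)),
    }


def _beats_from_table(table, config, animal):
    df = table[["systolic_time_s", "sbp", "dbp", "map", "pulse_interval_ms"]].copy()
    df = df.reset_index(drop=True)
    return BeatSeries(
        df, start=config.start, schedule=config.schedule, animal=animal
    )


# ----------------------------------------------------------------------
# public entry points
# ----------------------------------------------------------------------


def simulate_waveform(
    preset: StrainPreset,
    config: SimConfig,
    schedule: DrugSchedule | None = None,
    animal: str = "animal-0",
    delay_beats: int = 0,
) -> tuple[Waveform, GroundTruth]:
    """Simulate one animal's sampled pressure trace plus its ground truth.

    ``delay_beats`` is the beat lag of the baroreflex pulse-interval response.
    Identical ``config.seed`` gives bit-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    table = _generate_beats(preset, config, schedule, rng, delay_beats=delay_beats)
    wf = _render_waveform(table, config, animal)
    gt = GroundTruth(
        animals=[_truth_record(preset, config, table, config.seed, animal)],
        config=_config_dict(config),
        schedule_info=_drug_dict(schedule),
    )
    return wf, gt


def simulate_beats(
    preset: StrainPreset,
    config: SimConfig,
    schedule: DrugSchedule | None = None,
    animal: str = "animal-0",
    delay_beats: int = 0,
) -> tuple[BeatSeries, GroundTruth]:
    """Generate the per-beat series directly, skipping waveform rendering.

    The beat table is the same one :func:`simulate_waveform` renders; this
    path is for cohort-scale experiments whose methods operate on beat series.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    table = _generate_beats(preset, config, schedule, rng, delay_beats=delay_beats)
    gt = GroundTruth(
        animals=[_truth_record(preset, config, table, config.seed, animal)],
        config=_config_dict(config),
        schedule_info=_drug_dict(schedule),
    )
    return _beats_from_table(table, config, animal), gt


def simulate_cohort(
    presets,
    config: SimConfig,
    schedule: DrugSchedule | None = None,
    jitter: CohortJitter | None = None,
    render: str = "waveform",
) -> tuple[list, GroundTruth]:
    """Simulate ``config.n_animals`` independent animals per preset.

    Per-animal seeds are spawned deterministically from the master seed
    (``numpy.random.SeedSequence`` children), and each animal's preset is
    jittered around the group means per ``jitter`` (see :class:`CohortJitter`).
    Returns one Waveform (``render='waveform'``) or BeatSeries
    (``render='beats'``) per animal, in preset-major order, plus a single
    GroundTruth covering the cohort.
    """
    presets = list(presets)
    if not presets:
        raise ConfigError("empty preset list")
    if render not in ("waveform", "beats"):
        raise ConfigError("render must be 'waveform' or 'beats'")
    jitter = jitter if jitter is not None else CohortJitter()
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(len(presets) * config.n_animals)
    out = []
    gt = GroundTruth(config=_config_dict(config), schedule_info=_drug_dict(schedule))
    k = 0
    for preset in presets:
        for i in range(config.n_animals):
            child = children[k]
            k += 1
            rng = np.random.default_rng(child)
            p_i = _jitter_preset(preset, jitter, rng)
            animal = f"{preset.name}-{i}"
            table = _generate_beats(p_i, config, schedule, rng)
            rec = _truth_record(p_i, config, table, config.seed, animal)
            rec["animal_index"] = i
            gt.animals.append(rec)
            if render == "waveform":
                out.append(_render_waveform(table, config, animal))
            else:
                out.append(_beats_from_table(table, config, animal))
    return out, gt


def _jitter_preset(preset, jitter, rng):
    level = rng.normal(0.0, jitter.level_sd)
    d_dark = rng.normal(0.0, jitter.period_sd)
    d_light = rng.normal(0.0, jitter.period_sd)
    hr = rng.normal(0.0, jitter.hr_sd)
    gain = preset.brg_true * float(
        np.clip(1.0 + rng.normal(0.0, jitter.gain_frac_sd), 0.2, 3.0)
    )
    return replace(
        preset,
        map_dark=preset.map_dark + level + d_dark,
        map_light=preset.map_light + level + d_light,
        hr_dark=float(np.clip(preset.hr_dark + hr, 200.0, 500.0)),
        hr_light=float(np.clip(preset.hr_light + hr, 200.0, 500.0)),
        brg_true=gain,
        day_sd=jitter.day_sd,
    )


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["start"] = str(config.start)
    d["schedule"] = asdict(config.schedule)
    return d


def _drug_dict(schedule) -> dict:
    if schedule is None:
        return {}
    return asdict(schedule)


# ----------------------------------------------------------------------
# grouped biomarker tables
# ----------------------------------------------------------------------


def make_biomarker_tables(
    cells: pd.DataFrame,
    n_per_cell: int,
    seed: int,
    subject_factors: list[str] | None = None,
    subject_sd: float = 0.0,
) -> pd.DataFrame:
    """Draw a long-format grouped table (strain x period x treatment style).

    ``cells`` has one row per design cell: arbitrary factor columns plus
    ``mean``, ``sd`` and optionally ``dist`` ('normal', the default, or
    'lognormal' — the variance-heterogeneous case that routes the statistical
    decision tree to its nonparametric branch). Lognormal cells are
    parameterised to reach the stated mean and SD.

    ``subject_factors`` lists within-subject factors: subjects are shared
    across their levels (enabling repeated-measures designs), with an optional
    per-subject random intercept of SD ``subject_sd``.
    """
    if n_per_cell < 2:
        raise ConfigError("n_per_cell must be >= 2")
    cells = cells.copy()
    if "dist" not in cells.columns:
        cells["dist"] = "normal"
    factor_cols = [c for c in cells.columns if c not in ("mean", "sd", "dist")]
    if not factor_cols:
        raise ConfigError("cells needs at least one factor column")
    subject_factors = subject_factors or []
    between = [c for c in factor_cols if c not in subject_factors]

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    # subject random intercepts, keyed by between-cell and replicate index
    intercepts: dict[tuple, float] = {}
    rows = []
    for _, cell in cells.iterrows():
        mean, sd, dist = float(cell["mean"]), float(cell["sd"]), str(cell["dist"])
        if dist == "normal":
            vals = rng.normal(mean, sd, n_per_cell)
        elif dist == "lognormal":
            if mean <= 0:
                raise ConfigError("lognormal cells need a positive mean")
            sigma2 = np.log1p((sd / mean) ** 2)
            mu = np.log(mean) - sigma2 / 2.0
            vals = rng.lognormal(mu, np.sqrt(sigma2), n_per_cell)
        else:
            raise ConfigError(f"unknown distribution {dist!r}")
        bkey = tuple(cell[c] for c in between)
        for i, v in enumerate(vals):
            skey = bkey + (i,)
            if skey not in intercepts:
                intercepts[skey] = rng.normal(0.0, subject_sd) if subject_sd > 0 else 0.0
            row = {c: cell[c] for c in factor_cols}
            row["animal"] = "-".join(str(x) for x in skey)
            row["value"] = v + intercepts[skey]
            rows.append(row)
    return pd.DataFrame(rows)
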