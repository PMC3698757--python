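"""Telemetry binning, 12-h dark/light summaries, dipper calls, dose response.

The acquisition convention is the telemetry vendor's: one bin every 5 minutes,
each holding the average of the first 30 seconds of the bin for MAP, HR and
locomotor activity. Twelve-hour period summaries average the valid bins of
each dark or light half of an analysis day (days are anchored at dark onset,
matching the dosing time in the drug studies).

A cohort or animal is a *dipper* when its light-period MAP is significantly
lower than its dark-period MAP in a paired per-day comparison (paired t when
the differences pass Shapiro-Wilk, Wilcoxon signed-rank otherwise) — the
statistical criterion, not the clinical 10 %-dip rule; the descriptive dip
percentage is reported either way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beats import BeatSeries
from .errors import DataError
from .stats import paired_compare

BIN_S = 300.0
SAMPLE_S = 30.0  # averaged portion at the head of each bin


@dataclass
class DipperCall:
    """Dipper/nondipper classification for one animal or cohort."""

    subject: str
    classification: str  # 'dipper' | 'nondipper'
    dark_mean: float
    light_mean: float
    p_value: float
    dip_percent: float
    test: str = ""
    n_pairs: int = 0


def bin_telemetry(
    beats: BeatSeries,
    activity=None,
    bin_s: float = BIN_S,
    sample_s: float = SAMPLE_S,
    min_beats: int = 3,
) -> pd.DataFrame:
    """Average beats into 5-min telemetry bins (30-s sampling window each).

    ``activity`` is an optional array of locomotor counts, one per bin. Bins
    whose sampling window holds fewer than ``min_beats`` beats are flagged
    invalid and carry NaN values. HR is ``60000 / mean pulse interval``.

    Returns columns ``bin_start`` (record-relative s), ``map``, ``hr``,
    ``activity``, ``n_beats``, ``valid``.
    """
    t = beats.df["systolic_time_s"].to_numpy()
    if t.size == 0:
        raise DataError("empty beat series")
    n_bins = int(t[-1] // bin_s) + 1
    idx = (t // bin_s).astype(int)
    offset = t - idx * bin_s
    in_window = offset < sample_s
    pi = beats.df["pulse_interval_ms"].to_numpy()
    map_ = beats.df["map"].to_numpy()
    usable = in_window & ~np.isnan(map_) & ~np.isnan(pi)

    sums_map = np.bincount(idx[usable], weights=map_[usable], minlength=n_bins)
    sums_pi = np.bincount(idx[usable], weights=pi[usable], minlength=n_bins)
    counts = np.bincount(idx[usable], minlength=n_bins)

    valid = counts >= min_beats
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_map = np.where(valid, sums_map / counts, np.nan)
        mean_hr = np.where(valid, 60000.0 / (sums_pi / counts), np.nan)
    act = np.full(n_bins, np.nan)
    if activity is not None:
        a = np.asarray(activity, dtype=float)
        act[: min(a.size, n_bins)] = a[:n_bins]
    return pd.DataFrame(
        {
            "bin_start": np.arange(n_bins) * bin_s,
            "map": mean_map,
            "hr": mean_hr,
            "activity": act,
            "n_beats": counts,
            "valid": valid,
        }
    )


def period_summary(
    bins: pd.DataFrame,
    schedule,
    start,
    animal: str = "animal-0",
) -> pd.DataFrame:
    """Unweighted mean of valid bins per animal-day-period.

    ``schedule`` is the :class:`~telebp.schedule.LightDarkSchedule` and
    ``start`` the wall-clock time of ``bin_start = 0``. A day is one dark
    period plus the following light period. Periods without a single valid
    bin yield no row (missing, not zero).
    """
    end_s = float(bins["bin_start"].max()) + BIN_S
    periods = schedule.day_periods(pd.Timestamp(start), end_s)
    t = bins["bin_start"].to_numpy()
    rows = []
    for _, w in periods.iterrows():
        sel = bins.loc[(t >= w["start_s"]) & (t < w["end_s"]) & bins["valid"]]
        if sel.empty:
            continue
        rows.append(
            {
                "animal": animal,
                "day": int(w["day"]),
                "period": w["period"],
                "mean_map": float(sel["map"].mean()),
                "mean_hr": float(sel["hr"].mean()),
                "mean_activity": float(sel["activity"].mean()),
                "n_bins": int(len(sel)),
            }
        )
    return pd.DataFrame(rows)


def classify_dipper(
    summaries: pd.DataFrame,
    alpha: float = 0.05,
    subject: str = "",
) -> DipperCall:
    """Classify a set of period summaries as dipper or nondipper.

    ``summaries`` holds matched dark/light rows; pairing is per (animal, day).
    At least 3 complete pairs are required. Classification is *dipper* iff the
    light-period mean is below the dark-period mean with p < alpha in the
    paired comparison; the dip percentage 100*(dark-light)/dark is descriptive.
    """
    wide = summaries.pivot_table(
        index=["animal", "day"], columns="period", values="mean_map"
    )
    if "dark" not in wide.columns or "light" not in wide.columns:
        raise DataError("need both dark and light period summaries")
    wide = wide.dropna(subset=["dark", "light"])
    if len(wide) < 3:
        raise DataError("need >= 3 paired day records for dipper classification")
    dark = wide["dark"].to_numpy()
    light = wide["light"].to_numpy()
    res = paired_compare(dark, light, alpha=alpha)  # effect = mean(light - dark)
    dark_mean = float(dark.mean())
    light_mean = float(light.mean())
    dip = 100.0 * (dark_mean - light_mean) / dark_mean if dark_mean else float("nan")
    is_dipper = light_mean < dark_mean and res.p_value < alpha
    return DipperCall(
        subject=subject or "/".join(sorted(summaries["animal"].unique())),
        classification="dipper" if is_dipper else "nondipper",
        dark_mean=dark_mean,
        light_mean=light_mean,
        p_value=float(res.p_value),
        dip_percent=float(dip),
        test=res.name,
        n_pairs=int(len(wide)),
    )


def classify_cohort_dipper(
    summaries: pd.DataFrame,
    alpha: float = 0.05,
    subject: str = "",
) -> tuple[DipperCall, list[DipperCall]]:
    """Cohort-level dipper call: majority vote over per-animal classifications.

    Each animal is classified from its own per-day dark/light pairs (so every
    animal needs >= 3 recorded days); the cohort is a dipper when a strict
    majority of its animals are. The returned cohort call carries the cohort
    mean dark/light MAP and the majority fraction in place of a p-value.
    """
    per_animal = []
    for animal, grp in summaries.groupby("animal"):
        per_animal.append(classify_dipper(grp, alpha=alpha, subject=str(animal)))
    if not per_animal:
        raise DataError("no animals to classify")
    votes = sum(c.classification == "dipper" for c in per_animal)
    frac = votes / len(per_animal)
    dark_mean = float(np.mean([c.dark_mean for c in per_animal]))
    light_mean = float(np.mean([c.light_mean for c in per_animal]))
    call = DipperCall(
        subject=subject or "cohort",
        classification="dipper" if votes > len(per_animal) / 2 else "nondipper",
        dark_mean=dark_mean,
        light_mean=light_mean,
        p_value=float(frac),
        dip_percent=100.0 * (dark_mean - light_mean) / dark_mean if dark_mean else float("nan"),
        test="majority of per-animal paired calls",
        n_pairs=len(per_animal),
    )
    return call, per_animal


def dose_response(
    baseline: pd.DataFrame,
    treated: pd.DataFrame,
    dose_by_day: dict,
    strain_of=None,
) -> pd.DataFrame:
    """Average change in 12-h MAP after 7 days at each dose.

    ``baseline`` and ``treated`` are period-summary frames; ``dose_by_day``
    maps analysis-day index -> dose (mg/kg). For every dose the *last* day
    carrying it (day 7 of its week) is compared against the animal's mean
    pre-treatment baseline for the same period:
    ``delta_map = treated - baseline``.

    ``strain_of`` optionally maps animal id -> strain label (defaults to the
    prefix of the animal id before the final dash).
    """
    if baseline.empty:
        raise DataError("missing baseline summaries")
    if strain_of is None:
        strain_of = lambda a: str(a).rsplit("-", 1)[0]  # noqa: E731
    base = (
        baseline.groupby(["animal", "period"], as_index=False)["mean_map"]
        .mean()
        .rename(columns={"mean_map": "baseline_map"})
    )
    doses = sorted({d for d in dose_by_day.values() if d > 0})
    rows = []
    for dose in doses:
        day = max(dd for dd, dz in dose_by_day.items() if dz == dose)
        sel = treated.loc[treated["day"] == day]
        merged = sel.merge(base, on=["animal", "period"], how="inner")
        for _, r in merged.iterrows():
            rows.append(
                {
                    "strain": strain_of(r["animal"]),
                    "period": r["period"],
                    "dose": dose,
                    "animal": r["animal"],
                    "delta_map": float(r["mean_map"] - r["baseline_map"]),
                }
            )
    if not rows:
        raise DataError("no treated day matched the dose map")
    return pd.DataFrame(rows)
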