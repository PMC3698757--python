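"""Band power of beat-to-beat systolic pressure variability.

The low-frequency (LF, 0.27-0.75 Hz) power of systolic-pressure variability is
the vasomotor sympathetic-tone index; the high-frequency band (HF,
0.75-3.3 Hz) captures respiratory modulation. The beat series is linearly
interpolated onto a uniform grid, a Welch-averaged periodogram is taken with
per-segment linear detrending and a Hann taper, and the one-sided density is
integrated over each band by the trapezoid rule with interpolated band edges
(which makes band power exactly additive over adjacent bands).

Telemetry convention for time courses: one 5-min analysis window at the top of
every hour, giving hourly LF/HF values; windows that are too sparse are
propagated as missing, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import welch

from .beats import BeatSeries, split_by_window
from .errors import DataError

LF_BAND = (0.27, 0.75)
HF_BAND = (0.75, 3.3)

DEFAULT_RESAMPLE_HZ = 10.0
DEFAULT_SEGMENT_S = 60.0
DEFAULT_OVERLAP = 0.5


@dataclass
class EvenSeries:
    """SBP on a uniform time grid (linear-interpolation product of a beat series)."""

    values: np.ndarray
    rate: float
    window_start: float = 0.0  # record-relative seconds

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 2 * HF_BAND[1]:
            raise DataError(f"resampling rate must exceed {2 * HF_BAND[1]} Hz")


@dataclass
class PSD:
    """One-sided power spectral density, mmHg^2/Hz."""

    freqs: np.ndarray
    density: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0) or self.freqs[0] < 0:
            raise DataError("frequencies must be non-negative ascending")
        if np.any(self.density < 0):
            raise DataError("spectral density must be non-negative")

    @property
    def nyquist(self) -> float:
        return float(self.freqs[-1])

    def total_power(self) -> float:
        return float(np.trapezoid(self.density, self.freqs))


@dataclass
class BandPower:
    """Integrated LF and HF power for one analysis window."""

    lf: float
    hf: float
    window_start: float
    valid: bool = True

    @property
    def lf_hf_ratio(self) -> float:
        if self.hf == 0:
            return float("nan")
        return self.lf / self.hf


def resample_evenly(
    beats: BeatSeries,
    rate: float = DEFAULT_RESAMPLE_HZ,
    max_gap_fraction: float = 0.25,
) -> EvenSeries:
    """Linear interpolation of SBP against systolic time onto a uniform grid.

    The mean is *not* removed here; detrending belongs to :func:`estimate_psd`.
    Windows with fewer than 8 beats, or where the largest inter-beat gap
    exceeds ``max_gap_fraction`` of the window (artifact exclusions), raise
    ``DataError`` so callers can mark the window invalid rather than silently
    producing a zero.
    """
    t = beats.df["systolic_time_s"].to_numpy()
    y = beats.df["sbp"].to_numpy()
    if t.size < 8:
        raise DataError("window too sparse: fewer than 8 beats")
    span = t[-1] - t[0]
    if span <= 0:
        raise DataError("degenerate window")
    if np.max(np.diff(t)) > max_gap_fraction * span:
        raise DataError("window too sparse: gap exceeds allowed fraction")
    grid = np.arange(t[0], t[-1], 1.0 / rate)
    vals = np.interp(grid, t, y)
    return EvenSeries(vals, rate=rate, window_start=float(t[0]))


def estimate_psd(
    series: EvenSeries,
    segment_s: float = DEFAULT_SEGMENT_S,
    overlap: float = DEFAULT_OVERLAP,
) -> PSD:
    """Welch-averaged one-sided periodogram of an evenly sampled SBP series.

    Each segment is linearly detrended and Hann-tapered; the density is
    normalised so that its integral over [0, Nyquist] equals the variance of
    the detrended series (Parseval).
    """
    nperseg = int(round(segment_s * series.rate))
    if nperseg > series.values.size:
        raise DataError("segment longer than the series")
    freqs, dens = welch(
        series.values,
        fs=series.rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        detrend="linear",
        scaling="density",
    )
    return PSD(freqs=freqs, density=dens, resolution=float(freqs[1] - freqs[0]))


def band_power(psd: PSD, lo: float, hi: float) -> float:
    """Trapezoidal integral of the density over [lo, hi), edges interpolated.

    Because edge values are linearly interpolated, band power is exactly
    additive over adjacent bands: power([a,b]) + power([b,c]) = power([a,c]).
    """
    if not 0 <= lo < hi:
        raise DataError("need 0 <= lo < hi")
    if hi > psd.nyquist + 1e-12:
        raise DataError("band extends beyond the PSD support")
    f, d = psd.freqs, psd.density
    inside = (f > lo) & (f < hi)
    xs = np.concatenate([[lo], f[inside], [hi]])
    ys = np.concatenate([[np.interp(lo, f, d)], d[inside], [np.interp(hi, f, d)]])
    return float(np.trapezoid(ys, xs))


def window_band_power(
    beats: BeatSeries,
    rate: float = DEFAULT_RESAMPLE_HZ,
    segment_s: float = DEFAULT_SEGMENT_S,
    overlap: float = DEFAULT_OVERLAP,
) -> BandPower:
    """LF/HF band power of one analysis window of beats."""
    series = resample_evenly(beats, rate=rate)
    psd = estimate_psd(series, segment_s=segment_s, overlap=overlap)
    return BandPower(
        lf=band_power(psd, *LF_BAND),
        hf=band_power(psd, *HF_BAND),
        window_start=series.window_start,
    )


def lf_sbp_series(
    beats: BeatSeries,
    window_s: float = 300.0,
    offset_s: float = 0.0,
    rate: float = DEFAULT_RESAMPLE_HZ,
    segment_s: float = DEFAULT_SEGMENT_S,
    overlap: float = DEFAULT_OVERLAP,
) -> pd.DataFrame:
    """Hourly LF/HF band power: one 5-min window at the top of each hour.

    Returns a frame with ``window_start`` (record-relative s), ``lf_mmHg2``,
    ``hf_mmHg2``, ``lf_hf_ratio`` and ``valid``; invalid windows keep their row
    with NaN values so that missingness is explicit.
    """
    t = beats.df["systolic_time_s"].to_numpy()
    if t.size == 0 or t[-1] - t[0] < 3595.0:
        raise DataError("need at least one hour of beats")
    n_hours = int(t[-1] // 3600.0) + 1
    starts = np.arange(n_hours) * 3600.0 + offset_s
    starts = starts[starts + window_s <= t[-1] + 1e-9]
    windows = [(s, s + window_s) for s in starts]
    rows = []
    for win in split_by_window(beats, windows):
        start = win.df["systolic_time_s"].iloc[0] if len(win) else np.nan
        try:
            bp = window_band_power(
                win, rate=rate, segment_s=segment_s, overlap=overlap
            )
            rows.append((bp.window_start, bp.lf, bp.hf, bp.lf_hf_ratio, True))
        except DataError:
            rows.append((start, np.nan, np.nan, np.nan, False))
    df = pd.DataFrame(
        rows, columns=["window_start", "lf_mmHg2", "hf_mmHg2", "lf_hf_ratio", "valid"]
    )
    # anchor window_start at the nominal hour boundary for readability
    df["window_start"] = [w[0] for w in windows]
    return df
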