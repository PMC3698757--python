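"""Spontaneous baroreflex gain (sBRG) by the sequence method.

The arterial baroreflex buffers pressure changes by adjusting heart period:
a spontaneous ramp of systolic pressure over consecutive beats is met by a
concordant ramp of pulse interval (higher pressure -> longer interval, reflex
bradycardia). The sequence (time-series) method scans the beat series for
maximal runs of at least ``min_len`` beats in which SBP changes monotonically
by at least ``min_dsbp`` per beat and the pulse interval (at a configurable
beat delay) changes in the same direction by at least ``min_dpi`` per beat.
The slope of an ordinary least-squares fit of pulse interval on SBP over each
run, in ms/mmHg, estimates the reflex gain; runs with correlation below
``min_r`` are discarded.

Falling-pressure runs with shortening intervals are kept — they also carry a
positive slope. Only sequences whose fitted slope is positive enter the gain
(negative slopes arise from non-baroreflex coupling and are excluded, but
counted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beats import BeatSeries, split_by_window
from .errors import DataError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequenceCriteria:
    """Sequence-detection thresholds (conventional sequence-method settings)."""

    min_len: int = 3  # beats
    min_dsbp: float = 0.5  # mmHg per beat
    min_dpi: float = 1.0  # ms per beat
    delay: int = 0  # beats of PI lag relative to SBP
    min_r: float = 0.8  # minimum |correlation| of the PI~SBP fit

    def __post_init__(self) -> None:
        if self.min_len < 3:
            raise DataError("min_len must be >= 3 beats")
        if self.min_dsbp < 0 or self.min_dpi < 0 or self.delay < 0:
            raise DataError("thresholds and delay must be >= 0")


@dataclass
class Sequence:
    """One concordant SBP/PI ramp."""

    start: int  # index of first beat (SBP indexing)
    length: int  # number of beats
    direction: str  # 'up' | 'down'
    slope: float  # ms/mmHg
    r: float

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.length)


@dataclass
class SBRGEstimate:
    """Mean positive-slope sequence gain for one analysis window."""

    gain: float  # ms/mmHg, NaN when invalid
    n_sequences: int  # positive-slope sequences used
    n_negative: int = 0  # negative-slope sequences excluded
    window_start: float = 0.0
    valid: bool = True


def _ols_slope_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    if sxx == 0:
        return np.nan, np.nan
    slope = sxy / sxx
    r = sxy / np.sqrt(sxx * syy) if syy > 0 else np.nan
    return slope, r


def find_sequences(beats: BeatSeries, criteria: SequenceCriteria | None = None):
    """Locate maximal concordant SBP/PI ramps and fit their slopes.

    Beats with undefined pulse interval (the final beat of a record, artifact
    neighbours) break candidate runs. Returns a list of :class:`Sequence`;
    an empty list is a valid outcome.
    """
    c = criteria or SequenceCriteria()
    sbp = beats.df["sbp"].to_numpy(dtype=float)
    pi = beats.df["pulse_interval_ms"].to_numpy(dtype=float)
    n = sbp.size
    if n < c.min_len:
        raise DataError(f"need at least {c.min_len} beats")

    # PI aligned to the SBP beat that drives it: beat i pairs with PI of beat i+delay
    if c.delay > 0:
        pi_al = np.concatenate([pi[c.delay :], np.full(c.delay, np.nan)])
    else:
        pi_al = pi

    dsbp = np.diff(sbp)
    dpi = np.diff(pi_al)
    ok = ~np.isnan(dpi)
    up = ok & (dsbp >= c.min_dsbp) & (dpi >= c.min_dpi)
    down = ok & (dsbp <= -c.min_dsbp) & (dpi <= -c.min_dpi)

    out: list[Sequence] = []
    for mask, direction in ((up, "up"), (down, "down")):
        for start, length in _maximal_runs(mask, c.min_len - 1):
            idx = slice(start, start + length + 1)  # steps -> beats
            slope, r = _ols_slope_r(sbp[idx], pi_al[idx])
            if np.isnan(r) or abs(r) < c.min_r:
                continue
            out.append(
                Sequence(
                    start=start,
                    length=length + 1,
                    direction=direction,
                    slope=slope,
                    r=r,
                )
            )
    out.sort(key=lambda s: s.start)
    return out


def _maximal_runs(mask: np.ndarray, min_steps: int):
    """Yield (start, length) of maximal True runs of at least ``min_steps`` steps."""
    if mask.size == 0:
        return
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    for s, e in zip(starts, ends):
        if e - s >= min_steps:
            yield int(s), int(e - s)


def sbrg(
    beats: BeatSeries,
    criteria: SequenceCriteria | None = None,
    min_sequences: int = 1,
) -> SBRGEstimate:
    """Spontaneous baroreflex gain: mean slope over positive-slope sequences.

    Both rising and falling ramps contribute as long as the fitted slope is
    positive; negative-slope sequences are counted and excluded. An estimate
    based on fewer than ``min_sequences`` qualifying sequences is flagged
    invalid (gain NaN), never reported as zero.
    """
    seqs = find_sequences(beats, criteria)
    slopes = np.array([s.slope for s in seqs])
    pos = slopes[slopes > 0]
    n_neg = int((slopes <= 0).sum())
    if n_neg:
        log.debug("excluded %d non-positive-slope sequences", n_neg)
    if pos.size == 0 or pos.size < min_sequences:
        return SBRGEstimate(
            gain=float("nan"),
            n_sequences=int(pos.size),
            n_negative=n_neg,
            valid=False,
        )
    return SBRGEstimate(
        gain=float(pos.mean()), n_sequences=int(pos.size), n_negative=n_neg
    )


def sbrg_series(
    beats: BeatSeries,
    criteria: SequenceCriteria | None = None,
    window_s: float = 300.0,
    offset_s: float = 0.0,
    min_sequences: int = 3,
) -> pd.DataFrame:
    """Hourly sBRG: one 5-min window at the top of each hour.

    Same cadence and validity rules as the hourly LF series; invalid windows
    are kept as NaN rows.
    """
    t = beats.df["systolic_time_s"].to_numpy()
    if t.size == 0 or t[-1] - t[0] < 3595.0:
        raise DataError("need at least one hour of beats")
    n_hours = int(t[-1] // 3600.0) + 1
    starts = np.arange(n_hours) * 3600.0 + offset_s
    starts = starts[starts + window_s <= t[-1] + 1e-9]
    windows = [(s, s + window_s) for s in starts]
    rows = []
    c = criteria or SequenceCriteria()
    for (w0, _), win in zip(windows, split_by_window(beats, windows)):
        try:
            est = sbrg(win, c, min_sequences=min_sequences)
        except DataError:
            est = SBRGEstimate(float("nan"), 0, valid=False)
        rows.append((w0, est.gain if est.valid else np.nan, est.n_sequences, est.valid))
    return pd.DataFrame(
        rows, columns=["window_start", "gain_ms_per_mmHg", "n_sequences", "valid"]
    )
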