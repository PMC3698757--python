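"""Light/dark schedule arithmetic.

Rats are nocturnal: the dark period is the active phase. The housing schedule
is a 12:12 light-dark cycle with dark running 20:00-8:00 by default. Analysis
days are anchored at dark onset, so one "day" is a dark period followed by the
light period that completes the cycle (dosing in the drug studies also happens
at dark onset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DAY_S = 86400.0


@dataclass(frozen=True)
class LightDarkSchedule:
    """A fixed daily light/dark cycle.

    Parameters
    ----------
    dark_onset_hour : float
        Wall-clock hour (0-24) at which lights go off. Default 20:00.
    dark_hours : float
        Length of the dark period in hours. Default 12.
    """

    dark_onset_hour: float = 20.0
    dark_hours: float = 12.0

    def __post_init__(self) -> None:
        if not 0 <= self.dark_onset_hour < 24:
            raise ValueError("dark_onset_hour must be in [0, 24)")
        if not 0 < self.dark_hours < 24:
            raise ValueError("dark_hours must be in (0, 24)")

    def is_dark(self, clock_hour):
        """True where ``clock_hour`` (hour-of-day, scalar or array) is in the dark period."""
        h = np.asarray(clock_hour, dtype=float)
        rel = (h - self.dark_onset_hour) % 24.0
        return rel < self.dark_hours

    def period_of(self, clock_hour):
        """'dark' / 'light' label(s) for hour-of-day value(s)."""
        d = self.is_dark(clock_hour)
        if np.ndim(d) == 0:
            return "dark" if d else "light"
        return np.where(d, "dark", "light")

    # ------------------------------------------------------------------
    # record-relative helpers: times are seconds from the record start
    # ------------------------------------------------------------------

    def clock_hours(self, start: pd.Timestamp, t_s):
        """Hour-of-day for record-relative second offsets ``t_s``."""
        start = pd.Timestamp(start)
        start_h = (start - start.normalize()).total_seconds() / 3600.0
        return (start_h + np.asarray(t_s, dtype=float) / 3600.0) % 24.0

    def dark_weight(self, start: pd.Timestamp, t_s, ramp_s: float = 0.0):
        """Smooth 0/1 dark indicator with optional half-cosine ramps.

        With ``ramp_s`` > 0 the transition from light (0) to dark (1) is a
        half-cosine centred on each lights-off/on instant and lasting
        ``ramp_s`` seconds, which avoids step discontinuities when the weight
        drives a simulated pressure baseline.
        """
        h = self.clock_hours(start, t_s)
        rel = (h - self.dark_onset_hour) % 24.0 * 3600.0  # s since dark onset
        dark_s = self.dark_hours * 3600.0
        w = (rel < dark_s).astype(float)
        if ramp_s > 0 and w.ndim:
            half = ramp_s / 2.0
            # ramps touch only a sliver of the record; work on index subsets
            d_on = np.minimum(rel, DAY_S - rel)  # distance to dark onset
            idx = np.flatnonzero(d_on < half)
            if idx.size:
                sgn = np.where(rel[idx] < DAY_S / 2, 1.0, -1.0)  # after vs before
                w[idx] = 0.5 * (1.0 + np.sin(np.pi * sgn * d_on[idx] / ramp_s))
            d_off = np.abs(rel - dark_s)  # distance to lights-on
            idx = np.flatnonzero(d_off < half)
            if idx.size:
                sgn = np.where(rel[idx] > dark_s, 1.0, -1.0)
                w[idx] = 0.5 * (1.0 - np.sin(np.pi * sgn * d_off[idx] / ramp_s))
        elif ramp_s > 0:
            raise ValueError("ramped dark_weight expects an array of times")
        return w

    def day_periods(self, start: pd.Timestamp, duration_s: float) -> pd.DataFrame:
        """Partition a record into dark/light half-windows of analysis days.

        Returns a frame with columns ``day`` (0-based index of the dark onset
        at or before the record start), ``period`` (dark|light), ``start_s``
        and ``end_s`` (record-relative, clipped to the record, half-open).
        """
        start = pd.Timestamp(start)
        start_h = (start - start.normalize()).total_seconds() / 3600.0
        # seconds from record start to the dark onset that begins "day 0"
        back = ((start_h - self.dark_onset_hour) % 24.0) * 3600.0
        first_onset = -back
        dark_s = self.dark_hours * 3600.0
        rows = []
        day = 0
        onset = first_onset
        while onset < duration_s:
            for period, a, b in (
                ("dark", onset, onset + dark_s),
                ("light", onset + dark_s, onset + DAY_S),
            ):
                lo, hi = max(a, 0.0), min(b, duration_s)
                if hi > lo:
                    rows.append((day, period, lo, hi))
            onset += DAY_S
            day += 1
        return pd.DataFrame(rows, columns=["day", "period", "start_s", "end_s"])
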