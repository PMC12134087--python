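"""Wet/dry season segmentation from a standardised NDVI series.

The NDVI series is standardised over the whole tracking period and, per
season-year, thresholded at z = 0 (the period mean) after light smoothing.
The wet season of a year is the longest contiguous above-threshold run; its
first and last zero-crossings (linearly interpolated between records) are
the two seasonal cut points, and the remainder of the year is dry.  Season
years run July-June so that a southern-hemisphere November-April wet season
is never split across a year boundary.  A year with no crossing carries no
seasonal signal and falls back to calendar seasons (November-April wet)
with a warning.

The rule (threshold, window, longest run) is the simplest two-cut-point
scheme consistent with an NDVI-indicated wet season; every choice is a
parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["SeasonTable", "standardize_ndvi", "season_cutpoints", "assign_season"]


@dataclass
class SeasonYear:
    label: str            # e.g. "2013/2014"
    start: float          # epoch seconds, inclusive
    end: float            # epoch seconds, exclusive
    wet_start: float
    wet_end: float
    fallback: bool = False


@dataclass
class SeasonTable:
    """Per-year wet interval; the complement of wet within a year is dry."""

    years: list[SeasonYear] = field(default_factory=list)

    @property
    def coverage(self) -> tuple[float, float]:
        if not self.years:
            raise ValueError("empty season table")
        return self.years[0].start, self.years[-1].end

    def wet_intervals(self) -> list[tuple[float, float]]:
        return [(y.wet_start, y.wet_end) for y in self.years]

    def dry_intervals(self) -> list[tuple[float, float]]:
        out = []
        for y in self.years:
            if y.wet_start > y.start:
                out.append((y.start, y.wet_start))
            if y.wet_end < y.end:
                out.append((y.wet_end, y.end))
        return out

    def to_frame(self) -> pd.DataFrame:
        def iso(t):
            return pd.Timestamp(t, unit="s", tz="UTC").isoformat()

        return pd.DataFrame(
            [{"year": y.label, "wet_start": iso(y.wet_start), "wet_end": iso(y.wet_end),
              "fallback": y.fallback} for y in self.years]
        )


def standardize_ndvi(times, values) -> tuple[np.ndarray, np.ndarray]:
    """Standardise an NDVI series over its whole period (sample-sd convention).

    Returns (times, z) with mean(z) = 0 and sd(z, ddof=1) = 1.
    """
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    if len(np.unique(v)) < 2:
        raise ValueError("constant NDVI series cannot be standardised")
    sd = np.std(v, ddof=1)
    return t, (v - v.mean()) / sd


def _smooth(z: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return z.copy()
    s = pd.Series(z).rolling(window, center=True, min_periods=1).mean()
    return s.to_numpy()


def _crossing_time(t0, z0, t1, z1) -> float:
    # linear interpolation of the zero crossing between two records
    return t0 + (0.0 - z0) / (z1 - z0) * (t1 - t0)


def season_cutpoints(times, z, smooth_window: int = 3,
                     year_start_month: int = 7,
                     fallback_wet=(11, 1, 5, 1)) -> SeasonTable:
    """Two seasonal cut points per year from a standardised NDVI series.

    Parameters
    ----------
    times, z : standardised series (epoch seconds, z-scores)
    smooth_window : centred moving-mean window in records (default 3)
    year_start_month : first month of the season-year (default July)
    fallback_wet : (start_month, start_day, end_month, end_day) of the
        calendar wet season used when a year shows no crossing; the default
        is November 1 to May 1 (i.e. November-April wet).
    """
    t = np.asarray(times, float)
    z = np.asarray(z, float)
    if len(t) < 2:
        raise ValueError("need at least 2 records")
    zs = _smooth(z, smooth_window)
    ts_first = pd.Timestamp(t[0], unit="s", tz="UTC")
    ts_last = pd.Timestamp(t[-1], unit="s", tz="UTC")

    # season-year boundaries covering the record span
    y0 = ts_first.year if ts_first.month >= year_start_month else ts_first.year - 1
    boundaries = []
    y = y0
    while True:
        b = pd.Timestamp(year=y, month=year_start_month, day=1, tz="UTC")
        boundaries.append(b)
        if b > ts_last:
            break
        y += 1
    if len(boundaries) < 2:
        raise ValueError("need at least 1 complete season-year of records")

    table = SeasonTable()
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        s0, s1 = b0.timestamp(), b1.timestamp()
        sel = (t >= s0) & (t < s1)
        if not sel.any():
            continue
        label = f"{b0.year}/{b1.year}"
        runs = _super_threshold_runs(t, zs, s0, s1)
        if not runs:
            wet0, wet1 = _calendar_fallback(b0, b1, fallback_wet)
            logger.warning("season-year %s: no seasonal signal, calendar fallback wet %s",
                           label, (pd.Timestamp(wet0, unit='s', tz='UTC').date(),
                                   pd.Timestamp(wet1, unit='s', tz='UTC').date()))
            table.years.append(SeasonYear(label, s0, s1, wet0, wet1, fallback=True))
        else:
            wet0, wet1 = max(runs, key=lambda r: r[1] - r[0])
            table.years.append(SeasonYear(label, s0, s1, wet0, wet1))
    if not table.years:
        raise ValueError("no records fall inside any season-year")
    return table


def _calendar_fallback(b0: pd.Timestamp, b1: pd.Timestamp, spec) -> tuple[float, float]:
    m0, d0, m1, d1 = spec
    start_year = b0.year if m0 >= b0.month else b1.year
    wet0 = pd.Timestamp(year=start_year, month=m0, day=d0, tz="UTC")
    end_year = wet0.year if m1 > m0 else wet0.year + 1
    wet1 = pd.Timestamp(year=end_year, month=m1, day=d1, tz="UTC")
    return wet0.timestamp(), wet1.timestamp()


def _super_threshold_runs(t, zs, s0, s1) -> list[tuple[float, float]]:
    """Contiguous z > 0 runs inside [s0, s1), ends interpolated at crossings."""
    idx = np.flatnonzero((t >= s0) & (t < s1))
    if len(idx) == 0:
        return []
    above = zs > 0.0
    # require at least one crossing visible within the year
    if np.all(above[idx]) or not np.any(above[idx]):
        return []
    runs = []
    i = idx[0]
    last = idx[-1]
    while i <= last:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 <= last and above[j + 1]:
            j += 1
        if i > 0 and not above[i - 1]:
            start = max(s0, _crossing_time(t[i - 1], zs[i - 1], t[i], zs[i]))
        else:
            start = max(s0, t[i] if i == 0 else s0)
        if j + 1 < len(t) and not above[j + 1]:
            end = min(s1, _crossing_time(t[j], zs[j], t[j + 1], zs[j + 1]))
        else:
            end = min(s1, t[j] if j == len(t) - 1 else s1)
        runs.append((start, end))
        i = j + 1
    return runs


def assign_season(t, st: SeasonTable) -> np.ndarray:
    """Label each time wet or dry; wet intervals are closed at both ends.

    Raises for times outside the table coverage.
    """
    tt = np.atleast_1d(np.asarray(t, float))
    c0, c1 = st.coverage
    if np.any(tt < c0) or np.any(tt > c1):
        raise ValueError("timestamp outside season-table coverage")
    out = np.full(tt.shape, "dry", dtype=object)
    for w0, w1 in st.wet_intervals():
        out[(tt >= w0) & (tt <= w1)] = "wet"
    return out if np.ndim(t) else out  # always array; scalar callers index [0]
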