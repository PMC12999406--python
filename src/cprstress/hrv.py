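"""Heart-rate-variability metrics from inter-beat-interval (IBI) series.

The wristband exports beat offsets (seconds from recording start) and
beat-to-beat intervals.  This module cleans the series (zero and isolated
outlier removal), and computes heart rate, RMSSD and the Poincare short-term
index SD1, including the windowed-SD1 variant used under non-stationary
stress (SD1 per consecutive 10-s window over the first 90 s, then averaged).

Units: intervals and RMSSD are in milliseconds; SD1 is reported in seconds,
the scale on which the performance models operate (an optimal value around
0.02 s corresponds to ~20 ms of beat-to-beat dispersion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import UnusableSignalError, ValidationError

__all__ = [
    "IBISeries",
    "HRVSummary",
    "clean_ibi",
    "heart_rate",
    "rmssd",
    "poincare_sd1",
    "windowed_sd1",
    "summarize_hrv",
]


@dataclass
class IBISeries:
    """A timestamped beat-to-beat interval series for one participant-phase.

    Parameters
    ----------
    start_time:
        UNIX start time of the recording in seconds.
    offsets:
        Beat offsets in seconds from ``start_time``, strictly increasing.
    intervals:
        Beat-to-beat intervals in milliseconds, aligned with ``offsets``.
    contiguous:
        ``contiguous[i]`` is True when beat ``i`` directly follows beat
        ``i - 1`` in the original recording.  Cleaning breaks contiguity at
        every removed beat; successive-difference statistics never straddle
        such a gap.  ``contiguous[0]`` is always False.
    """

    start_time: float
    offsets: np.ndarray
    intervals: np.ndarray
    contiguous: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.offsets.ndim != 1 or self.offsets.shape != self.intervals.shape:
            raise ValidationError("offsets and intervals must be 1-D and aligned")
        if len(self.offsets) and np.any(np.diff(self.offsets) <= 0):
            raise ValidationError("beat offsets must be strictly increasing")
        if self.contiguous is None:
            c = np.ones(len(self.offsets), dtype=bool)
            if len(c):
                c[0] = False
            self.contiguous = c
        else:
            self.contiguous = np.asarray(self.contiguous, dtype=bool)
            if self.contiguous.shape != self.offsets.shape:
                raise ValidationError("contiguous flags must align with beats")
            if len(self.contiguous):
                self.contiguous[0] = False

    def __len__(self) -> int:
        return len(self.offsets)

    def successive_differences(self) -> np.ndarray:
        """Interval differences (ms) between beats adjacent in the recording."""
        if len(self) < 2:
            return np.empty(0)
        d = np.diff(self.intervals)
        return d[self.contiguous[1:]]


@dataclass
class HRVSummary:
    """Per-phase HRV summary: HR (bpm), RMSSD (ms), windowed SD1 (s)."""

    hr: float
    rmssd: float
    sd1_windows: Sequence[float]
    sd1_mean: Optional[float]
    n_beats: int


def _loo_band(values: np.ndarray, k: float = 2.0):
    """Leave-one-out mean +- k*SD membership for each value.

    Each interval is judged against the mean and population SD of the *other*
    intervals; a gross artifact therefore cannot mask itself by inflating the
    band it is tested against.  For long series this converges to the global
    mean +- k*SD band.
    """
    n = len(values)
    if n < 3:
        return np.ones(n, dtype=bool)
    s, ss = values.sum(), (values**2).sum()
    loo_mean = (s - values) / (n - 1)
    loo_var = np.maximum((ss - values**2) / (n - 1) - loo_mean**2, 0.0)
    return np.abs(values - loo_mean) <= k * np.sqrt(loo_var)


def clean_ibi(series: IBISeries) -> IBISeries:
    """Remove zero intervals and isolated outlier beats.

    Zero (or negative) intervals are discarded outright.  A remaining
    interval is an *isolated outlier* when it falls outside the mean +- 2 SD
    band while both neighbours fall inside; isolated points are single-beat
    artifacts (e.g. a missed or doubled pulse), whereas runs of extreme
    values are kept as genuine physiology.  The screen is a single pass,
    and every removal breaks successive-difference adjacency.

    Raises
    ------
    UnusableSignalError
        If fewer than three beats survive.
    """
    if len(series) == 0:
        raise UnusableSignalError("empty IBI series")
    pos = series.intervals > 0
    off, iv = series.offsets[pos], series.intervals[pos]
    contig = series.contiguous[pos].copy()
    # a removed zero breaks adjacency for the following retained beat
    if len(iv):
        kept_idx = np.flatnonzero(pos)
        contig &= np.concatenate([[False], np.diff(kept_idx) == 1])
        contig[0] = False

    inside = _loo_band(iv)
    # "isolated" needs two existing neighbours, both inside the band; the
    # first and last beats therefore never qualify, and runs of extreme
    # values (genuine physiology, not single-beat artifacts) are kept
    isolated = np.zeros(len(iv), dtype=bool)
    if len(iv) > 2:
        isolated[1:-1] = ~inside[1:-1] & inside[:-2] & inside[2:]
    keep = ~isolated

    if keep.sum() < 3:
        raise UnusableSignalError(
            f"only {int(keep.sum())} usable beats after cleaning"
        )
    kept_idx = np.flatnonzero(keep)
    new_contig = contig[kept_idx]
    # beats only remain adjacent when nothing between them was removed
    new_contig[1:] &= np.diff(kept_idx) == 1
    if len(new_contig):
        new_contig[0] = False
    return IBISeries(series.start_time, off[kept_idx], iv[kept_idx], new_contig)


def heart_rate(series: IBISeries) -> float:
    """Mean heart rate in beats per minute: 60000 / mean interval (ms)."""
    if len(series) == 0:
        raise UnusableSignalError("empty IBI series")
    return 60000.0 / float(np.mean(series.intervals))


def rmssd(series: IBISeries) -> float:
    """Root mean square of successive differences, in milliseconds.

    Differences are taken only between beats adjacent in the recording;
    a cleaning gap breaks adjacency so artifact removal cannot inflate
    the statistic.
    """
    if len(series) < 2:
        raise UnusableSignalError("RMSSD needs at least two beats")
    d = series.successive_differences()
    if len(d) == 0:
        raise UnusableSignalError("no adjacent beat pairs for RMSSD")
    return float(np.sqrt(np.mean(d**2)))


def poincare_sd1(series: IBISeries) -> float:
    """Poincare SD1 in seconds.

    SD1 is the dispersion of Poincare-plot points perpendicular to the line
    of identity, equal to the population standard deviation of successive
    differences divided by sqrt(2).  The population (divisor N) form makes
    the identity SD1 = RMSSD/sqrt(2) exact whenever the successive
    differences have zero mean, and SD1 <= RMSSD/sqrt(2) always.
    """
    if len(series) < 3:
        raise UnusableSignalError("SD1 needs at least three beats")
    d = series.successive_differences()
    if len(d) < 2:
        raise UnusableSignalError("SD1 needs at least two successive differences")
    return float(np.std(d) / np.sqrt(2.0) / 1000.0)


def windowed_sd1(
    series: IBISeries, window: float = 10.0, span: float = 90.0
) -> tuple[list[float], float]:
    """SD1 per consecutive non-overlapping window over the opening span.

    The series is truncated to beat offsets in ``[0, span)`` and partitioned
    into ``floor(span/window)`` windows of ``window`` seconds.  SD1 is
    computed in every window holding at least three beats (and two adjacent
    differences); sparser windows are skipped.  Returns the per-window SD1
    values (s) and their arithmetic mean.

    Raises
    ------
    UnusableSignalError
        If no window is usable.
    """
    if window <= 0 or span <= 0:
        raise ValidationError("window and span must be positive")
    n_windows = int(span // window)
    values: list[float] = []
    for k in range(n_windows):
        lo, hi = k * window, (k + 1) * window
        sel = (series.offsets >= lo) & (series.offsets < hi)
        if sel.sum() < 3:
            continue
        sub = IBISeries(
            series.start_time,
            series.offsets[sel],
            series.intervals[sel],
            series.contiguous[sel],
        )
        try:
            values.append(poincare_sd1(sub))
        except UnusableSignalError:
            continue
    if not values:
        raise UnusableSignalError("no window with enough beats for SD1")
    return values, float(np.mean(values))


def summarize_hrv(
    series: IBISeries, window: float = 10.0, span: float = 90.0
) -> HRVSummary:
    """Clean a series and compute the full per-phase HRV summary."""
    cleaned = clean_ibi(series)
    try:
        wins, mean = windowed_sd1(cleaned, window=window, span=span)
    except UnusableSignalError:
        wins, mean = [], None
    return HRVSummary(
        hr=heart_rate(cleaned),
        rmssd=rmssd(cleaned),
        sd1_windows=wins,
        sd1_mean=mean,
        n_beats=len(cleaned),
    )
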