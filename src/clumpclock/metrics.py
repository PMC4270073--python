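"""Quantitative outputs: the F75/F25 oscillation score, clump-size
histograms, pulse-width size ratios, and peak-spacing period estimation.

The F75/F25 score summarizes one FACS event table: fluorescence intensity and
pulse width are each min-max scaled to [0, 100]; F25 counts events jointly in
the bottom quartile of both channels (single-cell-like), F75 counts events
jointly in the top quartile of both (large-clump-like), and the score is
log10(F75/F25). A synchronized culture alternates between F25-heavy and
F75-heavy tables over its daily cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import DegenerateInputError

__all__ = [
    "OscillationScore",
    "SizeHistogram",
    "PeriodEstimate",
    "f75_f25",
    "size_histogram",
    "fraction_large",
    "estimate_period",
]


@dataclass(frozen=True)
class OscillationScore:
    f25: int
    f75: int
    log_ratio: float


@dataclass(frozen=True)
class SizeHistogram:
    """Clump-frequency fractions in the bins 1-4, 5-10, and >10 cells."""

    freq_1_4: float
    freq_5_10: float
    freq_gt10: float

    def as_tuple(self) -> tuple:
        return (self.freq_1_4, self.freq_5_10, self.freq_gt10)


@dataclass(frozen=True)
class PeriodEstimate:
    period: float
    n_cycles: int
    method: str = "peak_spacing"


def _log_ratio(numer: int, denom: int, pseudo: float, log_base: float) -> float:
    # pseudo-count applied only when either raw count is zero
    if numer == 0 or denom == 0:
        value = (numer + pseudo) / (denom + pseudo)
    else:
        value = numer / denom
    return float(np.log(value) / np.log(log_base))


def _channels(events) -> tuple:
    if isinstance(events, pd.DataFrame):
        return events["yfp"].to_numpy(float), events["pulse_width"].to_numpy(float)
    yfp, pw = events
    return np.asarray(yfp, float), np.asarray(pw, float)


def f75_f25(
    events: Union[pd.DataFrame, tuple],
    pseudo: float = 0.5,
    log_base: float = 10.0,
) -> OscillationScore:
    """Score one event table by its joint intensity/pulse-width quartile tails.

    Each channel is independently scaled so its lowest value maps to 0 and
    its highest to 100, linearly in between. F25 = number of events with both
    scaled values <= 25; F75 = number with both >= 75 (boundaries included).
    ``log_ratio`` is ``log10(F75/F25)``; when either count is zero, a
    pseudo-count of ``pseudo`` is added to both.

    Accepts an event DataFrame (columns ``yfp``, ``pulse_width``) or a pair
    of arrays. Raises :class:`DegenerateInputError` for fewer than two events
    or a zero range in either channel.
    """
    yfp, pw = _channels(events)
    if yfp.size < 2:
        raise DegenerateInputError("need at least two events")
    scaled = []
    for values in (yfp, pw):
        lo, hi = values.min(), values.max()
        if hi == lo:
            raise DegenerateInputError("zero range in a channel")
        scaled.append((values - lo) / (hi - lo) * 100.0)
    s_yfp, s_pw = scaled
    f25 = int(np.count_nonzero((s_yfp <= 25.0) & (s_pw <= 25.0)))
    f75 = int(np.count_nonzero((s_yfp >= 75.0) & (s_pw >= 75.0)))
    return OscillationScore(f25, f75, _log_ratio(f75, f25, pseudo, log_base))


def size_histogram(sizes) -> SizeHistogram:
    """Fraction of clumps containing 1-4, 5-10, and >10 cells.

    Accepts an array of clump sizes or a :class:`~clumpclock.oscillator.Population`.
    """
    if hasattr(sizes, "clump_sizes"):
        sizes = sizes.clump_sizes()
    sizes = np.asarray(sizes)
    if sizes.size == 0:
        raise DegenerateInputError("no clumps")
    if (sizes < 1).any():
        raise ValueError("clump sizes must be >= 1")
    n = sizes.size
    small = np.count_nonzero(sizes <= 4)
    mid = np.count_nonzero((sizes >= 5) & (sizes <= 10))
    big = np.count_nonzero(sizes > 10)
    return SizeHistogram(small / n, mid / n, big / n)


def fraction_large(
    events: Union[pd.DataFrame, Sequence[float]],
    pw_cutoff: float,
    pseudo: float = 0.5,
) -> float:
    """Ratio of events above vs below a pulse-width cutoff.

    The cutoff is calibrated in practice against beads of known size; the
    ratio ``(# pulse_width > cutoff) / (# pulse_width <= cutoff)`` then
    tracks the abundance of large aggregates. The zero-count pseudo-count
    rule of :func:`f75_f25` applies.
    """
    if pw_cutoff <= 0:
        raise ValueError("pw_cutoff must be positive")
    pw = (
        events["pulse_width"].to_numpy(float)
        if isinstance(events, pd.DataFrame)
        else np.asarray(events, float)
    )
    if pw.size == 0:
        raise DegenerateInputError("empty event table")
    above = int(np.count_nonzero(pw > pw_cutoff))
    below = pw.size - above
    if above == 0 or below == 0:
        return (above + pseudo) / (below + pseudo)
    return above / below


def estimate_period(times, values, smooth_window: int = 3) -> PeriodEstimate:
    """Estimate an oscillation period from peak-to-peak spacing.

    The series is smoothed with a centered moving average (``smooth_window``
    points, 'valid' so the ends are dropped), local maxima exceeding the
    smoothed series' median are detected, and the period is the mean spacing
    between consecutive peak times. Needs at least two peaks.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if times.size != values.size:
        raise ValueError("times and values must have equal length")
    if times.size < smooth_window + 2:
        raise DegenerateInputError("series too short")
    if np.ptp(values) == 0:
        raise DegenerateInputError("constant series has no defined period")
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(values, kernel, mode="valid")
    offset = (smooth_window - 1) // 2
    t_smooth = times[offset : offset + smoothed.size]
    median = np.median(smoothed)
    peaks, _ = find_peaks(smoothed)
    peaks = peaks[smoothed[peaks] > median]
    if peaks.size < 2:
        raise DegenerateInputError(
            f"found {peaks.size} peak(s); need >= 2 to estimate a period"
        )
    spacings = np.diff(t_smooth[peaks])
    return PeriodEstimate(float(spacings.mean()), int(spacings.size) + 1)
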