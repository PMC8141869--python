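"""Artifact-aware preprocessing of minute-resolution temperature streams.

The fixed pipeline order is::

    mask/trim -> stitch -> 5-min bin -> { 1-h smooth -> day profile }
                                        { hourly means (gap rules)  }

Threshold comparisons are strict (``< 30``, ``> 38``, ``< 36``): a reading
of exactly 30.0 °C is retained.  No stage invents temperature outside the
convex hull of its non-missing inputs, except the explicitly flagged linear
imputation of fully-missing hours.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .series import (
    N_PROFILE_BINS,
    PROFILE_BIN_MINUTES,
    DayProfile,
    HourlySeries,
    MinuteSeries,
)

NONPHYSIOLOGICAL_THRESHOLD = 30.0  # °C; chest readings below this = sensor off
PILL_BOUNDS = (36.0, 38.0)  # °C plausibility band for core readings
PILL_WINDOW_MINUTES = 30.0
GAP_DROP_HOURS = 7.0  # missing runs longer than this drop the 24-h segment


def mask_nonphysiological(
    series: MinuteSeries, threshold: float = NONPHYSIOLOGICAL_THRESHOLD
) -> MinuteSeries:
    """Mark chest readings strictly below ``threshold`` °C as missing.

    Sensor removal (e.g. showering) makes the chest reading collapse to room
    temperature; such values carry no physiology and are masked.
    """
    if series.channel != "chest":
        raise ValueError(
            f"non-physiological masking applies to the chest channel, got {series.channel!r}"
        )
    values = series.values.copy()
    values[values < threshold] = np.nan
    return series.copy_with(values)


def trim_pill_transients(
    series: MinuteSeries,
    ingestion_time,
    window: float = PILL_WINDOW_MINUTES,
    bounds: tuple[float, float] = PILL_BOUNDS,
) -> MinuteSeries:
    """Remove implausible core readings right after pill ingestion.

    Within ``[ingestion, ingestion + window)`` minutes, readings above
    ``bounds[1]`` or below ``bounds[0]`` (hot/cold drink swallowed with the
    pill) become missing; everything outside the window is untouched.
    """
    if not series.channel.startswith("core"):
        raise ValueError(f"pill trimming applies to core channels, got {series.channel!r}")
    ingestion = pd.Timestamp(ingestion_time)
    if not (series.timestamps[0] <= ingestion <= series.timestamps[-1]):
        raise ValueError("ingestion_time lies outside the series span")
    dt_min = np.asarray((series.timestamps - ingestion) / pd.Timedelta(minutes=1))
    in_win = (dt_min >= 0) & (dt_min < window)
    values = series.values.copy()
    lo, hi = bounds
    values[in_win & ((values > hi) | (values < lo))] = np.nan
    return series.copy_with(values)


def stitch_pills(
    pill1: MinuteSeries, pill2: MinuteSeries, elimination_time_pill1
) -> MinuteSeries:
    """Join two pill streams into one continuous core series.

    Pill-1 readings are used strictly before the pill-1 elimination time and
    pill-2 readings at/after it; any coverage hole between pill-1 elimination
    and pill-2 start is flagged missing with a warning.
    """
    cut = pd.Timestamp(elimination_time_pill1)
    if not (pill1.timestamps[0] <= cut <= pill1.timestamps[-1] + pd.Timedelta(minutes=1)):
        raise ValueError("elimination_time_pill1 lies outside the pill-1 span")
    res = pill1.resolution_minutes
    if pill2.resolution_minutes != res:
        raise ValueError("pill streams must share one resolution")
    start = pill1.timestamps[0]
    end = max(pill1.timestamps[-1], pill2.timestamps[-1])
    ts = pd.date_range(start, end, freq=f"{int(res)}min")
    values = np.full(len(ts), np.nan)

    s1 = pd.Series(pill1.values, index=pill1.timestamps).reindex(ts)
    s2 = pd.Series(pill2.values, index=pill2.timestamps).reindex(ts)
    before = np.asarray(ts < cut)
    values[before] = s1.to_numpy()[before]
    values[~before] = s2.to_numpy()[~before]

    if pill2.timestamps[0] > cut:
        warnings.warn(
            "pill 2 starts after pill-1 elimination: coverage hole flagged missing",
            stacklevel=2,
        )
    return MinuteSeries(ts, values, "core")


def bin_5min(series: MinuteSeries) -> MinuteSeries:
    """Average to 5-min bins (noise and data-size reduction).

    Each bin is the mean of its non-missing samples; a bin with no samples
    stays missing.  A series already at 5-min resolution passes unchanged.
    """
    res = series.resolution_minutes
    if res > PROFILE_BIN_MINUTES:
        raise ValueError("series resolution must be <= 5 minutes")
    if res == PROFILE_BIN_MINUTES:
        return series.copy_with(series.values)
    s = pd.Series(series.values, index=series.timestamps)
    binned = s.resample("5min").mean()
    return MinuteSeries(binned.index, binned.to_numpy(), series.channel)


def smooth_moving_average(series: MinuteSeries, window_minutes: float = 60.0) -> MinuteSeries:
    """Centered moving average over a 1-h window of 5-min bins.

    An even number of 5-min bins cannot be centered exactly, so the kernel
    is the symmetric 13-tap average with half weight at both ends (the mean
    of the two half-bin-offset 12-bin boxcars); this keeps the smoother
    phase-neutral, which matters because acrophases are read off the
    smoothed curve.  Edges shrink to the available members; a window with
    no non-missing member stays missing.  Constants are preserved exactly;
    a pure 24-h harmonic is attenuated by the boxcar factor ≈ 0.997.
    """
    if series.resolution_minutes != PROFILE_BIN_MINUTES:
        raise ValueError("smoothing expects a 5-min binned series")
    w = int(round(window_minutes / PROFILE_BIN_MINUTES))
    kernel = np.ones(w + 1)
    kernel[0] = kernel[-1] = 0.5
    ok = ~series.missing
    filled = np.where(ok, series.values, 0.0)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(ok.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(den > 0, num / den, np.nan)
    return MinuteSeries(series.timestamps, sm, series.channel)


def _bin_index(ts: pd.DatetimeIndex) -> np.ndarray:
    """5-min bin number from clock noon (0 .. 287) for each timestamp."""
    minutes_since_noon = (ts.hour.to_numpy() * 60 + ts.minute.to_numpy() - 12 * 60) % 1440
    return minutes_since_noon // PROFILE_BIN_MINUTES


def day_profile(series: MinuteSeries) -> DayProfile:
    """Average the (smoothed) 5-min series into a noon-anchored 24-h profile.

    Bin ``b`` is the mean over recording days of the non-missing values at
    clock offset ``5·b`` minutes after 12:00; contributing-day counts are
    recorded per bin.
    """
    if series.resolution_minutes != PROFILE_BIN_MINUTES:
        raise ValueError("day profile expects a 5-min binned series")
    if series.span_hours < 24:
        raise ValueError("day profile requires at least 24 h of data")
    bins = _bin_index(series.timestamps)
    values = np.full(N_PROFILE_BINS, np.nan)
    counts = np.zeros(N_PROFILE_BINS, dtype=int)
    ok = ~series.missing
    for b in range(N_PROFILE_BINS):
        sel = ok & (bins == b)
        counts[b] = int(sel.sum())
        if counts[b]:
            values[b] = series.values[sel].mean()
    if counts.sum() == 0:
        raise ValueError("all profile bins are empty")
    return DayProfile(values, counts, series.channel)


def split_days(series: MinuteSeries) -> list[np.ndarray]:
    """Per-day value blocks (288 bins each) from the subject's first noon.

    Used by the day-resampling bootstrap; trailing partial days are padded
    with NaN so every block has the full 288 bins.
    """
    if series.resolution_minutes != PROFILE_BIN_MINUTES:
        raise ValueError("day splitting expects a 5-min binned series")
    bins = _bin_index(series.timestamps)
    # index of the first sample at bin 0 (first noon); samples before it are
    # folded into a leading partial day
    days: list[np.ndarray] = []
    day = np.full(N_PROFILE_BINS, np.nan)
    started = False
    for v, b in zip(series.values, bins):
        if b == 0 and started:
            days.append(day)
            day = np.full(N_PROFILE_BINS, np.nan)
        day[b] = v
        started = True
    days.append(day)
    return days


def profile_from_days(days: list[np.ndarray], channel: str = "chest") -> DayProfile:
    """Rebuild a :class:`DayProfile` from per-day blocks (bootstrap helper)."""
    stack = np.vstack(days)
    counts = np.sum(~np.isnan(stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(stack, axis=0)
    return DayProfile(values, counts, channel)


def hourly_means(series: MinuteSeries) -> HourlySeries:
    """Hourly means with the 1-h imputation and 7-h segment-drop rules.

    Hours with any raw sample use the mean of the available samples.  Hours
    with none are linearly interpolated between the nearest observed hourly
    means and flagged as imputed.  A contiguous run of fully-missing hours
    longer than 7 h drops every calendar 24-h segment (counted from the
    subject's first noon) that the run touches: those hours are flagged
    not-retained and excluded downstream.
    """
    if series.span_hours < 24:
        raise ValueError("hourly means require at least 24 h of data")
    s = pd.Series(series.values, index=series.timestamps)
    hourly = s.resample("1h").mean()
    ts = pd.DatetimeIndex(hourly.index)
    values = hourly.to_numpy()
    observed = ~np.isnan(values)
    if observed.sum() < 2:
        raise ValueError("fewer than 2 observed hours")

    # contiguous fully-missing runs > 7 h drop the 24-h segment(s) they touch
    first_noon = ts[0].normalize() + pd.Timedelta(hours=12)
    if ts[0] > first_noon:
        first_noon += pd.Timedelta(hours=24)
    seg = np.floor(
        np.asarray((ts - first_noon) / pd.Timedelta(hours=24))
    ).astype(int)
    retained = np.ones(len(ts), dtype=bool)
    dropped_segments: set[int] = set()
    i = 0
    while i < len(ts):
        if not observed[i]:
            j = i
            while j < len(ts) and not observed[j]:
                j += 1
            if j - i > GAP_DROP_HOURS:
                dropped_segments.update(seg[i:j].tolist())
            i = j
        else:
            i += 1
    for sgmt in dropped_segments:
        retained[seg == sgmt] = False

    # linear imputation of fully-missing hours (flagged); dropped hours stay NaN
    imputed = ~observed & retained
    filled = pd.Series(values).interpolate(method="linear", limit_area="inside").to_numpy()
    out = values.copy()
    out[imputed] = filled[imputed]
    imputed &= ~np.isnan(out)  # edge hours with no neighbour stay missing
    out[~retained] = np.nan
    return HourlySeries(
        ts,
        out,
        imputed,
        retained,
        channel=series.channel,
        dropped_segments=sorted(dropped_segments),
    )


def preprocess_temperature(
    chest: MinuteSeries | None = None,
    pills: tuple[MinuteSeries, MinuteSeries] | None = None,
    ingestion_times: tuple | None = None,
    elimination_time_pill1=None,
    smooth: bool = True,
) -> dict:
    """Run the fixed pipeline for one subject's temperature channels.

    Returns a dict with, per available channel, the 5-min series, the
    (optionally) smoothed series, the day profile and the hourly means.
    ``smooth=False`` skips the 1-h moving average (useful when the unbiased
    harmonic content matters more than noise reduction).
    """
    out: dict = {}
    if chest is not None:
        masked = mask_nonphysiological(chest)
        b5 = bin_5min(masked)
        sm = smooth_moving_average(b5) if smooth else b5
        out["chest"] = {
            "series_5min": b5,
            "smoothed": sm,
            "profile": day_profile(sm),
            "hourly": hourly_means(masked),
        }
    if pills is not None:
        p1, p2 = pills
        if ingestion_times is not None:
            p1 = trim_pill_transients(p1, ingestion_times[0])
            p2 = trim_pill_transients(p2, ingestion_times[1])
        if elimination_time_pill1 is None:
            elimination_time_pill1 = p1.timestamps[-1]
        core = stitch_pills(p1, p2, elimination_time_pill1)
        b5 = bin_5min(core)
        sm = smooth_moving_average(b5) if smooth else b5
        out["core"] = {
            "series_5min": b5,
            "smoothed": sm,
            "profile": day_profile(sm),
            "hourly": hourly_means(core),
        }
    return out
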