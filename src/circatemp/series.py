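"""Core time-series containers shared by every pipeline stage.

Three containers mirror the three analysis products of the telemonitoring
pipeline: the raw/binned minute-resolution stream (:class:`MinuteSeries`),
the averaged 24-h day profile at 5-min resolution anchored at clock noon
(:class:`DayProfile`), and the gap-handled hourly means that feed spectral
analysis (:class:`HourlySeries`).

Missing samples are represented as ``NaN`` in ``values``; the boolean
``missing`` mask is always derived from that, so the two can never drift
apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: number of 5-min bins in one day profile
N_PROFILE_BINS = 288
#: minutes per profile bin
PROFILE_BIN_MINUTES = 5

TEMPERATURE_CHANNELS = ("chest", "core", "core_pill1", "core_pill2")
ACTIVITY_CHANNEL = "activity"
KNOWN_CHANNELS = TEMPERATURE_CHANNELS + (ACTIVITY_CHANNEL,)


@dataclass
class MinuteSeries:
    """Uniformly sampled sensor stream with wall-clock timestamps.

    Parameters
    ----------
    timestamps
        Strictly increasing, uniformly spaced local-clock datetimes.
    values
        Measurements (°C for temperature channels, accelerations/min for
        activity); ``NaN`` marks a missing sample.
    channel
        One of ``chest``, ``core``, ``core_pill1``, ``core_pill2``,
        ``activity``.
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    channel: str

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.timestamps):
            raise ValueError("values must be 1-D and match timestamps")
        if len(self.timestamps) >= 2:
            deltas = np.diff(self.timestamps.asi8)
            if deltas.min() <= 0:
                raise ValueError("timestamps must be strictly increasing")
            if deltas.max() != deltas.min():
                raise ValueError("timestamps must be uniformly spaced")
        if self.channel not in KNOWN_CHANNELS:
            raise ValueError(
                f"unknown channel {self.channel!r}; expected one of {KNOWN_CHANNELS}"
            )

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask, ``True`` where the sample is absent."""
        return np.isnan(self.values)

    @property
    def resolution_minutes(self) -> float:
        if len(self.timestamps) < 2:
            raise ValueError("resolution undefined for series shorter than 2 samples")
        return (self.timestamps[1] - self.timestamps[0]) / pd.Timedelta(minutes=1)

    @property
    def span_hours(self) -> float:
        """Time from first to one-past-last sample, in hours."""
        n = len(self.timestamps)
        if n == 0:
            return 0.0
        return n * self.resolution_minutes / 60.0 if n > 1 else 0.0

    @property
    def is_temperature(self) -> bool:
        return self.channel in TEMPERATURE_CHANNELS

    def clock_hours(self) -> np.ndarray:
        """Clock time of each sample in fractional hours of day [0, 24)."""
        ts = self.timestamps
        return (
            ts.hour.to_numpy()
            + ts.minute.to_numpy() / 60.0
            + ts.second.to_numpy() / 3600.0
        )

    def copy_with(self, values: np.ndarray) -> "MinuteSeries":
        return MinuteSeries(self.timestamps, np.array(values, dtype=float), self.channel)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self.timestamps, "value": self.values, "channel": self.channel}
        )

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class DayProfile:
    """Averaged 24-h cycle in 288 five-minute bins, bin 0 at clock noon.

    ``values[b]`` is the mean over recording days of the (smoothed) 5-min
    samples falling at clock offset ``b * 5`` minutes after 12:00;
    ``counts[b]`` records how many days contributed.
    """

    values: np.ndarray
    counts: np.ndarray
    channel: str = "chest"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.values.shape != (N_PROFILE_BINS,) or self.counts.shape != (N_PROFILE_BINS,):
            raise ValueError(f"day profile must have exactly {N_PROFILE_BINS} bins")

    @property
    def time_hours(self) -> np.ndarray:
        """Bin centers as hours elapsed since clock noon (0, 1/12, ...)."""
        return np.arange(N_PROFILE_BINS) * PROFILE_BIN_MINUTES / 60.0

    @property
    def clock_hours(self) -> np.ndarray:
        """Bin positions as clock hours of day in [0, 24)."""
        return (12.0 + self.time_hours) % 24.0

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(N_PROFILE_BINS),
                "clock_hour": self.clock_hours,
                "value": self.values,
                "n_days": self.counts,
            }
        )


@dataclass
class HourlySeries:
    """Hourly means with imputation and 24-h-segment retention flags.

    ``imputed[i]`` marks hours filled by linear interpolation (no raw sample
    in the hour); ``retained[i]`` is ``False`` for hours inside a dropped
    calendar 24-h segment (a contiguous missing run longer than 7 h).
    Dropped hours hold ``NaN`` and never reach the spectral stage.
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    imputed: np.ndarray
    retained: np.ndarray
    channel: str = "chest"
    dropped_segments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        self.retained = np.asarray(self.retained, dtype=bool)
        n = len(self.timestamps)
        if not (len(self.values) == len(self.imputed) == len(self.retained) == n):
            raise ValueError("hourly fields must share one length")

    @property
    def retained_hours(self) -> int:
        return int(np.sum(self.retained & ~np.isnan(self.values)))

    def retained_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(hours-since-start, values) for retained, non-NaN hours."""
        keep = self.retained & ~np.isnan(self.values)
        t = (self.timestamps.asi8 - self.timestamps.asi8[0]) / 3.6e12
        return t[keep], self.values[keep]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "value": self.values,
                "imputed": self.imputed,
                "retained": self.retained,
            }
        )
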