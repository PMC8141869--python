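"""Plain-text serialisation of pipeline products.

Sensor streams travel as long-format CSV (timestamp, value, channel);
profiles, hourly series, spectra and score tables as CSV with small JSON
sidecars for flags and scalars.  Everything round-trips losslessly at
float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cosinor import CosinorFit
from .series import DayProfile, HourlySeries, MinuteSeries
from .spectral import SpectrumEstimate


def write_series(series: MinuteSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_series(path, channel: str | None = None) -> MinuteSeries:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    if channel is not None:
        df = df[df["channel"] == channel]
        if df.empty:
            raise ValueError(f"no rows for channel {channel!r} in {path}")
    channels = df["channel"].unique()
    if len(channels) != 1:
        raise ValueError(f"expected one channel per read, found {list(channels)}")
    return MinuteSeries(
        pd.DatetimeIndex(df["timestamp"]), df["value"].to_numpy(), str(channels[0])
    )


def write_profile(profile: DayProfile, path) -> None:
    profile.to_frame().to_csv(path, index=False)


def read_profile(path, channel: str = "chest") -> DayProfile:
    df = pd.read_csv(path)
    return DayProfile(df["value"].to_numpy(), df["n_days"].to_numpy(), channel)


def write_hourly(hourly: HourlySeries, path) -> None:
    hourly.to_frame().to_csv(path, index=False)
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(
        json.dumps({"channel": hourly.channel, "dropped_segments": hourly.dropped_segments})
    )


def read_hourly(path) -> HourlySeries:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    sidecar = Path(path).with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return HourlySeries(
        pd.DatetimeIndex(df["timestamp"]),
        df["value"].to_numpy(),
        df["imputed"].to_numpy(dtype=bool),
        df["retained"].to_numpy(dtype=bool),
        channel=meta.get("channel", "chest"),
        dropped_segments=meta.get("dropped_segments", []),
    )


def write_fit(fit: CosinorFit, path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=1))


def read_fit(path) -> dict:
    return json.loads(Path(path).read_text())


def write_spectrum(spectrum: SpectrumEstimate, csv_path, json_path=None) -> None:
    pd.DataFrame(
        {
            "period_hours": spectrum.periods,
            "density": spectrum.density,
            "envelope_lo": spectrum.envelope_lo,
            "envelope_hi": spectrum.envelope_hi,
        }
    ).to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(
                {
                    "dominant_period": spectrum.dominant_period,
                    "dominant_class": spectrum.dominant_class.value,
                    "sgc": spectrum.sgc,
                    "n_hours": spectrum.n_hours,
                    "metadata": spectrum.metadata,
                },
                indent=1,
            )
        )
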