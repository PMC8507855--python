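"""CSV input/output for series and manual observations.

Series CSV: columns ``timestamp`` (ISO-8601) and ``value`` (°C, empty field =
missing); an optional ``mask`` column is written on request. Manual
observation CSV: sparse ``timestamp``/``value`` rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .series import MaskSeries, RegularSeries, build_mask


def read_series_csv(path) -> RegularSeries:
    df = pd.read_csv(path, parse_dates=["timestamp"], float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty series file")
    ts = pd.DatetimeIndex(df["timestamp"])
    if len(ts) > 1:
        steps = np.unique(np.diff(ts.asi8))
        if steps.size != 1:
            raise ValueError(f"{path}: timestamps are not regularly spaced")
        step = pd.Timedelta(int(steps[0]), unit="ns")
    else:
        step = pd.Timedelta(minutes=30)
    return RegularSeries(start_time=ts[0], values=df["value"].to_numpy(dtype=float),
                         step=step)


def write_series_csv(path, series: RegularSeries, mask: MaskSeries | None = None,
                     include_mask: bool = False) -> None:
    df = pd.DataFrame({"timestamp": series.timestamps(), "value": series.values})
    if include_mask:
        df["mask"] = (mask or build_mask(series)).bits
    df.to_csv(path, index=False, float_format="%.17g")


def read_manual_csv(path) -> pd.Series:
    df = pd.read_csv(path, parse_dates=["timestamp"], float_precision="round_trip")
    return pd.Series(df["value"].to_numpy(dtype=float),
                     index=pd.DatetimeIndex(df["timestamp"]), name="manual")


def write_manual_csv(path, manual: pd.Series) -> None:
    pd.DataFrame({"timestamp": manual.index, "value": manual.values}).to_csv(
        path, index=False, float_format="%.17g")
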