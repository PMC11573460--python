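"""Accelerometer-based grazing behavior.

Tri-axial acceleration (X surge, Y sway, Z heave, gravitational units) is
split into a static (gravity) and a dynamic component by subtracting a
centered running mean per axis. Overall dynamic body acceleration,

    ODBA = |dyn_x| + |dyn_y| + |dyn_z|,

averaged over fixed epochs, classifies each epoch as grazing (ODBA above
the threshold, default 0.1 g) or non-grazing; grazing epochs accumulate
into daily grazing time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "dynamic_component",
    "odba",
    "epoch_odba",
    "classify",
    "daily_grazing_time",
    "G_PER_MS2",
]

GRAZING_THRESHOLD_G = 0.1
G_PER_MS2 = 1.0 / 9.80665

AXES = ("ax", "ay", "az")


def _sample_rate(timestamps: np.ndarray) -> float:
    dt = np.diff(timestamps)
    if len(dt) == 0:
        raise ValueError("trace needs at least 2 samples")
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    return 1.0 / float(np.median(dt))


def dynamic_component(trace: pd.DataFrame, smoothing_window: float = 2.0) -> pd.DataFrame:
    """Dynamic (gravity-removed) acceleration per axis.

    The static component is estimated as a centered running mean over
    ``smoothing_window`` seconds (truncated at the trace edges, so the
    output has the input length) and subtracted from the raw signal.
    """
    missing = set(AXES) - set(trace.columns)
    if missing:
        raise ValueError(f"trace missing axis columns: {sorted(missing)}")
    ts = trace["timestamp"].to_numpy(dtype=float)
    rate = _sample_rate(ts)
    window = max(2, int(round(smoothing_window * rate)))
    if len(trace) < window:
        raise ValueError(
            f"trace of {len(trace)} samples shorter than smoothing window ({window} samples)"
        )
    out = trace[["timestamp"]].copy()
    for axis in AXES:
        static = trace[axis].rolling(window, center=True, min_periods=1).mean()
        out[axis] = trace[axis] - static
    return out


def odba(dynamic) -> np.ndarray:
    """Per-sample ODBA: sum of absolute dynamic accelerations over the 3 axes."""
    if isinstance(dynamic, pd.DataFrame):
        arr = dynamic[list(AXES)].to_numpy(dtype=float)
    else:
        arr = np.asarray(dynamic, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
    if arr.shape[1] != 3:
        raise ValueError("ODBA needs three aligned axes")
    return np.abs(arr).sum(axis=1)


def epoch_odba(
    trace: pd.DataFrame,
    smoothing_window: float = 2.0,
    epoch: float = 60.0,
) -> pd.DataFrame:
    """Mean ODBA per fixed epoch (default 60 s) for one animal's trace.

    Returns window_start, window_end (seconds) and the epoch-mean odba (g).
    """
    dyn = dynamic_component(trace, smoothing_window=smoothing_window)
    values = odba(dyn)
    ts = dyn["timestamp"].to_numpy(dtype=float)
    t0 = ts[0]
    bins = np.floor((ts - t0) / epoch).astype(int)
    df = pd.DataFrame({"bin": bins, "odba": values})
    agg = df.groupby("bin", sort=True)["odba"].mean()
    out = pd.DataFrame(
        {
            "window_start": t0 + agg.index.to_numpy() * epoch,
            "window_end": t0 + (agg.index.to_numpy() + 1) * epoch,
            "odba": agg.to_numpy(),
        }
    )
    # the trailing partial epoch ends at the last sample, not the bin edge
    out.loc[out.index[-1], "window_end"] = min(out["window_end"].iloc[-1], ts[-1] + (ts[-1] - ts[-2]))
    return out


def classify(series: pd.DataFrame, threshold: float = GRAZING_THRESHOLD_G) -> pd.DataFrame:
    """Label each ODBA window grazing / non-grazing at a strict threshold.

    Windows with ODBA exactly equal to the threshold are non-grazing (the
    tie policy for the measure-zero boundary case).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    out = series.copy()
    out["label"] = np.where(out["odba"] > threshold, "grazing", "non-grazing")
    return out


def daily_grazing_time(series: pd.DataFrame, day_window: tuple[float, float] | None = None) -> float:
    """Hours of grazing-labeled time, optionally clipped to a day window.

    ``series`` needs window_start, window_end and label columns; windows
    must not overlap.
    """
    s = series.sort_values("window_start")
    starts = s["window_start"].to_numpy(dtype=float)
    ends = s["window_end"].to_numpy(dtype=float)
    if np.any(ends[:-1] > starts[1:] + 1e-9):
        raise ValueError("behavior windows overlap")
    if day_window is not None:
        lo, hi = day_window
        starts = np.clip(starts, lo, hi)
        ends = np.clip(ends, lo, hi)
    grazing = (s["label"] == "grazing").to_numpy()
    return float(((ends - starts) * grazing).sum() / 3600.0)
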