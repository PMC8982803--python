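"""CGM series I/O, scaling, gap-aware windowing and chronological splits.

Continuous glucose monitors report interstitial glucose in mg/dl at a nominal
5-minute cadence.  Real streams contain gaps (sensor change, signal loss); this
module never imputes across a gap — a (history, target) training pair is only
emitted when every underlying sample is exactly one nominal step from its
neighbour, within a configurable timestamp tolerance.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

NOMINAL_STEP_SECONDS = 300.0
DEFAULT_SCALE = 0.01
DEFAULT_TOLERANCE_SECONDS = 60.0
DEFAULT_TS_FORMAT = "%d-%m-%Y %H:%M:%S"
GLUCOSE_MAX_MGDL = 600.0


@dataclass(frozen=True)
class GlucoseSeries:
    """A timestamped glucose trace for one patient, in mg/dl.

    Timestamps are strictly increasing; values lie in (0, 600].  Consecutive
    samples whose spacing deviates from the nominal 5 minutes mark a gap.
    """

    patient_id: str
    timestamps: np.ndarray  # datetime64[s], strictly increasing
    values: np.ndarray      # float64, mg/dl

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype="datetime64[s]")
        vals = np.asarray(self.values, dtype=np.float64)
        if ts.shape != vals.shape or ts.ndim != 1:
            raise ValueError("timestamps and values must be equal-length 1-D arrays")
        if len(ts) == 0:
            raise ValueError("empty glucose series")
        if len(ts) > 1 and not np.all(np.diff(ts).astype("timedelta64[s]").astype(np.int64) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise ValueError("glucose values must be finite")
        if np.any(vals <= 0) or np.any(vals > GLUCOSE_MAX_MGDL):
            raise ValueError("glucose values must lie in (0, 600] mg/dl")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def step_seconds(self) -> np.ndarray:
        """Interval between consecutive samples, in seconds (length n-1)."""
        return np.diff(self.timestamps).astype("timedelta64[s]").astype(np.float64)

    @classmethod
    def from_values(
        cls,
        values: Sequence[float],
        start: str = "2024-01-01T00:00:00",
        step_minutes: float = 5.0,
        patient_id: str = "synthetic",
    ) -> "GlucoseSeries":
        """Build a gap-free series on a regular grid from raw mg/dl values."""
        n = len(values)
        t0 = np.datetime64(start, "s")
        ts = t0 + (np.arange(n) * step_minutes * 60).astype("timedelta64[s]")
        return cls(patient_id=patient_id, timestamps=ts, values=np.asarray(values, float))


def read_ohio_xml(path: str | Path, ts_format: str = DEFAULT_TS_FORMAT) -> GlucoseSeries:
    """Read the CGM trace from an Ohio-T1DM-style patient XML file.

    The file carries a ``glucose_level`` element whose ``event`` children have
    ``ts`` and ``value`` attributes.  Events are returned sorted by time.
    Non-numeric or non-positive glucose values raise ``ValueError``.
    """
    path = Path(path)
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed XML in {path.name}: {exc}") from exc
    gl = root if root.tag == "glucose_level" else root.find(".//glucose_level")
    if gl is None:
        raise ValueError(f"no <glucose_level> element found in {path.name}")
    stamps: list[np.datetime64] = []
    vals: list[float] = []
    for ev in gl.findall("event"):
        ts_raw = ev.get("ts")
        val_raw = ev.get("value")
        if ts_raw is None or val_raw is None:
            raise ValueError(f"<event> missing ts/value attribute in {path.name}")
        try:
            stamp = pd.to_datetime(ts_raw, format=ts_format)
        except ValueError as exc:
            raise ValueError(f"unparseable timestamp {ts_raw!r} in <event>") from exc
        try:
            val = float(val_raw)
        except ValueError as exc:
            raise ValueError(f"non-numeric glucose value {val_raw!r} in <event>") from exc
        stamps.append(np.datetime64(stamp, "s"))
        vals.append(val)
    if not stamps:
        raise ValueError(f"no glucose events in {path.name}")
    order = np.argsort(np.asarray(stamps, dtype="datetime64[s]"), kind="stable")
    patient_id = root.get("id", path.stem)
    return GlucoseSeries(
        patient_id=patient_id,
        timestamps=np.asarray(stamps, dtype="datetime64[s]")[order],
        values=np.asarray(vals, float)[order],
    )


def read_csv(path: str | Path, patient_id: str | None = None) -> GlucoseSeries:
    """Read the plain CSV dialect (columns ``timestamp`` ISO-8601, ``value`` mg/dl)."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    pid = patient_id if patient_id is not None else Path(path).stem
    return GlucoseSeries(
        patient_id=pid,
        timestamps=df["timestamp"].to_numpy().astype("datetime64[s]"),
        values=df["value"].to_numpy(float),
    )


def write_csv(series: GlucoseSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"timestamp": pd.to_datetime(series.timestamps).strftime("%Y-%m-%dT%H:%M:%S"),
         "value": series.values}
    ).to_csv(path, index=False)


def scale(values: np.ndarray | GlucoseSeries, factor: float = DEFAULT_SCALE) -> np.ndarray:
    """Scale mg/dl values into the order-1 range used for training (x 0.01)."""
    vals = values.values if isinstance(values, GlucoseSeries) else np.asarray(values, float)
    return vals * factor


def unscale(values: np.ndarray, factor: float = DEFAULT_SCALE) -> np.ndarray:
    """Inverse of :func:`scale` (x 100 for the default factor)."""
    return np.asarray(values, float) / factor


@dataclass
class WindowedDataset:
    """Gap-validated (history, target) pairs for supervised forecasting.

    ``X`` holds scaled history rows (oldest first, ``h`` columns); ``y`` the
    scaled target ``d`` nominal steps past the last history sample.
    ``target_raw`` keeps the unscaled mg/dl target for metric reporting.
    """

    X: np.ndarray                   # (n, h) scaled
    y: np.ndarray                   # (n,) scaled
    target_raw: np.ndarray          # (n,) original units
    history_len: int                # h, samples
    horizon_steps: int              # d, nominal steps
    scale: float = 1.0
    target_times: np.ndarray | None = None  # (n,) datetime64[s] or None
    patient_ids: np.ndarray | None = None   # (n,) object/str or None

    def __len__(self) -> int:
        return len(self.y)

    @property
    def last_history_raw(self) -> np.ndarray:
        """Last observed value of each window, back in original units."""
        return self.X[:, -1] / self.scale


def window_values(
    values: np.ndarray,
    history_len: int,
    horizon_steps: int,
    scale_factor: float = 1.0,
) -> WindowedDataset:
    """Window a gap-free, regularly sampled value array (waveforms etc.)."""
    values = np.asarray(values, float)
    h, d = int(history_len), int(horizon_steps)
    if h < 1 or d < 1:
        raise ValueError("history_len and horizon_steps must be positive")
    span = h + d
    n = len(values)
    if n < span:
        return WindowedDataset(
            X=np.empty((0, h)), y=np.empty(0), target_raw=np.empty(0),
            history_len=h, horizon_steps=d, scale=scale_factor,
        )
    win = np.lib.stride_tricks.sliding_window_view(values, span)
    return WindowedDataset(
        X=win[:, :h] * scale_factor,
        y=win[:, -1] * scale_factor,
        target_raw=win[:, -1].copy(),
        history_len=h,
        horizon_steps=d,
        scale=scale_factor,
    )


def make_windows(
    series: GlucoseSeries,
    history_minutes: int,
    horizon_minutes: int,
    tolerance_seconds: float = DEFAULT_TOLERANCE_SECONDS,
    scale_factor: float = DEFAULT_SCALE,
) -> WindowedDataset:
    """Build gap-validated (history, target) pairs from a glucose series.

    A window uses the ``h = history_minutes/5`` most recent samples ending at
    prediction time ``t`` and targets the sample ``d = horizon_minutes/5``
    nominal steps later.  It is emitted only when all ``h + d`` underlying
    samples are pairwise 5 minutes apart within ``tolerance_seconds``; windows
    spanning a gap are dropped, never filled.  A series shorter than ``h + d``
    samples yields an empty dataset.
    """
    for name, m in (("history_minutes", history_minutes), ("horizon_minutes", horizon_minutes)):
        if m <= 0 or m % 5 != 0:
            raise ValueError(f"{name} must be a positive multiple of 5, got {m}")
    if tolerance_seconds < 0:
        raise ValueError("tolerance_seconds must be non-negative")
    h = history_minutes // 5
    d = horizon_minutes // 5
    span = h + d
    n = len(series)
    empty = WindowedDataset(
        X=np.empty((0, h)), y=np.empty(0), target_raw=np.empty(0),
        history_len=h, horizon_steps=d, scale=scale_factor,
        target_times=np.empty(0, dtype="datetime64[s]"),
        patient_ids=np.empty(0, dtype=object),
    )
    if n < span:
        return empty
    ok = np.abs(series.step_seconds - NOMINAL_STEP_SECONDS) <= tolerance_seconds
    # window starting at s spans intervals s .. s+span-2; valid iff all ok
    ok_run = np.lib.stride_tricks.sliding_window_view(ok, span - 1).all(axis=1)
    starts = np.flatnonzero(ok_run)
    if len(starts) == 0:
        return empty
    win = np.lib.stride_tricks.sliding_window_view(series.values, span)[starts]
    t_idx = starts + span - 1
    return WindowedDataset(
        X=win[:, :h] * scale_factor,
        y=win[:, -1] * scale_factor,
        target_raw=win[:, -1].copy(),
        history_len=h,
        horizon_steps=d,
        scale=scale_factor,
        target_times=series.timestamps[t_idx],
        patient_ids=np.full(len(starts), series.patient_id, dtype=object),
    )


def concat_windows(datasets: Sequence[WindowedDataset]) -> WindowedDataset:
    """Pool window datasets (e.g. across patients) into one."""
    datasets = [d for d in datasets if len(d) > 0] or list(datasets[:1])
    first = datasets[0]
    for d in datasets[1:]:
        if (d.history_len, d.horizon_steps, d.scale) != (
            first.history_len, first.horizon_steps, first.scale
        ):
            raise ValueError("cannot pool windows with mismatched geometry or scaling")
    have_times = all(d.target_times is not None for d in datasets)
    have_ids = all(d.patient_ids is not None for d in datasets)
    return WindowedDataset(
        X=np.concatenate([d.X for d in datasets]),
        y=np.concatenate([d.y for d in datasets]),
        target_raw=np.concatenate([d.target_raw for d in datasets]),
        history_len=first.history_len,
        horizon_steps=first.horizon_steps,
        scale=first.scale,
        target_times=np.concatenate([d.target_times for d in datasets]) if have_times else None,
        patient_ids=np.concatenate([d.patient_ids for d in datasets]) if have_ids else None,
    )


@dataclass(frozen=True)
class SplitSpec:
    """Ordered chronological split proportions (per patient, before pooling)."""

    fractions: tuple[float, ...] = (0.6, 0.2, 0.2)

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.fractions)
        if any(f <= 0 for f in fr):
            raise ValueError("split fractions must be positive")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {sum(fr)}")
        object.__setattr__(self, "fractions", fr)


def chronological_split(series: GlucoseSeries, spec: SplitSpec) -> list[GlucoseSeries]:
    """Cut a series into contiguous chronological segments by sample count.

    All but the last segment get ``floor(fraction * n)`` samples; the last
    takes the remainder.  Windowing is applied after splitting, so no training
    pair ever straddles a split boundary.
    """
    n = len(series)
    counts = [int(np.floor(f * n)) for f in spec.fractions[:-1]]
    counts.append(n - sum(counts))
    if any(c <= 0 for c in counts):
        raise ValueError(f"split {spec.fractions} of {n} samples leaves an empty segment")
    out: list[GlucoseSeries] = []
    start = 0
    for c in counts:
        out.append(
            GlucoseSeries(
                patient_id=series.patient_id,
                timestamps=series.timestamps[start : start + c],
                values=series.values[start : start + c],
            )
        )
        start += c
    return out
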