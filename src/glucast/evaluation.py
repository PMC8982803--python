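"""Forecast metrics: RMSE, persistence baseline, surveillance-error-grid risk,
risk-zone classification, glycemic variability, and cross-patient aggregation.

The surveillance error grid (SEG) is a clinically derived risk surface over
(reference, predicted) glucose pairs on [0, 600] mg/dl with risk values in
[0, 4].  Scoring a prediction bilinearly interpolates the 600 x 600 grid; the
surveillance error SE of a prediction set is the mean interpolated risk.  The
authentic clinical matrix is external data: this module loads any delimited
numeric matrix of the right shape, and ships analytic grids for testing only.

Summary rows across patients use the arithmetic mean and the population
(divide-by-N) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .cgm_data import GlucoseSeries, NOMINAL_STEP_SECONDS, WindowedDataset

SEG_MAX_CONC = 600.0
SEG_MAX_RISK = 4.0


def rmse(predictions: Sequence[float], targets: Sequence[float]) -> float:
    """Root-mean-squared error, in the units of its inputs."""
    p = np.asarray(predictions, float)
    t = np.asarray(targets, float)
    if p.shape != t.shape:
        raise ValueError("predictions and targets must have equal lengths")
    if p.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((p - t) ** 2)))


def t0_baseline(dataset: WindowedDataset) -> np.ndarray:
    """Persistence forecast: predict the last observed value of each window.

    Returned in original (unscaled) units, matching ``dataset.target_raw``.
    """
    return dataset.last_history_raw


def t0_rmse(dataset: WindowedDataset) -> float:
    """RMSE of the persistence baseline on a window set, original units."""
    return rmse(t0_baseline(dataset), dataset.target_raw)


@dataclass(frozen=True)
class SEGrid:
    """A square clinical-risk surface over (reference, prediction) pairs.

    ``risk[i, j]`` is the risk at reference concentration ``coords[i]`` and
    predicted concentration ``coords[j]``.  With the default "span" node
    convention an n-node axis places nodes at ``i * 600/(n-1)`` so they span
    [0, 600] exactly; the alternate "unit" convention puts node i at i mg/dl.
    """

    risk: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        risk = np.asarray(self.risk, float)
        coords = np.asarray(self.coords, float)
        if risk.ndim != 2 or risk.shape[0] != risk.shape[1]:
            raise ValueError("risk matrix must be square")
        if risk.shape[0] != len(coords):
            raise ValueError("coords length must match grid size")
        if np.any(risk < 0) or np.any(risk > SEG_MAX_RISK):
            raise ValueError("risk values must lie in [0, 4]")
        object.__setattr__(self, "risk", risk)
        object.__setattr__(self, "coords", coords)

    @classmethod
    def from_array(cls, risk: np.ndarray, spacing: str = "span") -> "SEGrid":
        n = np.asarray(risk).shape[0]
        if spacing == "span":
            coords = np.linspace(0.0, SEG_MAX_CONC, n)
        elif spacing == "unit":
            coords = np.arange(n, dtype=float)
        else:
            raise ValueError("spacing must be 'span' or 'unit'")
        return cls(risk=risk, coords=coords)

    @classmethod
    def from_text(cls, path: str | Path, delimiter: str | None = None,
                  spacing: str = "span") -> "SEGrid":
        """Load a delimited numeric risk matrix (e.g. the 600 x 600 SEG)."""
        return cls.from_array(np.loadtxt(path, delimiter=delimiter), spacing=spacing)

    @classmethod
    def constant(cls, value: float, n: int = 16) -> "SEGrid":
        """Synthetic flat grid for testing."""
        return cls.from_array(np.full((n, n), float(value)))

    @classmethod
    def from_function(cls, fn, n: int = 16, spacing: str = "span") -> "SEGrid":
        """Synthetic grid sampled from ``fn(reference, prediction)``."""
        coords = (np.linspace(0.0, SEG_MAX_CONC, n) if spacing == "span"
                  else np.arange(n, dtype=float))
        cy, cp = np.meshgrid(coords, coords, indexing="ij")
        return cls(risk=fn(cy, cp), coords=coords)

    @cached_property
    def _interp(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            (self.coords, self.coords), self.risk, method="linear", bounds_error=True
        )


def seg_risk(y: float | np.ndarray, y_hat: float | np.ndarray, grid: SEGrid):
    """Clinical risk of predicting ``y_hat`` when the reference is ``y``.

    Bilinear interpolation of the four surrounding grid nodes; exact node
    coordinates return the node value.  Inputs outside the grid domain raise.
    """
    y_arr = np.asarray(y, float)
    yh_arr = np.asarray(y_hat, float)
    lo, hi = grid.coords[0], grid.coords[-1]
    if np.any(y_arr < lo) or np.any(y_arr > hi) or np.any(yh_arr < lo) or np.any(yh_arr > hi):
        raise ValueError(f"concentrations must lie within [{lo}, {hi}] mg/dl")
    pts = np.stack([np.broadcast_to(y_arr, np.broadcast_shapes(y_arr.shape, yh_arr.shape)),
                    np.broadcast_to(yh_arr, np.broadcast_shapes(y_arr.shape, yh_arr.shape))],
                   axis=-1)
    out = grid._interp(pts.reshape(-1, 2)).reshape(pts.shape[:-1])
    return float(out) if np.isscalar(y) and np.isscalar(y_hat) else out


def surveillance_error(predictions, references, grid: SEGrid) -> float:
    """Mean interpolated SEG risk: SE = (1/T) * sum_t e(y_t, yhat_t)."""
    p = np.asarray(predictions, float)
    r = np.asarray(references, float)
    if p.shape != r.shape or p.size == 0:
        raise ValueError("predictions and references must be equal-length, non-empty")
    return float(np.mean(seg_risk(r, p, grid)))


def clamp_prediction(y_hat, low: float = 0.0, high: float = SEG_MAX_CONC):
    """Constrain predictions to the SEG domain, flagging out-of-range values.

    Returns ``(clipped, flagged)``; ``flagged`` marks values that were moved.
    NaN inputs raise (they cannot be meaningfully constrained).
    """
    arr = np.asarray(y_hat, float)
    if np.any(np.isnan(arr)):
        raise ValueError("NaN prediction cannot be clamped")
    clipped = np.clip(arr, low, high)
    flagged = (arr < low) | (arr > high)
    if np.isscalar(y_hat):
        return float(clipped), bool(flagged)
    return clipped, flagged


@dataclass(frozen=True)
class RiskZones:
    """Thresholds partitioning [0, 4] into none / mild / moderate / high."""

    thresholds: tuple[float, float, float] = (0.5, 1.5, 2.5)
    labels: tuple[str, str, str, str] = ("none", "mild", "moderate", "high")

    def __post_init__(self) -> None:
        t = self.thresholds
        if not (0.0 < t[0] < t[1] < t[2] < SEG_MAX_RISK):
            raise ValueError("thresholds must be strictly increasing within (0, 4)")


def risk_zone(risk, zones: RiskZones = RiskZones()):
    """Bin a risk value into a zone; bins are right-open, top bin closed at 4."""
    arr = np.asarray(risk, float)
    if np.any(arr < 0) or np.any(arr > SEG_MAX_RISK):
        raise ValueError("risk must lie in [0, 4]")
    idx = np.digitize(arr, zones.thresholds, right=False)
    labels = np.asarray(zones.labels, dtype=object)[idx]
    return str(labels) if np.isscalar(risk) else labels


def excursion_rate(
    series: GlucoseSeries,
    threshold: float = 10.0,
    tolerance_seconds: float = 60.0,
) -> float:
    """Percentage of 5-minute first differences with |delta| > threshold mg/dl.

    Differences are only taken across valid nominal steps; steps spanning a
    gap are skipped.  Raises if no valid difference exists.
    """
    if len(series) < 2:
        raise ValueError("need at least two samples")
    ok = np.abs(series.step_seconds - NOMINAL_STEP_SECONDS) <= tolerance_seconds
    diffs = np.diff(series.values)[ok]
    if len(diffs) == 0:
        raise ValueError("no valid 5-minute first differences in series")
    return float(100.0 * np.mean(np.abs(diffs) > threshold))


def mean_and_std(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and population (divide-by-N) standard deviation."""
    arr = np.asarray(values, float)
    if arr.size == 0:
        raise ValueError("empty input")
    return float(np.mean(arr)), float(np.std(arr, ddof=0))


def summarize(df: pd.DataFrame, value_cols: Sequence[str],
              label_col: str = "patient_id") -> pd.DataFrame:
    """Append mean and population-std summary rows to a per-patient table."""
    out = df.copy()
    mu_row = {label_col: "mean"}
    sd_row = {label_col: "std"}
    for col in value_cols:
        m, s = mean_and_std(df[col].to_numpy())
        mu_row[col] = m
        sd_row[col] = s
    return pd.concat([out, pd.DataFrame([mu_row, sd_row])], ignore_index=True)
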