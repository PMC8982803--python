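"""Synthetic signals: square-wave noise experiments and a CGM-like surrogate.

The three waveform experiments isolate what kind of uncertainty a Gaussian
NLL forecaster can learn.  The base signal is a square wave with step length
20 samples alternating between -1 and 1:

* ``deterministic`` — the clean wave; a model that identifies the phase can
  predict it exactly, so predicted sigma should collapse.
* ``measurement-noise`` — i.i.d. N(0, 0.3^2) added to every sample; the future
  state is still determined by the history, so the NLL-optimal predicted
  sigma is the observation noise scale 0.3 everywhere.
* ``state-length-noise`` — state durations drawn from N(20, 3^2); the timing
  of the next transition is irreducibly uncertain, so predicted sigma should
  rise near state changes and stay low mid-state.

The CGM surrogate emulates the *structure* of a real sensor trace (mg/dl
range, 5-minute cadence, meal-like excursions, dropout gaps) so the data
pipeline is testable without the restricted clinical dataset.  It makes no
claim of physiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cgm_data import GlucoseSeries

WAVE_PRESETS = ("deterministic", "measurement-noise", "state-length-noise")


@dataclass(frozen=True)
class WaveformSpec:
    """Square-wave generator settings (defaults mirror the noise experiments)."""

    n_samples: int
    step_len: int = 20
    levels: tuple[float, float] = (-1.0, 1.0)
    measurement_noise_sd: float = 0.0   # 0.3 in the measurement-noise preset
    state_len_sd: float = 0.0           # 3.0 in the state-length-noise preset
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.step_len < 1:
            raise ValueError("step_len must be >= 1")
        if self.levels[0] == self.levels[1]:
            raise ValueError("levels must be distinct")
        if self.measurement_noise_sd < 0 or self.state_len_sd < 0:
            raise ValueError("noise scales must be non-negative")


def square_wave(spec: WaveformSpec) -> np.ndarray:
    """Deterministic square wave: sample t is ``levels[(t // step_len) % 2]``."""
    t = np.arange(spec.n_samples)
    idx = (t // spec.step_len) % 2
    return np.asarray(spec.levels, float)[idx]


def add_measurement_noise(
    values: np.ndarray, sd: float = 0.3, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Add i.i.d. N(0, sd^2) noise to every sample; reproducible given seed."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    values = np.asarray(values, float)
    if sd == 0:
        return values.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return values + rng.normal(0.0, sd, size=values.shape)


def state_length_noise_wave(spec: WaveformSpec) -> np.ndarray:
    """Square wave whose state durations are drawn from N(step_len, state_len_sd^2).

    Durations are rounded to the nearest integer and clamped to at least one
    sample; states alternate between the two levels starting at ``levels[0]``.
    With ``state_len_sd == 0`` this reduces to :func:`square_wave`.
    """
    if spec.state_len_sd == 0:
        return square_wave(spec)
    rng = np.random.default_rng(spec.seed)
    out = np.empty(spec.n_samples)
    pos = 0
    state = 0
    while pos < spec.n_samples:
        dur = max(1, int(np.rint(rng.normal(spec.step_len, spec.state_len_sd))))
        out[pos : pos + dur] = spec.levels[state]
        pos += dur
        state ^= 1
    return out


def generate_waveform(spec: WaveformSpec) -> np.ndarray:
    """Dispatch on the spec: state-length noise first, then measurement noise."""
    base = state_length_noise_wave(spec) if spec.state_len_sd > 0 else square_wave(spec)
    if spec.measurement_noise_sd > 0:
        # separate stream so the duration draws are unaffected by this knob
        base = add_measurement_noise(base, spec.measurement_noise_sd, spec.seed + 1)
    return base


def waveform_preset(name: str, n_samples: int, seed: int = 0) -> WaveformSpec:
    """The three named experiment setups."""
    if name == "deterministic":
        return WaveformSpec(n_samples=n_samples, seed=seed)
    if name == "measurement-noise":
        return WaveformSpec(n_samples=n_samples, measurement_noise_sd=0.3, seed=seed)
    if name == "state-length-noise":
        return WaveformSpec(n_samples=n_samples, state_len_sd=3.0, seed=seed)
    raise ValueError(f"unknown preset {name!r}; choose from {WAVE_PRESETS}")


@dataclass(frozen=True)
class SurrogateCGMSpec:
    """Mean-reverting glucose surrogate with meal bumps and sensor gaps.

    ``mean_level`` is the long-run glucose level (mg/dl); ``reversion`` the
    per-step pull toward it; ``noise_sd`` the per-step process noise (mg/dl);
    meals arrive as a Bernoulli event per step adding an exponentially
    decaying excursion; gaps remove whole runs of samples.
    """

    n_samples: int = 2000
    mean_level: float = 140.0
    reversion: float = 0.05
    noise_sd: float = 2.0
    meal_rate: float = 0.01          # events per 5-min step (~3 meals/day)
    meal_magnitude: float = 60.0     # peak excursion, mg/dl
    meal_decay: float = 0.97         # per-step decay of the excursion state
    gap_rate: float = 0.002          # gap starts per step
    gap_mean_len: float = 12.0       # mean gap length, samples (1 hour)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name in ("reversion", "noise_sd", "meal_rate", "meal_magnitude",
                     "gap_rate", "gap_mean_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def surrogate_cgm(spec: SurrogateCGMSpec, patient_id: str = "surrogate") -> GlucoseSeries:
    """Generate a CGM-like series at exact 5-minute cadence with gaps removed.

    Values are clipped into (0, 600] mg/dl.  Fully deterministic given seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    base = np.empty(n)
    g = spec.mean_level
    excursion = 0.0
    for t in range(n):
        if rng.random() < spec.meal_rate:
            excursion += spec.meal_magnitude
        excursion *= spec.meal_decay
        g = g + spec.reversion * (spec.mean_level - g) + rng.normal(0.0, spec.noise_sd)
        base[t] = g + excursion
    values = np.clip(base, 20.0, 600.0)

    keep = np.ones(n, dtype=bool)
    if spec.gap_rate > 0:
        t = 0
        while t < n:
            if rng.random() < spec.gap_rate:
                gap_len = 1 + rng.poisson(max(spec.gap_mean_len - 1, 0.0))
                keep[t : t + gap_len] = False
                t += gap_len
            else:
                t += 1
        if not keep.any():  # degenerate draw; keep at least one sample
            keep[0] = True

    t0 = np.datetime64("2024-01-01T00:00:00", "s")
    timestamps = t0 + (np.arange(n) * 300).astype("timedelta64[s]")
    return GlucoseSeries(
        patient_id=patient_id,
        timestamps=timestamps[keep],
        values=values[keep],
    )
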