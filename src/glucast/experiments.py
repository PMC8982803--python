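"""End-to-end runners for the square-wave noise experiments.

Each experiment generates a waveform, splits it chronologically into
train / validation / test segments (60/20/20), windows each segment without
scaling (the signal is already order-1), trains the LSTM-Gaussian model on
the NLL, and summarizes the predictive distribution on the held-out segment:

* test RMSE of the predicted mean,
* mean predicted sigma,
* mean predicted sigma near state transitions vs. mid-state,
* mean predicted mean over targets in the upper waveform state.

The default history is 24 samples with a 6-step horizon.  With a step length
of 20, a 24-sample window always spans at least one state transition, so the
phase of the clean wave is identifiable from every history window — a
requirement for the deterministic experiment to be solvable at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cgm_data import WindowedDataset, window_values
from .evaluation import rmse
from .model import ModelConfig, forward
from .synthetic import WaveformSpec, generate_waveform, waveform_preset
from .training import TrainConfig, TrainResult, fast_model_config, fast_train_config, train

NOISE_HISTORY = 24   # samples; spans >= 1 transition for step length 20
NOISE_HORIZON = 6    # steps ahead
TRANSITION_NEAR = 3  # "near a state change": within 3 samples
TRANSITION_MID = 8   # "mid-state": at least 8 samples from any change


@dataclass
class NoiseExperimentResult:
    preset: str
    test_rmse: float
    mean_sigma: float
    sigma_near_transition: float   # NaN when the segment has no transitions
    sigma_mid_state: float
    upper_state_mean_mu: float     # NaN when no target sits exactly on a level
    n_test: int
    train_result: TrainResult


def split_windows(
    values: np.ndarray,
    history_len: int,
    horizon_steps: int,
    fractions: tuple[float, ...] = (0.6, 0.2, 0.2),
) -> tuple[list[WindowedDataset], list[np.ndarray]]:
    """Chronological split of a gap-free array, windowed per segment.

    Returns the window sets and the raw value segments (same order).  Windows
    are built after splitting, so none straddles a segment boundary.
    """
    n = len(values)
    counts = [int(np.floor(f * n)) for f in fractions[:-1]]
    counts.append(n - sum(counts))
    segments, datasets, start = [], [], 0
    for c in counts:
        seg = values[start : start + c]
        segments.append(seg)
        datasets.append(window_values(seg, history_len, horizon_steps))
        start += c
    return datasets, segments


def _transition_distances(segment: np.ndarray, target_idx: np.ndarray) -> np.ndarray:
    """Distance (samples) from each target position to the nearest level change."""
    trans = np.flatnonzero(np.diff(segment) != 0) + 1
    if len(trans) == 0:
        return np.full(len(target_idx), np.inf)
    return np.min(np.abs(target_idx[:, None] - trans[None, :]), axis=1)


def run_noise_experiment(
    preset: str,
    n_samples: int = 4000,
    seed: int = 0,
    history_len: int = NOISE_HISTORY,
    horizon_steps: int = NOISE_HORIZON,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
) -> NoiseExperimentResult:
    """Run one waveform experiment end to end and summarize the test set."""
    spec: WaveformSpec = waveform_preset(preset, n_samples, seed)
    values = generate_waveform(spec)
    (tr, va, te), (_, _, te_seg) = split_windows(values, history_len, horizon_steps)
    if min(len(tr), len(va), len(te)) == 0:
        raise ValueError("waveform too short for the requested windows and split")

    mc = model_config or fast_model_config(history_len, horizon_steps)
    tc = train_config or fast_train_config(seed=seed)
    result = train(mc, tr, va, tc)
    pred = forward(te.X, result.params, mc)

    upper = max(spec.levels)
    on_level = te.y == upper
    upper_mu = float(np.mean(pred.mu[on_level])) if on_level.any() else float("nan")

    # target of window i sits at local index i + h + d - 1 within the segment
    t_idx = np.arange(len(te)) + history_len + horizon_steps - 1
    dist = _transition_distances(te_seg, t_idx)
    near = dist <= TRANSITION_NEAR
    mid = dist >= TRANSITION_MID
    sigma_near = float(np.mean(pred.sigma[near])) if near.any() else float("nan")
    sigma_mid = float(np.mean(pred.sigma[mid])) if mid.any() else float("nan")

    return NoiseExperimentResult(
        preset=preset,
        test_rmse=rmse(pred.mu, te.y),
        mean_sigma=float(np.mean(pred.sigma)),
        sigma_near_transition=sigma_near,
        sigma_mid_state=sigma_mid,
        upper_state_mean_mu=upper_mu,
        n_test=len(te),
        train_result=result,
    )
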