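import numpy as np
import pytest

from glucast.cgm_data import GlucoseSeries
from glucast.experiments import run_noise_experiment

EXPERIMENT_N = 3000
EXPERIMENT_SEED = 1


@pytest.fixture(scope="session")
def deterministic_run():
    """Model trained on the clean square wave (shared across tests)."""
    return run_noise_experiment("deterministic", n_samples=EXPERIMENT_N,
                                seed=EXPERIMENT_SEED)


@pytest.fixture(scope="session")
def measurement_noise_run():
    """Model trained on the wave with N(0, 0.3^2) observation noise."""
    return run_noise_experiment("measurement-noise", n_samples=EXPERIMENT_N,
                                seed=EXPERIMENT_SEED)


@pytest.fixture(scope="session")
def state_length_noise_run():
    """Model trained on the wave with N(20, 3^2) state durations."""
    return run_noise_experiment("state-length-noise", n_samples=EXPERIMENT_N,
                                seed=EXPERIMENT_SEED)


def random_gapped_series(rng: np.random.Generator, n: int,
                         gap_prob: float = 0.08) -> GlucoseSeries:
    """Regular 5-minute series with random intervals stretched into gaps."""
    steps = np.full(n - 1, 300, dtype=np.int64)
    gaps = rng.random(n - 1) < gap_prob
    steps[gaps] += rng.integers(120, 7200, size=int(gaps.sum()))
    ts = np.datetime64("2024-03-01T00:00:00", "s") + np.concatenate(
        [[0], np.cumsum(steps)]
    ).astype("timedelta64[s]")
    values = rng.uniform(60, 300, size=n)
    return GlucoseSeries(patient_id="rand", timestamps=ts, values=values)


def brute_force_window_starts(series: GlucoseSeries, h: int, d: int,
                              tolerance_seconds: float = 60.0) -> list[int]:
    """Enumerate every start offset whose h+d samples are consecutive 5-min steps."""
    sec = series.timestamps.astype("int64")
    span = h + d
    out = []
    for s in range(len(series) - span + 1):
        if all(abs(sec[i + 1] - sec[i] - 300) <= tolerance_seconds
               for i in range(s, s + span - 1)):
            out.append(s)
    return out
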