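# Methods

## Model

The forecaster maps a window of recent glucose history to a univariate
Gaussian predictive distribution over the glucose level a fixed horizon
ahead. The history (one scalar per 5-minute step, mg/dl scaled by 0.01 so
values are order 1) is read by an LSTM; the cell output at the final step is
fed through two rectified-linear dense layers (default 512 and 256 units,
dropout 20% and 30% during training), and two output heads read the last
dense activation h_fc:

    mu    = W1 h_fc + b1             (linear head)
    sigma = exp(W2 h_fc + b2)        (exponential head, so sigma > 0)

Training minimizes the mean Gaussian negative log-likelihood

    L = (1/k) * sum_i -log N(y_i | mu_i, sigma_i^2)

with Adam (default learning rate 1e-3, batch size 1024). The NLL objective is
what makes the second head meaningful: for a fixed residual r the pointwise
loss is minimized at sigma = |r|, and for a pool of residuals the optimal
constant sigma is their root mean square, so a converged model's sigma
estimates the conditional spread of the target given the history. Both facts
are pinned by search-oracle tests.

The LSTM uses the standard gate equations (input/forget/output sigmoid gates,
tanh candidate, c_t = i*u + f*c_{t-1}, h_t = o*tanh(c_t)), input dimension 1.
Dropout is applied only after the dense hidden layers, never inside the
recurrence, and only during training; inference is a pure function of
(history, parameters).

### Implementation and numerics

The network, backpropagation through time and Adam are implemented directly
in NumPy (float64). Exactness of the analytic gradients is enforced by a
finite-difference check in the test suite (agreement to 1e-5 scaled, away
from ReLU kinks, where the loss is not differentiable and a finite-difference
comparison is meaningless). Other numerical choices:

* the sigma head predicts log(sigma) internally, clamped to [-10, 10] before
  a single exponentiation, keeping the loss finite for any parameters (the
  gradient is zeroed on the clamp boundary);
* gradients are globally norm-clipped at 100 by default: late in training on
  near-deterministic data sigma collapses and the 1/sigma^2 factor in the
  NLL gradient can spike on a single batch;
* initialization is Glorot-uniform for input/dense weights, per-gate
  orthogonal for recurrent weights, zero biases except the forget gate
  bias, which starts at 1 (configurable) so early training does not flush
  the cell memory. The initialization scheme is a package choice; only the
  seed protocol matters for reproducibility.

Given a seed, training is bit-reproducible in single-threaded mode: one
generator drives initialization, batch shuffling and dropout.

## Data handling

CGM input is the Ohio-style patient XML (a `glucose_level` element with
`event` children carrying `ts` and `value` attributes; timestamp format
configurable, default `DD-MM-YYYY HH:MM:SS`) or a plain CSV dialect
(ISO-8601 timestamp, mg/dl value). Values must lie in (0, 600] mg/dl.

Windowing is gap-aware and never imputes: a training pair (h history
samples ending at prediction time, target d nominal steps later) is emitted
only when all h+d underlying samples are pairwise 5 minutes apart within a
tolerance (default 60 s around the nominal 300 s, to absorb real sensor
timestamp jitter while still treating any dropped sample as a gap). On a
gap-free series of n samples this yields exactly n - h - d + 1 pairs; the
implementation is checked against brute-force enumeration on random gapped
series. Splits are chronological by sample count (floor for all but the
last segment, remainder to the last), applied per patient before pooling,
and windows are built after splitting so none straddles a boundary.

## Evaluation

* RMSE in mg/dl (windows are unscaled before metric computation).
* Persistence baseline ("t0"): predict the last observed value. On a random
  walk with step sd s and horizon d its RMSE is s*sqrt(d), a closed form
  used as a test oracle.
* Surveillance error: the mean of a clinical risk surface e(y, y_hat) in
  [0, 4], obtained by bilinear interpolation of a 600x600 grid over
  (reference, prediction) concentrations in [0, 600] mg/dl. The authentic
  clinical matrix is distributed under its own terms and is not shipped;
  the module loads any delimited numeric matrix, and the tests use analytic
  grids (constant and affine surfaces, which bilinear interpolation must
  reproduce exactly). Grid nodes map to concentrations i*600/(n-1) by
  default ("span"); a 1-mg/dl-per-node convention ("unit") is selectable.
  Predictions outside [0, 600] are constrained (clipped) by default with
  the count reported, keeping the number of evaluated points fixed;
  discarding is available to the caller by masking on the returned flags.
* Risk zones none/mild/moderate/high partition [0, 4] at 0.5/1.5/2.5
  (right-open bins, top bin closed). The four category names are standard;
  the numeric bounds are package defaults and configurable.
* Glycemic variability: percentage of valid 5-minute first differences
  exceeding 10 mg/dl in magnitude; differences across gaps are skipped.
  For Gaussian increments N(0, s^2) the expected rate is 2*(1 - Phi(10/s)),
  used as a test oracle.
* Cross-patient summary rows use the arithmetic mean and the population
  (divide-by-N) standard deviation. The convention is pinned by
  reproducing, to three decimals, the published six-patient summary cells
  (30-min RMSE mean 18.867 / std 1.794, 60-min mean 31.403, baseline
  30-min mean 22.432, SE mean 0.186 / std 0.047); the sample convention
  does not reproduce them.

## Synthetic experiments

The waveform experiments probe what kind of uncertainty the Gaussian head
can learn. The base signal is a square wave, step length 20 samples, levels
-1 and 1. Three presets:

* `deterministic` — the clean wave. The future is a deterministic function
  of the phase, so a successful model drives RMSE toward 0 and sigma
  collapses.
* `measurement-noise` — adds i.i.d. N(0, 0.3^2) to every sample. The future
  *state* is still identified by the history, but the observed target
  carries irreducible observation noise, so the NLL-optimal prediction has
  sigma = 0.3 everywhere. A trained model's mean predicted sigma should
  recover 0.3.
* `state-length-noise` — state durations drawn from N(20, 3^2) (rounded to
  the nearest integer, clamped to >= 1 sample; rounding bias is negligible
  at these parameters). Transition timing is irreducibly uncertain and the
  uncertainty grows near a state change, so predicted sigma should peak
  near transitions ("near" = within 3 samples of a level change;
  "mid-state" = at least 8 samples away) and stay low mid-state.

Experiment protocol: the waveform is split chronologically 60/20/20 into
train / early-stopping / test segments, each windowed independently, and the
model is trained on the NLL; all summary quantities are measured on the test
segment. Waveforms bypass the x0.01 scaling (they are already order 1).

The history window for these experiments is 24 samples with a 6-step
horizon. The history must exceed the 20-sample step length: a shorter
window (e.g. 12 samples) can lie entirely inside one state, in which case
the phase — and hence the upcoming transition — is not identifiable from
the input and the deterministic task cannot be solved to near-zero error by
any predictor. 24 samples guarantee every window spans at least one
transition while keeping the sequence short.

### Desk-scale profile

The published protocol (256 LSTM units, 512/256 dense, batch 1024, up to
10,000 epochs, patience 200, 30-100 seeds) is available through the
configuration objects, but the default experiment and test runs use a
reduced profile chosen to converge in minutes on one CPU core: 32 LSTM
units, 64/32 dense layers without dropout, learning rate 3e-3, batch 256,
at most 300 epochs with patience 30. On the waveform tasks this profile
reaches the same qualitative regime (near-zero RMSE on the clean wave,
sigma ~= 0.3 under measurement noise); dropout is omitted because the small
network on ample stationary synthetic data does not overfit. Tests train on
3,000-sample waveforms; `scripts/acceptance.py` uses 20,000 samples.

## CGM surrogate

The surrogate stream exists so the data pipeline (XML/CSV I/O, gap
handling, splitting, CLI) is testable without the access-restricted
clinical dataset. It is a mean-reverting process around 140 mg/dl with
exponentially decaying meal-like excursions (~3 events/day, 60 mg/dl
magnitude), per-step noise of 2 mg/dl, and sensor gaps created by deleting
runs of samples (about one gap start per 500 steps, mean length 1 h),
clipped into (0, 600]. It reproduces the *structure* of real CGM data
(cadence, range, gaps), not its physiology: no insulin or carbohydrate
dynamics, no diurnal rhythm, no sensor drift or quantization. Passing tests
on the surrogate therefore validate the machinery, not clinical accuracy.

## Known limitations

* Per-patient clinical scores cannot be reproduced without the restricted
  dataset; the package verifies the aggregation conventions on the
  published summary cells and substitutes closed-form oracles (random-walk
  baseline, Gaussian excursion tail) for the data-dependent quantities.
* The Gaussian head cannot distinguish sensor error from physiological
  variability; it reports total conditional spread.
* The authentic surveillance-error-grid matrix must be supplied by the
  user; shipped grids are synthetic and for testing only.
* Whether the published per-patient "±" spreads over seeds use the sample
  or population convention is not decidable from the summary rows alone;
  only the cross-patient rows (population) are pinned.
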