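# Methods

## Problem setting

Automatic weather stations record temperature every 30 minutes (48 slots per
day). Equipment failures can knock a station out for weeks, leaving a
contiguous gap of `m` whole days in the machine record. At many field sites a
human observer still reads a thermometer three times a day — morning, midday
and evening — and those low-frequency readings are available inside the gap.
The task is to reconstruct the full half-hourly series across the gap from
(a) the complete machine record on either side and (b) the three daily
"anchor" readings inside it.

Internally a slot index runs 0–47 from 00:00; the default anchor slots are
{16, 27, 39}, i.e. 08:00, 13:30 and 19:30 local time. Manual readings are
mapped onto the machine scale by an affine calibration fitted by ordinary
least squares on a period where both channels exist (the two instruments are
assumed linearly related; the calibration defaults to the identity when the
channels are already commensurate).

## The BiLSTM-I imputer

One sequence step is one day, represented as a 48-vector; a training or
inference window spans `w = m + 2s` days — `s` fully observed days of
context on each side of the `m` anchor-only days (defaults m = 30 or 60,
s = 14).

**Encoder.** Each direction of the bidirectional encoder is an LSTM-I cell.
At step `t` the previous hidden state is first projected to an input-space
estimate

    x̃_t = W_x h_{t−1} + b_x

which is substituted into the input at masked positions,

    x_tᶜ = x_t ⊙ m_t + (1 − m_t) ⊙ x̃_t,

and the LSTM then updates on the completed vector: `h_t = LSTM(x_tᶜ, h_{t−1})`.
The forward and backward hidden sequences are concatenated per step,
`h_t = [h→_t, h←_t]`.

**Decoder.** A second LSTM consumes the encoded sequence step by step,
`s_t = LSTM(h_t, s_{t−1})`, and an affine head emits the imputed day,
`y_t = W_y s_t + b_y`. (An alternative design would pool the encoder output
into a single context vector; the step-by-step decoder was chosen because it
preserves the day alignment between encoder and decoder and needs no
attention mechanism.)

**Objective.** Training windows are cut from fully observed stretches, with
the middle `m` days artificially reduced to the anchor pattern, so ground
truth exists at every hidden position. The loss is

    L = l_f + l_b + l_y,

where `l_f` and `l_b` are the mean absolute errors of the forward and
backward encoder estimates `x̃_t` and `l_y` is the mean absolute error of
the decoder output, all three scored **only at the artificially hidden
positions** (`loss_mask = 1 − input_mask` inside the window's gap days).
Scoring at hidden positions rather than observed ones is deliberate: the
estimate at an observed position never influences the substituted input
(masked-substitution identity), so an observed-position error term would
train a head whose output is discarded, while the hidden-position error is
exactly the quantity the imputer is judged on. Each term is normalized by
the number of scored entries so the loss scale is independent of `m` and the
batch size.

**Training.** Values are z-scored by the training-set mean/sd and
denormalized before any metric is computed. Optimization is Adam (lr 1e-3,
batch 16) for at most 200 epochs with early stopping (patience 20) on a
held-out 10 % window split; hidden size is 64 per encoder direction and 64
in the decoder. Initial hidden/cell states are zero, so the first-step
estimate equals `b_x` — an accepted boundary effect. All parameter
initialization and batch shuffling derive from one integer seed; training is
exactly reproducible.

The models are implemented on the package's own reverse-mode autodiff tape
(`gapfill.autodiff`), a small NumPy-based engine providing exactly the
primitives the sequence models need. Its gradients are validated
operation-by-operation and end-to-end against central finite differences.

## The BRITS-I baseline

Two unidirectional RITS-I recurrences, forward and backward. Each maintains
a per-slot lag vector δ_t (steps since that slot was last observed) and a
temporal-decay factor

    γ_t = exp(−max(0, W_γ δ_t + b_γ)) ∈ (0, 1],

which multiplies the hidden state before the estimate `x̂_t = W_x h + b_x`
is formed and substituted as in LSTM-I. The final estimate is the mean of
the forward and backward estimates; the loss adds the two directional
estimation errors and a consistency term (mean absolute forward/backward
discrepancy at all positions). BiLSTM-I deliberately omits the decay factor:
its substitution estimate is refreshed every step from the hidden state, so
the lag information adds nothing at day granularity.

## Kalman-smoothing baselines

Both baselines are linear-Gaussian state-space models

    a_t = T a_{t−1} + R η_t,   η_t ~ N(0, Q)
    y_t = Z a_t + ε_t,         ε_t ~ N(0, H)

filtered forward (missing observations skip the measurement update) and
smoothed backward with the Rauch–Tung–Striebel recursion; a missing y_t is
imputed by `Z a_{t|n}` with variance `Z P_{t|n} Zᵀ + H`.

* **Kalman-Struct** uses the basic structural model: local linear trend
  (level + slope) plus a dummy-seasonal component whose values over one
  period sum to white noise. For half-hourly data the natural seasonal
  period is the daily cycle, s = 48 (state dimension 49); smaller periods
  (s = 4, s = 2) are supported and used in the exactness tests. The four
  disturbance variances are estimated by L-BFGS-B on log-variances against
  the prediction-error-decomposition likelihood, from fixed documented
  starting values (fractions of the sample variance), so refits are
  deterministic.
* **Kalman-ARIMA** represents ARIMA(p, d, q) in Harvey companion form
  (state dimension max(p, q+1), plus one integration state per difference).
  Coefficients are fitted by `statsmodels` SARIMAX (which shares the same
  prediction-error MLE) and the order is selected by AIC over a small grid;
  the fitted coefficients are then placed into the package's own state space
  so imputation always flows through the same smoother that is verified
  against the brute-force joint-Gaussian oracle.

Numerical choices: diffuse initialization is approximated by `P0 = 1e7·I`
with `a0 = 0` (ARMA cores instead use their exact stationary covariance);
predicted covariances are symmetrized each step; a singular predicted
covariance in the backward pass is ridge-stabilized with a warning. Short
gaps (≤ 48 slots by default) anywhere in a series can be prefilled by the
same smoothing machinery before windowing, leaving long gaps untouched.

## Synthetic weather generator

Real paired manual/machine station records are generally not
redistributable, so all experiments run on simulated series:

    truth(t) = mean + A_annual·sin(2π·day/365.25)
                     + A_diurnal·sin(2π·(slot − phase)/48) + d_t
    d_t = φ d_{t−1} + ε_t (shared AR(1) at the half-hour step,
                           stationary initialization)
    machine(t) = truth(t) + N(0, σ_obs²)
    manual(day, anchor) = truth + bias + N(0, σ_manual²)

Defaults emulate a humid subtropical site: mean 22 °C, annual half-amplitude
6 °C, diurnal half-amplitude 4 °C peaking mid-afternoon (phase 17 slots),
φ = 0.95 and innovation sd 0.6 °C (stationary weather-deviation sd ≈ 1.9 °C,
decorrelating over ~10 h), machine noise sd 0.2 °C, manual bias 0.3 °C and
manual noise sd 0.2 °C, over 730 days. The generator reproduces the
features the imputers rely on — nested periodicity, persistent autocorrelated
deviations, a linear manual/machine relation — but *not* weather fronts,
rain events, asymmetric diurnal shapes or heteroscedastic sensor error.
Results on it validate the machinery and the relative ordering of methods,
not absolute accuracy on any real station.

Two consequences worth stating. First, with these defaults the AR(1)
deviation carries genuinely unpredictable variance between anchor readings
(~5.5 h apart), so no method can push the gap RMSE much below ≈1 °C on this
generator; the interesting quantities are the margins between methods and
the cross-gap stability, which are scale-free. Second, the generator's truth
(level + seasonal cycle + AR noise) lies close to the basic structural
model's own class, so the Kalman baselines are unusually strong here and
their ordering relative to each other and to the learned imputers need not
match what heavier-tailed real station data produces; the comparison
harness therefore computes and reports explicit ordering flags for every
run instead of assuming one.

## Evaluation protocol

Metrics are RMSE, MAE, MRE and the Pearson correlation, computed at the
artificially hidden positions only (anchor slots, being observed, are
excluded), pooling all scored positions of a gap rather than averaging
per-day metrics. Because °C values can approach zero, positions with
|truth| < 0.5 °C are excluded from MRE only and counted in the report; the
default generator never produces such values.

The reference study (`gapfill.replication.run_study`, also behind
`scripts/acceptance.py`) simulates two years, injects a 30- and a 60-day
gap starting at day 440 (second summer), calibrates and inserts the manual
anchors, trains BiLSTM-I and BRITS-I on rolling windows (stride 2) cut from
the gap-free stretch left of the gap, fits both Kalman baselines, fills the
same gap with every method plus the climatological time-of-day mean and
straight-line interpolation, and scores all of them at the identical hidden
positions. The cross-gap stage applies each trained BiLSTM-I to the other
gap length — the architecture is sequence-length agnostic — and reports the
mismatched/matched RMSE ratio. The study caps training at 60 epochs
(patience 8) and fits the Kalman variance/coefficient MLEs on 28-day data
slices with a 56-day smoothing context per side; these sizes were chosen
once as the study's conditions and converge comfortably for this generator.

## Known limitations

* Univariate series on a regular grid only; no timezone/DST arithmetic.
* The ARIMA order grid is small (p, q ≤ 3, d ≤ 1 at most) and order
  selection is by AIC only.
* Diffuse initialization is the large-κ approximation, not an exact diffuse
  filter; log-likelihood contributions of the first few steps are therefore
  approximate for integrated models.
* MRE is undefined near 0 °C and is reported with exclusions rather than
  winsorized.
* The soft expectation that BiLSTM-I outperforms BRITS-I is a stochastic
  ordering across seeds, not a guarantee for any single seed.
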