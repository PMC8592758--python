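# Methods

## Problem and model

Surface EMG (sEMG) is a weak (microvolt), nonstationary bioelectric signal
whose useful energy lies roughly between 10 and 500 Hz. Recordings carry
time-varying, statistically unknown noise from electrodes, motion and
environment. The approach implemented here combines two ingredients:

1. **Autoregressive (AR) dynamics.** The signal is modelled as
   AR(n): `x_t = φ₁x_{t−1} + … + φₙx_{t−n} + ε_t`, with white innovation
   `ε_t ~ N(0, σ_ε²)`. Coefficients are estimated by ordinary least squares
   on the lagged design matrix (normal equations), with residual variance
   `σ_ε² = RSS/(N−n)`. The order is chosen by minimising information
   criteria over candidate orders:
   `AIC(n) = N ln σ² + 2n`, `BIC(n) = N ln σ² + n ln N`,
   `FPE(n) = ((N+n)/(N−n)) σ²`.

2. **Adaptive Kalman filtering.** AR fits of *every* order 1..n to the same
   signal are stacked into an n-dimensional state-space model

   - `A[i,j] = φ_{i,j}` for `j ≤ i` (lower triangular; row i holds the
     order-i coefficients),
   - `Q = diag(σ_ε1², …, σ_εn²)`,
   - `H = (φ_{n,1}, …, φ_{n,n})`,
   - `R = σ_εn²`,

   so state component i is the order-i model's running estimate of the
   signal. The filter runs the standard predict/update recursion with two
   adaptive mechanisms layered on top:

   - **Strong tracking.** The predicted covariance is inflated,
     `P_{k|k−1} = λ_k A P_{k−1} A' + Q_k`, by a fading factor computed from
     the smoothed innovation outer product
     `V0(k) = (ρ V0(k−1) + V_k²)/(1+ρ)` via
     `λ_k = max(tr(N_k)/tr(M_k), 1)` with
     `N_k = V0(k) − H Q_{k−1} H' − β R_k` and `M_k = H A P_{k−1} A' H'`.
     When innovations are consistent with the model, `E[N_k] ≈ M_k`, so λ
     hovers at its clamp; model mismatch drives λ above 1 and re-weights
     recent observations.
   - **Sage-Husa noise estimation (Q only).** The process-noise covariance
     is re-estimated with forgetting weights `d_k = (1−b)/(1−b^{k+1})`:
     `Q_k = (1−d_k)Q_{k−1} + d_k (K_{k−1} V_k² K_{k−1}' + A P_{k−1} A')`,
     with R held at its initial value. The joint Q-and-R estimator is
     implemented behind `adapt_R` but disabled by default: estimating both
     simultaneously is known to be unreliable and can destroy the positive
     definiteness of R. Note the update's additive `A P A'` term makes the
     estimator conservative (it biases tr(Q) upward relative to the
     filtered steady state); the strong-tracking clamp compensates in the
     combined variant.

   Variants: `KF` (λ≡1, fixed Q,R), `SHKF` (Q adapted), `STKF` (λ only),
   `STSHKF` (both — the denoiser of interest), and `RTS` (plain KF forward
   pass refined by a fixed-interval Rauch–Tung–Striebel backward pass, for
   offline use).

The denoised output is defined as `H·x̂_k` (plus the removed signal mean):
the observation row applied to the filtered state. After the update this is
a gain-weighted blend of the AR model-group prediction and the measurement,
which is the behaviour a denoiser needs. The state components have no other
canonical read-out; this choice is a modelling decision, documented rather
than implied.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `n` | selected | AR/state order; typical optima for sEMG are 3–4 |
| `n_max` | 10 | order-search upper bound (small orders with headroom) |
| `b` | 0.97 | forgetting factor, conventional range 0.95–0.99; `d_k → 1−b` |
| `rho` | 0.95 | innovation-covariance memory in the fading factor |
| `beta` | 1.0 | softening of R in the fading numerator (≥ 1 damps λ) |
| `x0` | mean of first n samples | initial state (every component) |
| `P0` | `10·var(signal)·I` | diffuse-ish initial covariance |
| `Q0`, `R0` | assembled Q, R | initial noise covariances |

`rho` and `beta` have no canonical values in the literature for this
construction; the defaults were fixed once as mild smoothing (ρ close to 1)
and no softening (β = 1), and both are exposed in `FilterConfig`.

The order-selection rule reports all three criterion columns and picks the
majority vote of their argmins, ties toward the smaller order. AIC and FPE
are near-equivalent and often outvote BIC by one or two orders on long
signals; users who want BIC's consistency can read it off the returned
table.

## Numerical choices

- **Joseph-form update** `P = (I−KH)P(I−KH)' + KRK'` with explicit
  symmetrisation `(P+P')/2` each step keeps P symmetric PSD in all
  variants; this is asserted per-step in the tests.
- Mean-centring before AR fitting (the model has no intercept); the mean is
  stored on the model and restored on the denoised output. `center=False`
  is available for signals satisfying an exact zero-intercept recurrence.
- Degeneracy guards: `σ² = 0` is floored at `1e−15·var(signal)` before
  logs; zero Q-diagonal entries at `1e−12·var(signal)`; condition number of
  `X'X` above `1e12` raises a rank-deficiency error; `tr(M_k) ≤ 0` forces
  λ = 1 with a logged warning; a non-positive innovation variance falls
  back to λ = 1 and R₀ for that step; a singular predicted covariance in
  the smoother falls back to the pseudo-inverse.
- Step indexing: the first measurement is k = 0 and `d_k` uses exponent
  k+1, so d₀ = 1 (the first innovation is fully trusted). In float64 the
  strictly decreasing sequence d_k saturates exactly at 1−b once `b^{k+1}`
  underflows (k ≈ 745 for b = 0.95); the tests verify strict monotonicity
  in exact rational arithmetic and the float path against it.
- Q adaptation starts at the second step (it needs the previous gain).

## Synthetic data

No public sEMG recordings accompany the method, so the package generates
its own study conditions:

- **AR processes** (`generate_ar_signal`) for parameter-recovery and
  filter-consistency tests: exact recurrence with Gaussian innovations,
  10·p-sample burn-in, stationarity enforced via the companion-matrix
  spectral radius.
- **sEMG-like bursts** (`generate_semg_like`): Gaussian noise band-passed
  to 20–450 Hz (zero-phase 4th-order Butterworth — the "band-limited"
  property matters, the exact filter shape does not), amplitude-modulated
  by raised-cosine activation bursts (2–4 per 2000 samples at 1000 Hz,
  mimicking repeated wrist-movement epochs) over a 10% resting floor so no
  segment is exactly silent, scaled to ~100 µV burst peaks.
- **Noise injection** (`add_noise_at_snr`): band-limited Gaussian noise
  scaled so the realised SNR equals the target exactly (checked to
  ±0.01 dB across the 5–30 dB grid).

What this emulates: sampling rate, spectral support, burst-like amplitude
modulation, microvolt scale, controlled noise levels. What it does not:
motor-unit action-potential shapes, recruitment/firing statistics,
electrode artefacts, power-line interference, or the heavier-tailed
amplitude distribution of real sEMG. Passing tests therefore demonstrate
the estimator and filter machinery under controlled conditions consistent
with the acquisition protocol, not clinical performance on real
recordings; published benchmark numbers from proprietary recordings are
not reproducible here and are not asserted anywhere.

## Problem sizes

Defaults throughout tests and the acceptance script: 2000-sample signals
at 1000 Hz (one movement epoch), 20 noise realisations per condition,
50 seeded draws for recovery/smoother statistics, N = 5000–10000 for
asymptotic AR estimates. These sizes give stable statistics (rates move by
well under the asserted margins across seeds) while keeping a full run in
tens of seconds.

## Known limitations

- The Sage-Husa Q update as implemented biases tr(Q) upward (see above);
  the plain `SHKF` variant consequently over-smooths less than expected
  and can underperform `STSHKF` on bursty signals.
- With β = 1 the fading factor clamps at 1 on only ~¾ of steps even for a
  perfectly consistent model (the ratio fluctuates around 1 by
  construction); raise β to damp spurious inflation.
- `MAPE` excludes samples with |clean| below 0.1% of the peak; it is still
  dominated by small-amplitude samples and is best read comparatively.
- The local-similarity score is a windowed Pearson-correlation mean
  (window 64, hop 32), a simplification of shaping-regularised local
  similarity maps used elsewhere in the denoising literature.
- The filter is causal but the implementation is batch; no streaming API.
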