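# arkalman

Adaptive Kalman denoising of surface-EMG-like signals through
autoregressive state-space models.

Surface electromyography (sEMG) is a microvolt-level, nonstationary
bioelectric signal (useful band roughly 10–500 Hz) whose noise is
time-varying and statistically unknown, which defeats filters that need
fixed noise covariances. `arkalman` addresses this for researchers and
engineers working with single-channel biosignals: it learns the signal's
own dynamics from the noisy recording and filters with noise statistics
estimated online.

## Method

1. **AR modelling.** Fit AR(n) models
   `x_t = φ₁x_{t−1} + … + φₙx_{t−n} + ε_t` by least squares; pick the
   order by minimising `AIC(n) = N ln σ² + 2n`,
   `BIC(n) = N ln σ² + n ln N`, `FPE(n) = ((N+n)/(N−n))σ²`.
2. **State-space lifting.** Stack the fits of orders 1..n into
   `X_{t+1} = A X_t + w`, `Z_t = H X_t + v`, with lower-triangular A (row
   i = order-i coefficients), `Q = diag(σ_ε1², …, σ_εn²)`, `H` the order-n
   coefficient row, `R = σ_εn²`.
3. **Adaptive filtering.** A Kalman filter with a strong-tracking fading
   factor `λ_k = max(tr(N_k)/tr(M_k), 1)` inflating the predicted
   covariance, and a Sage-Husa recursion
   `Q_k = (1−d_k)Q_{k−1} + d_k(K_{k−1}V_k²K_{k−1}' + A P_{k−1}A')` with
   forgetting weights `d_k = (1−b)/(1−b^{k+1})` updating the process
   noise online (R stays fixed). Variants: plain `KF`, `SHKF` (Q
   adaptation only), `STKF` (fading only), `STSHKF` (both), and `RTS`
   (KF + Rauch–Tung–Striebel smoother, offline). The denoised signal is
   `H·x̂_k`.

Evaluation metrics: RMSE, output SNR (dB), MAPE (%, amplitude-floored)
and a windowed-correlation local-similarity mean. Seeded generators
provide AR processes, burst-like band-limited sEMG surrogates (1000 Hz,
20–450 Hz) and noise injection at exact target SNRs (5–30 dB grid).
See `docs/methods.md` for assumptions, parameter meanings and
limitations.

## Worked example

```python
import arkalman as ak

clean = ak.generate_semg_like(N=2000, fs=1000.0, seed=7)   # burst-like surrogate
noisy, _ = ak.add_noise_at_snr(clean, ak.NoiseSpec(snr_db=5.0, seed=42))
result = ak.denoise(noisy, variant="STSHKF", n=4)
report = ak.evaluate(clean, result.denoised)

print(f"input SNR : {ak.snr_db(clean, noisy):.2f} dB")
print(f"output SNR: {report.snr_db:.2f} dB")
print(f"RMSE      : {report.rmse:.2f} uV")
print(f"local sim : {report.local_similarity_mean:.3f}")
```

prints

```
input SNR : 5.00 dB
output SNR: 6.38 dB
RMSE      : 10.12 uV
local sim : 0.570
```

The filter raised the SNR of a heavily polluted (5 dB) recording by
~1.4 dB on this single draw (the 20-seed mean improvement is ~2.5 dB);
RMSE is in the signal's microvolt units, and the local-similarity mean
near 0.6 says the denoised trace stays locally correlated with the clean
one through the activation bursts.

The same pipeline is scriptable from the shell:

```sh
arkalman simulate --kind semg --N 2000 --seed 7 --out clean.txt
arkalman evaluate clean.txt --variants STSHKF,STKF --n 4 \
    --snr-grid 5,10,15,20,25,30 --seeds 20 --out results.tsv --pivot
```

which writes a long-format table (one row per variant × SNR × seed, plus
per-condition means) mirroring the usual denoising evaluation grids, and
`arkalman denoise --variant STSHKF --n 4 noisy.txt --out den.txt` denoises
a recording of your own (text, one sample per line, optional `# fs=`
header).

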