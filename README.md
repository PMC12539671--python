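# armbr

Blink-artifact detection and removal for multichannel EEG by
artifact-reference multivariate backward regression.

Eye blinks add 50–100 µV monophasic deflections to scalp EEG, strongest
frontally and conducted into every channel.  `armbr` removes them with
minimal user input — just the names of a few blink-affected channels
(e.g. `Fp1`, `Fp2`):

1. average those channels into a blink reference `B_ref`;
2. binarize it into a mask `B_mask(n) = 1{B_ref(n) > T₀}`, with
   `T₀ = Q₂ + α₀ ν` built from robust quantiles
   (`ν = (Q_0.841 − Q_0.159)/2`) and the multiplier `α₀` selected
   automatically by maximizing the 1–8 Hz / 8–40 Hz band-power ratio of
   the extracted blink component;
3. solve the backward least-squares problem `[X, 1] W* = B_mask` for a
   spatial filter `Ŵ` (rescaled so `XŴ` has unit variance), giving the
   spatial pattern `Â = ΣŴ` and the oblique projector
   `M_purge = I − ŴŴᵀΣ`;
4. clean by a single matrix product, `X_purged = X M_purge`.

Because the cleaning map is per-sample linear, a model fitted on one
stretch of data can be applied to streamed chunks with output identical
to batch processing.  High-voltage non-blink transients are screened out
beforehand by a derivative-based 15 s segment rejection.  The package
also ships a seeded synthetic-scene generator with exact ground truth
(`S = S_clean + S_blink`) and the usual evaluation metrics (RMSE, SNR,
Pearson ρ, semi-normalized `R = Cov(X, X_purged)/Var(X)`, band-wise PSD
RMAE), so the whole pipeline is testable without any recorded data.

See `docs/methods.md` for the model, its assumptions and the numerical
choices.

## Worked example

```python
import numpy as np
from armbr import make_scene, fit_and_purge, metric_report, snr_db

scene = make_scene(C=32, fs=128.0, duration_s=60.0, rate_per_min=20.0,
                   peak_uV=100.0, background_rms_uV=10.0, seed=0)
model, result, mask = fit_and_purge(scene.mixed, ["Fp1", "Fp2"], alpha0="auto")
print(f"alpha0* = {mask.alpha0:.1f},  T0* = {mask.threshold:.1f} uV,  "
      f"{len(mask.intervals(128.0))} blink intervals detected "
      f"({len(scene.blink_intervals)} planted)")

rep = metric_report(scene.clean, result.purged, blink_affected=["Fp1", "Fp2"])
before = snr_db(scene.clean.data[:, 0], scene.mixed.data[:, 0])
print(f"Fp1: SNR {before:.2f} -> {rep.per_channel['Fp1']['snr']:.2f} dB,  "
      f"rmse {rep.per_channel['Fp1']['rmse']:.2f} uV,  "
      f"pearson {rep.per_channel['Fp1']['pearson']:.3f}")
```

prints

```
alpha0* = 2.9,  T0* = 24.1 uV,  25 blink intervals detected (20 planted)
Fp1: SNR -2.67 -> 3.08 dB,  rmse 4.92 uV,  pearson 0.870
```

The automatic sweep picks `α₀* = 2.9`, placing the threshold at 24 µV —
above the background reference distribution, below every 100 µV blink
peak (25 mask runs for 20 planted blinks: a few pulses are split by
near-threshold dips).  Cleaning raises Fp1's SNR, the log
standard-deviation ratio of clean signal to residual error, by ~5.8 dB,
i.e. the amplitude error on the most contaminated channel drops almost
4-fold; less-affected channels are barely touched and end up with a mean
SNR of ~12 dB.

## Command line

```bash
armbr synth --channels 32 --duration 60 --rate 20 --seed 7 --out-prefix scene
armbr clean --input scene_mixed.csv --fs 128 --blink-channels Fp1,Fp2 \
            --alpha auto --output purged.csv --save-model model.json \
            --mask-out mask.csv --sweep-out sweep.csv
armbr apply --input more_data.csv --fs 128 --model model.json --output purged2.csv
armbr evaluate --clean scene_clean.csv --contaminated scene_mixed.csv \
               --purged purged.csv --fs 128 --report metrics.csv
```

`clean` accepts EDF/BDF/FIF or delimited text (label header row; `--fs`
required for text), `--alpha auto|<float>`, and a YAML `--config` whose
keys mirror the flags.  Failures exit non-zero with a one-line
machine-parsable reason (`armbr-error reason=missing-channel: ...`).

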