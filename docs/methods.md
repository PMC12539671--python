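# Methods

## The problem

Eye blinks produce large (50–100 µV) positive monophasic deflections in
scalp EEG, strongest over frontal electrodes and attenuating toward the
back of the head.  They contaminate every channel through volume
conduction and can dwarf the brain signal of interest.  `armbr` removes
them by estimating the one-dimensional spatial subspace the blink
occupies and projecting it out, using only a list of blink-affected
channel labels as prior knowledge.

## The model

Let `X` be the `N × C` data matrix (microvolts, one column per channel).
The method assumes the recording is a linear mixture `X = s aᵀ + R`,
where `s(n)` is the blink source time course, `a` its scalp projection
(spatial pattern), and `R` everything else, with `s` uncorrelated with
the remaining sources.  The pipeline:

1. **Blink reference.** `B_ref(n)` = mean of the designated
   blink-affected channels (default `Fp1`, `Fp2`).  If the reference is
   left-skewed (negative sample third moment) it is negated, so blinks
   always occupy the right tail.
2. **Robust statistics.** Empirical quantiles `Q_a` (0.159), `Q_2`
   (median), `Q_b` (0.841), and the scale `ν = (Q_b − Q_a)/2`, which
   equals σ for a Gaussian but ignores isolated outliers.
3. **Mask.** `B_mask(n) = 1` iff `B_ref(n) > T₀`, with
   `T₀ = Q_2 + α₀ ν`.  The binarization deliberately discards amplitude
   information; it regularizes the regression that follows.
4. **Backward regression.** Solve `[X, 1] W* = B_mask` by least squares
   (SVD; minimum-norm pseudo-inverse with a warning if the design is
   rank-deficient).  The ones column absorbs any DC offset.  Strip the
   intercept and rescale each filter column so `X Ŵ` has unit
   (population) variance on the training data.
5. **Pattern and purge.** `Â = Σ Ŵ` with `Σ` the (centered, population)
   sensor covariance of the training rows; `M_purge = I − Ŵ Ŵᵀ Σ`.
   The unit-variance rescale makes `Ŵᵀ Σ Ŵ = I`, so `M_purge` is an
   idempotent oblique projector, the purged data `X_purged = X M_purge`
   satisfy `X_purged Ŵ = 0`, and the rank of full-rank training data
   drops by exactly `P` (the number of reference components; `P = 1`
   for blinks).
6. **Streaming.** `M_purge` acts row-wise, so a fitted model applied to
   arbitrary chunks reproduces the batch result bit-for-bit
   (`apply_pretrained`).

The backward direction — regressing the artifact reference *on* the full
channel set, rather than each channel on an EOG trace — is what lets the
method express the removal as a single spatial projector, and what makes
the pattern `Â = Σ Ŵ` (not `Ŵ` itself) the interpretable scalp map.

## Automatic threshold selection

`α₀` is swept over `{step, 2·step, …, 10}` (default step 0.1).  For each
candidate, the full mask→fit→component chain produces `B_c = X Ŵ`, which
is scored by the band-power ratio

    Δ(α₀) = E(bpf₁₋₈(B_c)) / E(bpf₈₋₄₀(B_c))

with 4th-order zero-phase Butterworth band-passes and `E` the sum of
squares (for sampling rates below 84 Hz the upper edge is capped at
0.95 × Nyquist).  Blink energy concentrates in 1–8 Hz, so Δ is large
exactly when the mask isolates real blinks.  Degenerate masks (all-0 or
all-1) are excluded from the sweep.

An alternative denominator, `E(B_c − bpf₁₋₈(B_c))`, is equivalent on
data already band-limited to 1–40 Hz — the standard preprocessing this
tool expects — but on broadband data it absorbs the large sub-1-Hz mass
of the monophasic blink pulse itself, making Δ nearly independent of the
threshold.  The band-power form is used because it behaves identically
in the band-limited regime and remains meaningful outside it.

**Plateau handling.**  When the blink subspace is cleanly separable,
every threshold that isolates the blinks yields essentially the same
component, and Δ(α₀) is flat over a wide range; a literal argmax then
wanders across the plateau on sub-percent fit noise and is unstable
under grid-step changes.  Selection therefore takes the *smallest* α₀
whose Δ is within 2% (relative) of the maximum — the most inclusive mask
among statistically indistinguishable scores.  On curves with a
pronounced maximum this is the plain argmax.  The resulting `T₀*`
typically lands just above the extreme tail of the background reference
distribution (≈99.5–99.9th percentile on Gaussian-background scenes).

**No-blink guard.**  A recording with no blinks still produces
non-degenerate masks (any threshold inside a noise distribution does),
so the pipeline additionally requires the best Δ to reach 1.0: a
component with less 1–8 Hz than 8–40 Hz energy is broadband background
(pure 1–40 Hz noise scores Δ ≈ 0.2; real blinks score ≫ 1), and
`fit_and_purge(..., alpha0="auto")` raises a no-blink error instead of
silently "removing" noise.

## High-voltage segment rejection

Before fitting, the reference trace is cut into 15 s segments; for each,
the maximum absolute first difference `A_max` is compared to the mean
and standard deviation of `A_max` over all *previous* segments, and the
segment is rejected when `|A_max − μ| > k_sigma · σ` (default
`k_sigma = 5`).  The first segment is never rejected, and rejection only
triggers from the third segment on, because σ over a single predecessor
is 0 and would reject any nonidentical segment.  Rejected segments are
excluded from the quantile statistics, the mask, the regression design
and Σ — but `M_purge` is still applied to them at cleaning time, since
the projector is defined for every sample.

## Synthetic scenes

`make_scene` builds fully synthetic ground-truth recordings,
`S = S_clean + S_blink` exactly:

* **Background** — per-channel white Gaussian noise band-limited to
  1–40 Hz and rescaled to a target RMS (default 10 µV).  Channels are
  independent; real EEG background is spatially correlated and
  temporally colored, so passing tests show algorithmic correctness
  under the stated mixture model, not clinical performance.  Notably,
  independent background makes the blink *harder* to separate than
  volume-conducted background would (the filter cannot cancel
  correlated noise across channels).
* **Blink pulses** — raised-cosine, single-peaked, non-negative, peak
  exactly `peak_uV` (default 75 µV, the middle of the physiological
  50–100 µV range), duration 0.3 s (typical blink).  Onsets are
  uniformly jittered inside equal slots so pulses never overlap; the
  blink count is `round(rate · duration / 60)`.
* **Spatial pattern** — exponential decay over the channel index from 1
  (front) to 0.02 (back) with ±10% seeded jitter, emulating
  eye-distance attenuation without montage geometry; only relative
  attenuation matters to the algorithm.

Scenes are bit-reproducible from their seed.  The raw pulse train is
*not* band-limited (its support is exactly the planted intervals); a
1 Hz high-pass would remove ~40% of a 0.3 s monophasic pulse's energy
and ring ~25% of peak outside the intervals, destroying the ground-truth
bookkeeping the scene exists for.

`semi_synthetic_from_recording` reproduces the construction used with
real data: band-pass a blink-contaminated record 1–15 Hz, zero it
outside labeled blink intervals, smooth with a centered moving average
(default 5 samples, edge-truncated) to attenuate brain-wave residue, and
add the result onto a blink-free record.

## Evaluation metrics

With ground truth: per-channel RMSE, Pearson ρ, and
`SNR = 10 log₁₀(STD(S_clean)/STD(S_clean − X_purged))` — note this is
the log of a *standard-deviation* ratio, implemented exactly as defined
(6 dB therefore means a 4-fold amplitude-error reduction).  Without
ground truth: the semi-normalized correlation
`R = Cov(X, X_purged)/Var(X)` (population moments, so `R(x,x) = 1`
exactly), compared between count-matched 1 s blink and non-blink epochs;
and the RMAE of the PSD, the mean absolute relative PSD error over the
bins of the 8–12, 12–25 and 25–40 Hz bands.  PSDs use Welch's method
(2 s Hann segments, 50% overlap), fixed so the RMAE is reproducible.
Blink epoch centers are the per-run maxima of the reference inside mask
runs, thinned strongest-first so epochs never overlap; non-blink centers
come from stretches at least half an epoch clear of any mask sample.

## Numerical choices and degenerate inputs

* Zero-phase (forward–backward) filtering everywhere; this squares the
  magnitude response (doubling the effective order) and preserves blink
  peak latency, which the mask/data alignment implicitly assumes.
* Quantiles by linear interpolation; skewness by the sample third
  standardized moment, with exact zero (or constant trace) leaving the
  orientation unchanged.
* Population (1/N) variance conventions throughout the fit (rescale, Σ,
  R), keeping the projector algebra exact.
* Strict inequality in the mask (`B_ref > T₀`); raising the threshold
  can only clear mask samples.
* All-zero/all-one masks, constant metric inputs, zero-power PSD bins,
  label mismatches and infeasible blink rates raise typed errors with
  machine-parsable reasons; nothing degrades silently.
* For `P > 1`, filter columns are rescaled independently and the
  projector algebra is exact only per-column; only replicated blink
  references are validated.

## Known limitations

* The synthetic background omits spatial correlation, 1/f spectra, and
  non-blink artifacts other than the injected high-voltage transients;
  conclusions about real-data performance require real recordings.
* The Δ sweep refits the spatial filter at every grid point (100 fits at
  step 0.1); on very long recordings, use step 0.2 or a manual α₀.
* Bad-channel flagging reports gross std-ratio outliers (>4× or <1/6 of
  the mean channel std) but never repairs them; a single extreme channel
  inflates the mean and can push healthy channels below the 1/6 bound,
  which is the documented behavior of the rule.
* Problem sizes used in the test suite (32 channels, 15–120 s at
  128 Hz, up to 20 seeds per property) were chosen to exercise every
  code path at desk scale while keeping the suite fast.
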