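# Methods

This note documents the models, estimators, and numerical choices behind
calscan, and states precisely what the synthetic-data tests establish.

## 1. The measurement model

A line scan is a raster `F(x, t)` of fluorescence counts: space along one
scanned line (pixel pitch in µm), time line by line (line period in ms).
Timestamps refer to line starts, line 0 is t = 0; pixel centers sit at
`(i + 0.5) · pitch`. Stimulus (pacing or sinus-beat) times are metadata
recorded by the rig, never inferred from the image.

All readouts are expressed in ΔF/F₀ = (F − F₀)/F₀, which cancels detector
gain, dye loading and illumination level. Every measurement in the
package is therefore invariant to a positive rescaling of the raw counts;
this is enforced by tests.

### F₀ (resting fluorescence)

Per spatial pixel, F₀ is the mean of the lowest 20% of that pixel's time
samples. This low-quantile estimator needs no beat annotation and is
robust to waves and transients occupying a majority of the record. Two
consequences are accepted and documented rather than patched:

- with shot noise the low quantile sits slightly below the true baseline
  (≲ 2% for the default SNR), which rescales ΔF/F₀ by a constant and
  offsets it slightly — both cancel out of τ (fit offset is free) and of
  amplitude (diastole is subtracted per segment);
- at fast pacing the signal never returns to baseline, so "F₀" is the
  inter-beat minimum plateau; again only the ΔF/F₀ scale is affected, and
  wave detection thresholds are data-driven (robust SDs of the same
  image), so detection is unaffected.

An optional detrend (`linear` / `exp`) handles bleaching and slow drift:
the low-quantile level is computed in 20 time bins, a shared
multiplicative trend is fit to the median across pixels, and the baseline
becomes `profile(x) · trend(t)`.

## 2. Transient kinetics

### Waveform and segmentation

Transients are segmented by stimulus windows (stimulus → next stimulus);
onset is the stimulus time, the peak is the window maximum, and the
diastolic background is the mean ΔF/F₀ over the 20 ms before onset (first
beat: the trace's 10th percentile). Segments whose peak-above-diastole is
below `max(5 · σ_noise, 0.02)` are flagged, not counted; σ_noise is
`1.4826 · MAD(ΔF/F₀ first differences)/√2`, a high-frequency noise
estimate insensitive to the smooth transient waveform itself (necessary
at 20 Hz pacing, where no sample is purely diastolic).

### τ estimators

τ is the e-fold decay time: one τ after the peak a mono-exponential has
lost 63.2% of its peak-above-baseline.

- `exp_fit` (default): least squares of `A·exp(−(t − t_peak)/τ) + C` on
  the decay span from one sample past the sampled peak to 90% of the
  window. The free offset C absorbs diastolic elevation and any F₀ bias.
- `crossing` (cross-check): the 1/e level crossing, interpolated in log
  space (exact for an exponential). Because the true peak generally falls
  between two scan lines, the naive `t_cross − t_peak` carries a bias of
  up to one line period; the implementation instead forms τ between the
  first decay sample and the crossing, which cancels the peak-time
  quantization exactly on a pure exponential. If the 1/e level is never
  reached inside the window, or fewer than 5 decay samples exist, τ is
  flagged undefined rather than extrapolated.

Both estimators are exact on noiseless mono-exponentials (< 0.5% relative
error across τ ∈ [10, 200] ms and line periods ∈ [0.5, 4] ms, enforced by
a property test); divergence between them beyond 10% flags the segment.

Known limitation: the nonlinear fit carries a positive O(σ²) bias that
grows as the averaging band narrows (≈ +0.1% at half the default band
width). At the default full-band SNR it is far below the Monte-Carlo
resolution of the acceptance experiments.

## 3. Wave detection

### The separation principle

A paced/sinus transient is spatially synchronous: the activation front
traverses the whole line orders of magnitude faster than any wave. A wave
starts at a point and propagates at ~1–5 mm/s. Detection therefore works
on the *residual* image — ΔF/F₀ minus its per-line spatial median — which
removes every spatially synchronous component (beats, drift) exactly,
leaving waves visible wherever they occur in the pacing cycle, including
on the decay of a beat.

### Onset points, clustering, splitting

Each local release onset is an upstroke: a temporal-derivative peak above
`max(4 · σ_deriv, 0.01 ms⁻¹)` whose pixel reaches the amplitude threshold
`max(3.5 · σ_res, 0.05)` within 16 ms. Onset points are clustered by
front continuity (links between nearby columns whose onset times are
consistent with one propagating front). Clusters smaller than 50 µm ×
20 ms are discarded — this excludes sparks, which are not counted.

A single bidirectional wave is a "V" of onset points with its apex at the
origin. Within a cluster:

1. primary origins are the local minima (prominence ≥ 6 ms, separation ≥
   20 µm) of the earliest-onset-per-column profile — i.e. the sign
   reversals of the front velocity; columns are partitioned at the latest
   onset between adjacent origins;
2. a propagation cone `t₀ + |x − x₀|/v` is fit to each origin (velocity by
   regression of arrival time on distance);
3. onset points explained by no cone (within 12 ms) are re-clustered:
   each leftover cluster spanning ≥ 40 µm is an additional event whose
   origin is its earliest point. This recovers waves that fire *on the
   front of an earlier wave*, whose apex is invisible in any
   first-arrival profile.

Against the generator's truth logs this reaches precision 1.0 and recall
1.0 at the 8 Hz rates and ≈ 0.99 at the densest 20 Hz regime (≈ 24
waves/(mm·s)), where genuinely coincident multi-wave pile-ups occur.

### Classification and frequency

An event is a **wave** iff its onset is > 30 ms from every stimulus, or
its velocity is < 5 mm/s (so a wave firing just after a beat is still
caught); full-width candidates synchronous with a stimulus and faster
than 20 mm/s are paced transients. These bounds separate the two regimes
by an order of magnitude and are config-exposed. Without a stimulus list
on a paced recording, classification degrades to the velocity criterion
with a warning.

Frequency = onsets inside the analysis window / (scanned length in mm ×
window in s). The default window runs from the first stimulus to 2 s
after the last, clipped to the scan; windows are half-open and events
straddling the edge follow their onset. The per-mm denominator is the
scanned-line length (the tissue dimension is unknown).

## 4. SR leak and load

Leak (tetracaine protocol): F₀ is the mean over the first 1 s of the pre
recording; leak = (pre mean − post steady-state mean)/F₀, each over the
final 2 s of its recording. The post window counts as settled when
|slope| < 0.5% F₀/s; unsettled or negative results are reported flagged,
never clamped. Values stay in ΔF/F₀ units — no dye calibration to µM is
attempted.

Load (caffeine protocol): the caffeine trace is normalized by the
baseline recording's F₀; the store-release peak is located on a 60 ms
smoothed trace and refined by a quadratic fit of the raw trace ± 50 ms
around it. A raw max-over-samples would ride the extreme of the noise
(≈ +0.5% bias at default SNR); the quadratic refinement is unbiased for
the rounded caffeine peak, which is what the Monte-Carlo recovery tests
require. A peak below the detection floor yields `defined=False`.

## 5. The synthetic generator

The generator states a world in which every analysis stage has a
recoverable truth; it does not attempt reaction–diffusion realism.

- **Transient**: saturating-exponential upstroke (time constant 3 ms,
  handed over at 5 rise constants = 99.3% saturation) joined to a *pure*
  mono-exponential decay, so the decay constant is exactly
  `tau_decay_ms` and the noiseless peak exactly `amplitude_dff0`. Paced
  transients are spatially simultaneous; this synchrony/velocity gap is
  precisely what wave detection exploits, and it is tunable.
- **Waves**: a Poisson number of events with mean `rate × mm × s`,
  origins uniform over diastole (a refractory window after each stimulus
  of `min(60 ms, cycle/2)` — capped so fast pacing keeps a late-diastolic
  window), bidirectional propagation at 2 mm/s, 150 µm extent, local
  release pulse decaying with `duration/3`. Origins are rejection-sampled
  against a 40 µm × 60 ms mutual exclusion box (local SR refractoriness);
  the Poisson count is drawn first, so exclusion never alters the count
  statistics. Origins avoid the last `duration + 40 ms` of the scan so no
  event is truncated by the recording edge.
- **Noise**: Gaussian approximation to photon shot noise with variance
  `shot_scale × mean counts` (default 1.0, i.e. ideal Poisson at a
  500-count baseline → ≈ 4.5% per-pixel SD at rest), optional linear
  drift and exponential bleaching. All randomness flows from one seeded
  generator: identical parameters + seed give byte-identical scans.
- **Protocol pairs**: the tetracaine pair settles to `F₀(1 − leak)` with
  a 300 ms time constant; the caffeine transient uses a smooth
  `(1−e^{−t/100 ms})·e^{−t/800 ms}` pulse normalized so its peak equals
  the load exactly.

**Group presets** (`wt_sham`, `wt_alc`, `jnk2dn_alc`) carry published
cohort means as ground truth for the decay constant and the
per-pacing-frequency wave rates; every other number (amplitude 0.8, rise
3 ms, 500-count baseline, wave geometry, noise level, 5 Hz intrinsic
sinus rate, leak/load values, and the JNK2dn decay constant, reported
only as "normalized to control") is a representative default, marked as
such in the preset files. The sinus-rhythm wave rate is 0 in all presets:
wave rates were characterized under pacing stress, and spontaneous
sinus-rhythm waves are rare.

### What a green test does and does not establish

Recovery on this generator establishes that the estimators are unbiased
and the detector complete *under the stated model*: mono-exponential
decay, synchronous beats, constant-velocity bidirectional waves, shot
noise, known stimulus times. It does not establish performance under
motion, focus drift, bi-exponential decays, curved or unidirectional wave
fronts, or misannotated stimuli — real-data features deliberately outside
the model. The 40-µm/60-ms exclusion box means the detector is never
tested on *exactly* coincident origins, which are unresolvable in
principle.

## 6. Statistics layer

Mean ± SEM (sample SD/√n) per group. Two groups: Student's t-test, or
Mann–Whitney U when Levene's test (median-centered, α = 0.05) detects
heterogeneity of variance; ≥ 3 groups: one-way ANOVA + Tukey HSD, or
Kruskal–Wallis under heterogeneity. The two-group path holds its nominal
5% type-I error under homoscedastic and (equal-n) heteroscedastic nulls,
verified by 5000-rep calibration tests. Degenerate zero-variance inputs
return p = 1 (no evidence of difference) rather than NaN.

## 7. Acceptance experiments

`scripts/acceptance.py` and `tests/test_acceptance.py` run the same six
experiments: 40 seeded scans per target (sinus τ for two presets; wave
frequency at 8/8/10/20 Hz), full pipeline blind to the truth logs, grand
mean compared against the preset ground truth within 2 SEM. τ uses the
pooled SEM over all ≈ 2000 accepted transients (the strictest reading);
wave frequency uses the SEM across the 40 per-scan values, the scan being
the natural unit of replication. The canonical run (seeds 1–40) takes
about 3 minutes on one CPU.
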