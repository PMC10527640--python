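"""dF/F0 normalization, transient segmentation, amplitude and decay kinetics.

The resting (diastolic) fluorescence F0 is estimated per spatial pixel from
the lowest 20% of that pixel's time samples — a low-quantile estimator that
needs no beat annotation and is robust to waves — optionally after removing
a slow linear or exponential baseline trend (bleaching).  The decay
constant tau is the e-fold time of the transient decay: one tau after the
peak a mono-exponential has lost 63.2% of its peak-above-baseline.  Two
estimators are provided, a 1/e level-crossing time and a least-squares
mono-exponential fit; they agree exactly on noiseless mono-exponential
decays and the fit is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import ValidationError
from .io import LineScanImage

_INV_E = float(np.exp(-1.0))


# ---------------------------------------------------------------------------
# baseline estimation and normalization


@dataclass
class F0Estimate:
    """Per-pixel resting fluorescence, with an optional temporal trend.

    ``baseline(x, t) = f0_profile[x] * trend[t]``; ``trend`` is all ones
    when no detrending was requested.
    """

    f0_profile: np.ndarray
    trend: np.ndarray
    low_fraction: float = 0.2

    def baseline(self) -> np.ndarray:
        return self.f0_profile[:, None] * self.trend[None, :]


@dataclass
class NormalizedScan:
    """dF/F0 matrix [space x time] plus the baseline used to produce it."""

    dff0: np.ndarray
    f0_profile: np.ndarray
    trend: np.ndarray
    provenance: LineScanImage

    @property
    def line_period_ms(self) -> float:
        return self.provenance.line_period_ms

    @property
    def pixel_pitch_um(self) -> float:
        return self.provenance.pixel_pitch_um

    @property
    def stimulus_times_ms(self) -> np.ndarray:
        return self.provenance.stimulus_times_ms


def _lowest_mean(values: np.ndarray, frac: float, axis: int = -1) -> np.ndarray:
    """Mean of the lowest ``frac`` samples along ``axis``."""
    n = values.shape[axis]
    k = max(1, int(round(frac * n)))
    part = np.partition(values, k - 1, axis=axis)
    return np.take(part, np.arange(k), axis=axis).mean(axis=axis)


def estimate_f0(
    image: LineScanImage,
    detrend: str | None = None,
    low_fraction: float = 0.2,
    n_bins: int = 20,
) -> F0Estimate:
    """Estimate the diastolic baseline F0 per spatial pixel.

    Parameters
    ----------
    image
        Recording with at least 200 time lines.
    detrend
        ``None`` (default), ``"linear"`` or ``"exp"``.  With detrending the
        per-pixel low-quantile level is computed in ``n_bins`` time bins, a
        shared multiplicative trend is fit to their median course, and the
        returned baseline is ``profile(x) * trend(t)``.
    """
    if image.n_lines < 200:
        raise ValidationError("F0 estimation requires at least 200 time lines")
    if detrend not in (None, "linear", "exp"):
        raise ValidationError(f"unknown detrend mode {detrend!r}")
    pixels = np.asarray(image.pixels, dtype=float)
    n_lines = image.n_lines

    if detrend is None:
        profile = _lowest_mean(pixels, low_fraction)
        trend = np.ones(n_lines)
    else:
        bins = np.array_split(np.arange(n_lines), n_bins)
        centers = np.array([b.mean() * image.line_period_ms for b in bins])
        binned = np.stack(
            [_lowest_mean(pixels[:, b], low_fraction) for b in bins], axis=1
        )
        profile = binned.mean(axis=1)
        if np.any(profile <= 0):
            raise ValidationError("F0 profile contains non-positive values")
        g = np.median(binned / profile[:, None], axis=0)
        t_s = centers / 1000.0
        if detrend == "linear":
            slope, intercept = np.polyfit(t_s, g, 1)
            trend_full = intercept + slope * (image.times_ms() / 1000.0)
        else:  # exp
            if np.any(g <= 0):
                raise ValidationError("cannot fit exponential trend to nonpositive levels")
            b, loga = np.polyfit(t_s, np.log(g), 1)
            trend_full = np.exp(loga + b * (image.times_ms() / 1000.0))
        # fold the fit's mean level into the profile so trend is relative
        scale = trend_full.mean()
        profile = profile * scale
        trend = trend_full / scale

    if np.any(profile <= 0) or np.any(trend <= 0):
        raise ValidationError(
            "F0 must be strictly positive everywhere (zero-intensity column?)"
        )
    return F0Estimate(f0_profile=profile, trend=trend, low_fraction=low_fraction)


def normalize(image: LineScanImage, f0: F0Estimate | np.ndarray) -> NormalizedScan:
    """Compute dF/F0 = (F - F0) / F0 elementwise against the baseline."""
    if isinstance(f0, np.ndarray):
        f0 = F0Estimate(f0_profile=np.asarray(f0, dtype=float), trend=np.ones(image.n_lines))
    if f0.f0_profile.shape != (image.n_space,):
        raise ValidationError(
            f"f0_profile shape {f0.f0_profile.shape} does not match n_space {image.n_space}"
        )
    if f0.trend.shape != (image.n_lines,):
        raise ValidationError("trend length does not match number of lines")
    if np.any(f0.f0_profile <= 0):
        raise ValidationError("f0_profile must be strictly positive")
    baseline = f0.baseline()
    dff0 = image.pixels / baseline - 1.0
    return NormalizedScan(
        dff0=dff0, f0_profile=f0.f0_profile, trend=f0.trend, provenance=image
    )


# ---------------------------------------------------------------------------
# traces and segmentation


@dataclass
class Trace:
    """Spatially averaged dF/F0 time course."""

    values: np.ndarray
    line_period_ms: float

    @property
    def n(self) -> int:
        return self.values.size

    def times_ms(self) -> np.ndarray:
        return np.arange(self.n) * self.line_period_ms


def extract_trace(
    norm: NormalizedScan,
    spatial_band: tuple[int, int] | None = None,
    exclude_mask: np.ndarray | None = None,
) -> Trace:
    """Mean dF/F0 over a spatial pixel band, per time line.

    ``exclude_mask`` (same shape as the scan, True = drop) removes pixels,
    e.g. those covered by detected waves, from the average; a time line with
    every band pixel excluded falls back to the unmasked band mean.
    """
    if spatial_band is None:
        lo, hi = 0, norm.dff0.shape[0]
    else:
        lo, hi = spatial_band
    if not (0 <= lo < hi <= norm.dff0.shape[0]):
        raise ValidationError(f"spatial band ({lo}, {hi}) empty or outside the image")
    band = norm.dff0[lo:hi]
    plain = band.mean(axis=0)
    if exclude_mask is None:
        return Trace(values=plain, line_period_ms=norm.line_period_ms)
    keep = ~exclude_mask[lo:hi]
    n_keep = keep.sum(axis=0)
    with np.errstate(invalid="ignore"):
        masked = np.where(n_keep > 0, (band * keep).sum(axis=0) / np.maximum(n_keep, 1), plain)
    return Trace(values=masked, line_period_ms=norm.line_period_ms)


@dataclass
class TransientSegment:
    """One stimulus-locked Ca2+ transient within a trace."""

    onset_ms: float
    peak_ms: float
    end_ms: float
    peak_dff0: float  # amplitude above the local diastolic background
    diastolic_dff0: float
    peak_idx: int
    onset_idx: int
    end_idx: int
    accepted: bool
    tau_ms: float | None = None
    tau_method: str | None = None
    tau_defined: bool = False
    fit_quality: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.onset_ms <= self.peak_ms < self.end_ms):
            raise ValidationError("segment times must satisfy onset <= peak < end")


def _robust_sd(values: np.ndarray) -> float:
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def segment_transients(
    trace: Trace,
    stimulus_times_ms: np.ndarray,
    *,
    floor_sd: float = 5.0,
    abs_floor: float = 0.02,
    pre_window_ms: float = 20.0,
) -> list[TransientSegment]:
    """Cut the trace into one window per stimulus and locate each peak.

    The window runs from the stimulus to the next stimulus (or trace end);
    onset is the stimulus time and the peak is the window maximum.  The
    diastolic background of a segment is the mean dF/F0 over the
    ``pre_window_ms`` preceding its onset.  Segments whose
    peak-above-diastole falls below ``max(floor_sd * noise_sd, abs_floor)``
    are returned flagged (``accepted=False``) rather than counted; the
    noise SD is a robust MAD estimate of the trace's first differences,
    which is insensitive to the smooth transient waveform itself (at fast
    pacing the signal never returns to baseline, so no sample is purely
    diastolic).
    """
    stim = np.asarray(stimulus_times_ms, dtype=float)
    if stim.size == 0:
        warnings.warn("no stimuli given; beat inference is not supported", stacklevel=2)
        return []
    period = trace.line_period_ms
    values = trace.values
    n = values.size
    pre_samples = max(1, int(round(pre_window_ms / period)))

    edges = np.round(stim / period).astype(int)
    edges = np.append(edges, n)
    global_floor = float(np.quantile(values, 0.1))

    raw: list[tuple] = []
    for i in range(stim.size):
        i0, i1 = edges[i], edges[i + 1]
        if i1 - i0 < 2 or i0 >= n:
            continue
        window = values[i0:i1]
        peak_rel = int(np.argmax(window))
        pre = values[max(0, i0 - pre_samples): i0]
        diastole = float(pre.mean()) if pre.size >= 3 else global_floor
        raw.append((i0, i1, peak_rel, diastole))

    noise_sd = _robust_sd(np.diff(values)) / np.sqrt(2.0)
    floor = max(floor_sd * noise_sd, abs_floor)

    segments = []
    for i0, i1, peak_rel, diastole in raw:
        peak_idx = i0 + peak_rel
        amp = float(values[peak_idx] - diastole)
        segments.append(
            TransientSegment(
                onset_ms=i0 * period,
                peak_ms=peak_idx * period,
                end_ms=i1 * period,
                peak_dff0=amp,
                diastolic_dff0=diastole,
                peak_idx=peak_idx,
                onset_idx=i0,
                end_idx=min(i1, n),
                accepted=amp >= floor,
            )
        )
    return segments


# ---------------------------------------------------------------------------
# kinetics


def _crossing_tau(
    t: np.ndarray, y: np.ndarray, peak_val: float, peak_ms: float, diastole: float
) -> float | None:
    """Time for the decay to lose 63.2% of its peak-above-baseline.

    The crossing of the 1/e level is interpolated in log space (exact for
    an exponential); when the first decay sample is still near the peak
    the estimate is formed between that sample and the crossing, which
    cancels the quantization of the sampled peak time (the true peak
    generally falls between two scan lines).  Falls back to the literal
    ``t_cross - peak_ms`` when the reference sample is unusable.
    """
    denom = peak_val - diastole
    if denom <= 0:
        return None
    yp = (np.asarray(y) - diastole) / denom
    below = np.flatnonzero(yp <= _INV_E)
    if below.size == 0:
        return None
    j = int(below[0])
    if j == 0:
        return float(t[0] - peak_ms)
    y0, y1 = yp[j - 1], yp[j]
    if y0 > 0 and y1 > 0:
        # log-linear interpolation: exact crossing for exponential decay
        frac = (np.log(y0) + 1.0) / (np.log(y0) - np.log(y1))
    else:
        frac = (y0 - _INV_E) / (y0 - y1) if y1 != y0 else 0.0
    t_cross = t[j - 1] + frac * (t[j] - t[j - 1])
    y_ref = yp[0]
    if y_ref >= 0.4:
        # two-point form: independent of where the true peak fell between
        # samples, since both times lie on the same exponential
        return float((t_cross - t[0]) / (np.log(y_ref) + 1.0))
    return float(t_cross - peak_ms)


def estimate_tau(
    segment: TransientSegment,
    trace: Trace,
    method: str = "exp_fit",
    decay_span_frac: float = 0.9,
    min_decay_samples: int = 5,
) -> float | None:
    """Estimate the decay constant tau of one accepted transient (ms).

    ``crossing``: time after the peak at which the trace first decays by
    63.2% of its peak-above-baseline, with linear interpolation between the
    bracketing samples.  ``exp_fit`` (default): least-squares
    mono-exponential ``A exp(-(t - t_peak)/tau) + C`` over the decay span
    from just after the peak to ``decay_span_frac`` of the window, with the
    crossing estimate as cross-check; if the fit fails it falls back to the
    crossing value and flags the segment.  Returns ``None`` (and flags the
    segment) when tau is undefined — the decay never reaches the 1/e level
    inside the window, or has fewer than ``min_decay_samples`` samples.

    The segment is updated in place (``tau_ms``, ``tau_method``,
    ``tau_defined``, ``fit_quality``).
    """
    if method not in ("crossing", "exp_fit"):
        raise ValidationError(f"unknown tau method {method!r}")
    if not segment.accepted:
        raise ValidationError("tau is only defined for accepted segments")
    period = trace.line_period_ms
    peak_idx = segment.peak_idx
    fit_end = peak_idx + int(round(decay_span_frac * (segment.end_idx - peak_idx)))
    fit_end = min(fit_end, trace.n)
    # start one sample past the sampled peak so the rise phase (the true
    # peak may sit between samples) never leaks into the decay fit
    start = peak_idx + 1
    if fit_end - start < min_decay_samples:
        segment.tau_ms = None
        segment.tau_defined = False
        segment.flags.append("too_few_decay_samples")
        return None

    t = np.arange(start, fit_end) * period
    y = trace.values[start:fit_end]
    peak_val = float(trace.values[peak_idx])
    diastole = segment.diastolic_dff0
    tau_cross = _crossing_tau(t, y, peak_val, segment.peak_ms, diastole)

    if method == "crossing":
        segment.tau_method = "crossing"
        if tau_cross is None or tau_cross <= 0:
            segment.tau_ms = None
            segment.tau_defined = False
            segment.flags.append("no_crossing_before_window_end")
            return None
        segment.tau_ms = tau_cross
        segment.tau_defined = True
        return tau_cross

    # exp_fit
    tau0 = tau_cross if (tau_cross is not None and tau_cross > 0) else (t[-1] - t[0]) / 3.0
    amp0 = max(peak_val - diastole, 1e-6)

    def model(tt, a, tau, c):
        return a * np.exp(-(tt - segment.peak_ms) / tau) + c

    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=(amp0, tau0, diastole),
            bounds=([0.0, 1e-3, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=2000,
        )
        tau_fit = float(popt[1])
        resid = y - model(t, *popt)
        segment.fit_quality = float(np.sqrt(np.mean(resid**2)) / amp0)
    except (RuntimeError, ValueError):
        segment.flags.append("fit_failed_fallback_crossing")
        segment.tau_method = "crossing"
        if tau_cross is None or tau_cross <= 0:
            segment.tau_ms = None
            segment.tau_defined = False
            return None
        segment.tau_ms = tau_cross
        segment.tau_defined = True
        return tau_cross

    if tau_cross is not None and tau_cross > 0:
        if abs(tau_fit - tau_cross) > 0.10 * tau_cross:
            segment.flags.append("crossing_fit_divergence")
    segment.tau_method = "exp_fit"
    segment.tau_ms = tau_fit
    segment.tau_defined = True
    return tau_fit


def measure_amplitude(segment: TransientSegment, trace: Trace) -> float:
    """Peak dF/F0 of a transient above its local diastolic background."""
    if not segment.accepted:
        raise ValidationError("amplitude is only defined for accepted segments")
    return float(trace.values[segment.peak_idx] - segment.diastolic_dff0)


def wave_exclusion_mask(norm: NormalizedScan, waves) -> np.ndarray:
    """Boolean mask of pixels covered by detected wave events.

    Used to keep diastolic wave release out of the spatially averaged
    transient trace before kinetics are measured.
    """
    mask = np.zeros(norm.dff0.shape, dtype=bool)
    pitch = norm.pixel_pitch_um
    period = norm.line_period_ms
    for w in waves:
        c0 = max(0, int((w.origin_um - w.extent_um) / pitch))
        c1 = min(mask.shape[0], int(np.ceil((w.origin_um + w.extent_um) / pitch)) + 1)
        r0 = max(0, int(w.origin_ms / period))
        r1 = min(mask.shape[1], int(np.ceil((w.origin_ms + 2.0 * w.span_ms) / period)) + 1)
        mask[c0:c1, r0:r1] = True
    return mask
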