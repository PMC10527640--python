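"""Tetracaine-sensitive SR Ca2+ leak and caffeine-releasable SR Ca2+ load.

Both measurements work on paired quiescent recordings and are reported in
dF/F0 units (dimensionless; no dye calibration to absolute [Ca2+] is
attempted).  F0 is the steady-state fluorescence at the beginning of the
reference recording of the pair.

* Leak: tetracaine closes RyR2, so the diastolic fluorescence that
  disappears after superfusion is the Ca2+ that was leaking from the SR:
  ``leak = (mean F_pre - mean F_post,steady) / F0``.
* Load: caffeine opens RyR2 fully, dumping the SR content into the
  cytosol; the peak of the evoked transient over the baseline recording's
  diastolic level measures the releasable load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LineScanImage, RecordingSet
from .transients import _robust_sd


@dataclass
class FluxResult:
    """One leak or load measurement from a paired recording set.

    ``value_dff0`` may legitimately be negative for a leak (protocol
    failure); it is then reported and flagged rather than clamped.
    ``defined`` is False when no caffeine transient cleared the detection
    floor.  ``settled`` records whether the post-recording signal reached
    steady state (slope criterion) inside its averaging window.
    """

    kind: str  # {"leak", "load"}
    value_dff0: float
    f0_counts: float
    pre_window_ms: tuple[float, float]
    post_window_ms: tuple[float, float]
    settled: bool
    defined: bool = True
    flags: list[str] = field(default_factory=list)


def _mean_trace(image: LineScanImage) -> np.ndarray:
    """Spatially averaged raw-intensity time course."""
    return np.asarray(image.pixels, dtype=float).mean(axis=0)


def measure_leak(
    pair: RecordingSet,
    f0_window_s: float = 1.0,
    window_s: float = 2.0,
    settle_tol_frac_per_s: float = 0.005,
) -> FluxResult:
    """Tetracaine-sensitive diastolic SR Ca2+ leak from a pre/post pair.

    F0 is the mean over the first ``f0_window_s`` of the pre recording; the
    leak is the drop from the pre-recording mean to the post-recording
    steady state (each averaged over the final ``window_s``), normalized by
    F0.  The post signal counts as settled when the magnitude of its slope
    over the averaging window is below ``settle_tol_frac_per_s * F0``.
    """
    pre, post = pair.pair("leak")
    pre_trace = _mean_trace(pre)
    post_trace = _mean_trace(post)
    period = pre.line_period_ms

    n_f0 = max(2, int(round(f0_window_s * 1000.0 / period)))
    f0 = float(pre_trace[:n_f0].mean())

    n_win_pre = max(2, int(round(window_s * 1000.0 / period)))
    n_win_post = max(2, int(round(window_s * 1000.0 / post.line_period_ms)))
    pre_win = pre_trace[-n_win_pre:]
    post_win = post_trace[-n_win_post:]
    leak = float((pre_win.mean() - post_win.mean()) / f0)

    t_s = np.arange(post_win.size) * post.line_period_ms / 1000.0
    slope = float(np.polyfit(t_s, post_win, 1)[0])
    settled = abs(slope) < settle_tol_frac_per_s * f0

    flags = []
    if leak < 0:
        flags.append("negative_leak_protocol_failure")
    if not settled:
        flags.append("post_not_settled")
    return FluxResult(
        kind="leak",
        value_dff0=leak,
        f0_counts=f0,
        pre_window_ms=(
            (pre_trace.size - n_win_pre) * period,
            pre_trace.size * period,
        ),
        post_window_ms=(
            (post_trace.size - n_win_post) * post.line_period_ms,
            post_trace.size * post.line_period_ms,
        ),
        settled=settled,
        flags=flags,
    )


def measure_load(
    pair: RecordingSet,
    f0_window_s: float = 1.0,
    floor_sd: float = 5.0,
    abs_floor: float = 0.02,
    smooth_ms: float = 60.0,
    refine_half_ms: float = 50.0,
) -> FluxResult:
    """Caffeine-releasable SR Ca2+ load from a baseline/caffeine pair.

    The caffeine trace is normalized by F0 (start of the baseline
    recording); the peak of the evoked transient is located on a lightly
    smoothed trace and its value refined by a local quadratic fit of the
    raw trace (``+- refine_half_ms``), which is unbiased for the rounded
    store-release peak where a plain max-over-samples would ride the noise
    extreme.  The load is that peak minus the baseline recording's
    diastolic dF/F0 level.  If the peak does not clear the detection floor
    (``floor_sd`` robust noise SDs of the baseline trace, at least
    ``abs_floor``), the result is returned with ``defined=False``.
    """
    base, caff = pair.pair("load")
    period = caff.line_period_ms
    base_trace = _mean_trace(base)
    caff_trace = _mean_trace(caff)

    n_f0 = max(2, int(round(f0_window_s * 1000.0 / base.line_period_ms)))
    f0 = float(base_trace[:n_f0].mean())

    base_dff0 = base_trace / f0 - 1.0
    caff_dff0 = caff_trace / f0 - 1.0
    background = float(base_dff0.mean())

    n_smooth = max(1, int(round(smooth_ms / period)))
    kernel = np.full(n_smooth, 1.0 / n_smooth)
    smoothed = np.convolve(caff_dff0, kernel, mode="same")
    peak_idx = int(np.argmax(smoothed))

    half = max(2, int(round(refine_half_ms / period)))
    lo = max(0, peak_idx - half)
    hi = min(caff_dff0.size, peak_idx + half + 1)
    t = np.arange(lo, hi) * period
    coeffs = np.polyfit(t - t.mean(), caff_dff0[lo:hi], 2)
    if coeffs[0] < 0:  # concave: evaluate parabola at its vertex
        tv = -coeffs[1] / (2.0 * coeffs[0])
        tv = float(np.clip(tv, t[0] - t.mean(), t[-1] - t.mean()))
        peak_val = float(np.polyval(coeffs, tv))
    else:  # degenerate (flat trace): fall back to the window mean level
        peak_val = float(caff_dff0[lo:hi].mean())

    load = peak_val - background
    noise_sd = _robust_sd(base_dff0)
    floor = max(floor_sd * noise_sd, abs_floor)
    defined = load >= floor
    flags = [] if defined else ["no_caffeine_transient_above_floor"]

    return FluxResult(
        kind="load",
        value_dff0=load,
        f0_counts=f0,
        pre_window_ms=(0.0, n_f0 * base.line_period_ms),
        post_window_ms=(lo * period, hi * period),
        settled=True,
        defined=defined,
        flags=flags,
    )
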