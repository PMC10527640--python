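"""Detection and counting of propagating diastolic Ca2+ waves in x-t scans.

Stimulus-evoked transients light up the whole scanned line at once (the
activation front traverses the field far faster than any wave), whereas a
wave starts at a point and spreads at a few mm/s, drawing an oblique "V"
in the x-t image.  Detection exploits this contrast in two steps:

1. the spatially synchronous component of the normalized scan (the
   per-line spatial median) is subtracted, leaving a residual image in
   which waves stand out wherever they occur in the pacing cycle;
2. every local Ca2+ release onset is located as an upstroke of the
   residual (temporal-derivative peak backed by a supra-threshold
   amplitude), and the resulting cloud of onset points is clustered into
   events.  A single bidirectional wave is a "V" of onset points with its
   apex at the origin; colliding waves merge into one cluster and are
   split at the local minima of the earliest-onset profile (the sign
   reversals of the front velocity).  Onset points not explained by any
   fitted propagation cone — a wave whose origin is occluded because it
   fired on the front of an earlier wave — are re-clustered into
   additional events.

Events are classified as waves if they are asynchronous with every
stimulus or propagate slower than the wave/paced velocity bound; wave
frequency is reported in waves/(mm x s): onsets counted in the analysis
window divided by scanned line length times window duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, maximum_filter1d, median_filter
from scipy.signal import find_peaks
from skimage.measure import label, regionprops

from .errors import ValidationError
from .io import LineScanImage
from .transients import NormalizedScan, _robust_sd


@dataclass(frozen=True)
class WaveDetectionConfig:
    """Thresholds separating waves from paced transients and from noise.

    The asynchrony tolerance and the velocity bounds separate the two
    propagation regimes by an order of magnitude (waves a few mm/s, paced
    activation effectively instantaneous along the line); the minimum
    component extent excludes sparks, which are not counted.
    """

    k_sd: float = 3.5  # amplitude threshold in robust noise SDs
    amp_floor_dff0: float = 0.05  # absolute amplitude floor (noiseless images)
    min_extent_um: float = 50.0
    min_span_ms: float = 20.0
    async_tol_ms: float = 30.0
    v_max_wave_mm_s: float = 5.0
    v_min_paced_mm_s: float = 20.0
    paced_width_frac: float = 0.8
    smooth_lines: float = 1.2  # temporal gaussian smoothing (lines)
    # upstroke (onset-point) detection
    deriv_k_sd: float = 4.0
    deriv_floor_per_ms: float = 0.01
    onset_lookahead_ms: float = 16.0
    # clustering / splitting / cone fit
    link_tol_ms: float = 4.0
    link_tol_per_col_ms: float = 4.0
    max_gap_cols: int = 3
    split_prominence_ms: float = 6.0
    split_min_sep_um: float = 20.0
    explain_tol_ms: float = 12.0
    secondary_min_extent_um: float = 40.0
    post_pacing_window_ms: float = 2000.0


@dataclass
class CandidateRegion:
    """One supra-threshold 8-connected x-t component."""

    label_id: int
    cols: np.ndarray  # distinct spatial pixels touched
    onset_rows: np.ndarray  # first supra-threshold line per spatial pixel
    onset_ms: float
    extent_um: float
    span_ms: float
    width_fraction: float
    peak_dff0: float
    scan: NormalizedScan


@dataclass
class WaveEvent:
    """One detected propagating diastolic release event."""

    origin_um: float
    origin_ms: float
    extent_um: float
    span_ms: float
    velocity_mm_s: float
    peak_dff0: float
    synchrony_offset_ms: float


@dataclass
class WaveFrequencyResult:
    """Wave count normalized by scanned length and analysis duration."""

    n_waves: int
    scan_length_mm: float
    duration_s: float
    frequency: float  # waves/(mm x s), == n/(mm*s) exactly
    pacing_hz: float
    window_ms: tuple[float, float] = (0.0, 0.0)


# ---------------------------------------------------------------------------
# shared helpers


def _smooth_time(a: np.ndarray, sigma_lines: float) -> np.ndarray:
    if sigma_lines <= 0:
        return a
    return gaussian_filter1d(a, sigma=sigma_lines, axis=1)


def _residual(dff0: np.ndarray) -> np.ndarray:
    """Remove the spatially synchronous component (per-line spatial median)."""
    return dff0 - np.median(dff0, axis=0, keepdims=True)


def _amp_threshold(work: np.ndarray, config: WaveDetectionConfig) -> float:
    return max(config.k_sd * _robust_sd(work.ravel()), config.amp_floor_dff0)


# ---------------------------------------------------------------------------
# candidate components (amplitude threshold + connected components)


def detect_candidate_events(
    norm: NormalizedScan, config: WaveDetectionConfig | None = None
) -> list[CandidateRegion]:
    """Find supra-threshold x-t components of any kind (beats and waves).

    Pixels exceeding the local diastolic level (per-pixel low quantile) by
    ``max(k * noise_sd, floor)`` are grouped into 8-connected components;
    components smaller than the minimum spatial x temporal extent (sparks)
    are discarded.  An empty list is a valid result.
    """
    config = config or WaveDetectionConfig()
    work = _smooth_time(norm.dff0, config.smooth_lines)
    thr = _amp_threshold(_residual(work), config)
    diastolic = np.quantile(work, 0.2, axis=1, keepdims=True)
    mask = work >= diastolic + thr

    pitch = norm.pixel_pitch_um
    period = norm.line_period_ms
    labels = label(mask, connectivity=2)
    out: list[CandidateRegion] = []
    for prop in regionprops(labels):
        r_min, c_min, r_max, c_max = prop.bbox  # rows = space, cols = time
        extent_um = (r_max - r_min) * pitch
        span_ms = (c_max - c_min) * period
        if extent_um < config.min_extent_um or span_ms < config.min_span_ms:
            continue
        sub = labels[r_min:r_max, c_min:c_max] == prop.label
        has_px = sub.any(axis=1)
        cols = np.flatnonzero(has_px) + r_min
        onset_rows = np.array([np.argmax(sub[c - r_min]) + c_min for c in cols])
        out.append(
            CandidateRegion(
                label_id=int(prop.label),
                cols=cols,
                onset_rows=onset_rows,
                onset_ms=float(onset_rows.min() * period),
                extent_um=extent_um,
                span_ms=span_ms,
                width_fraction=cols.size / norm.dff0.shape[0],
                peak_dff0=float(work[r_min:r_max, c_min:c_max][sub].max()),
                scan=norm,
            )
        )
    out.sort(key=lambda c: c.onset_ms)
    return out


def _front_speed_mm_s(cand: CandidateRegion) -> float:
    """Apparent traverse speed of the activation front across the component."""
    period = cand.scan.line_period_ms
    spread_ms = (cand.onset_rows.max() - cand.onset_rows.min()) * period
    if spread_ms <= 0:
        return np.inf
    return cand.extent_um / spread_ms  # um/ms == mm/s


# ---------------------------------------------------------------------------
# onset points: every local release upstroke in the residual image


def _onset_points(
    residual: np.ndarray, config: WaveDetectionConfig, period: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Locate release onsets as temporal-derivative peaks.

    Returns ``(cols, rows, r_smooth, amp_thr)`` where ``cols``/``rows`` are
    the spatial/temporal indices of onset points.  A point is an onset iff
    the smoothed residual's time derivative has a local maximum above the
    derivative threshold there AND the residual itself reaches the
    amplitude threshold within the lookahead window — so noise flickers
    that never amount to a release are rejected, while a second wave
    firing on top of an earlier wave's decaying fluorescence (no fresh
    amplitude crossing of its own) is still caught by its upstroke.
    """
    r_smooth = _smooth_time(residual, config.smooth_lines)
    amp_thr = _amp_threshold(r_smooth, config)
    # light spatial smoothing for the derivative only: waves are tens of
    # pixels wide, so this cuts derivative noise without blurring fronts
    deriv_src = gaussian_filter1d(r_smooth, sigma=1.0, axis=0)
    deriv = np.gradient(deriv_src, axis=1) / period  # dF/F0 per ms
    d_thr = max(config.deriv_k_sd * _robust_sd(deriv.ravel()), config.deriv_floor_per_ms)

    is_peak = (
        (deriv >= d_thr)
        & (deriv > np.roll(deriv, 1, axis=1))
        & (deriv >= np.roll(deriv, -1, axis=1))
    )
    is_peak[:, 0] = False
    is_peak[:, -1] = False
    look = max(1, int(round(config.onset_lookahead_ms / period)))
    future_max = maximum_filter1d(r_smooth, size=2 * look + 1, axis=1, mode="nearest")
    # shift so the window covers [t, t + 2*look] rather than being centered
    future_max = np.roll(future_max, -look, axis=1)
    future_max[:, -look:] = future_max[:, [-look - 1]]
    is_peak &= future_max >= amp_thr

    cols, rows = np.nonzero(is_peak)
    return cols, rows, r_smooth, amp_thr


def _cluster_points(
    cols: np.ndarray, rows: np.ndarray, period: float, config: WaveDetectionConfig
) -> list[np.ndarray]:
    """Group onset points into events by front continuity.

    Points in nearby spatial columns are linked when their onset times are
    consistent with one propagating front (tolerance grows with the column
    gap to admit the slowest waves); connected components of this linkage
    are the event clusters.  Returns index arrays into ``cols``/``rows``.
    """
    n = cols.size
    if n == 0:
        return []
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    order = np.argsort(cols, kind="stable")
    by_col: dict[int, list[int]] = {}
    for idx in order:
        by_col.setdefault(int(cols[idx]), []).append(int(idx))

    times_ms = rows * period
    for c, idxs in by_col.items():
        for gap in range(1, config.max_gap_cols + 1):
            neigh = by_col.get(c + gap)
            if not neigh:
                continue
            tol = config.link_tol_ms + config.link_tol_per_col_ms * gap
            for i in idxs:
                for j in neigh:
                    if abs(times_ms[i] - times_ms[j]) <= tol:
                        union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return [np.asarray(v) for v in clusters.values()]


def _earliest_profile(cols: np.ndarray, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Earliest onset row per distinct column (sorted by column)."""
    ucols, inv = np.unique(cols, return_inverse=True)
    earliest = np.full(ucols.size, np.iinfo(np.int64).max)
    np.minimum.at(earliest, inv, rows)
    return ucols, earliest


def _fit_velocity(x_um: np.ndarray, t_ms: np.ndarray, x0: float, t0: float) -> float:
    """Propagation speed from regression of front arrival vs distance."""
    dist = np.abs(x_um - x0)
    dt = t_ms - t0
    good = dist > 0
    if good.sum() < 3 or np.ptp(dist[good]) == 0:
        return np.inf
    slope = np.polyfit(dist[good], dt[good], 1)[0]  # ms per um
    return 1.0 / slope if slope > 1e-6 else np.inf


def _cluster_events(
    idx: np.ndarray,
    cols: np.ndarray,
    rows: np.ndarray,
    r_smooth: np.ndarray,
    pitch: float,
    period: float,
    config: WaveDetectionConfig,
) -> list[WaveEvent]:
    """Turn one onset-point cluster into one or more events.

    Primary origins are the prominence-filtered local minima of the
    cluster's earliest-onset profile; each origin gets a propagation cone
    ``t0 + |x - x0| / v`` fit to its columns.  Onset points lying outside
    every cone (occluded origins) are re-clustered into secondary events.
    """
    ccols, crows = cols[idx], rows[idx]
    ucols, earliest = _earliest_profile(ccols, crows)
    extent_um = (ucols.max() - ucols.min() + 1) * pitch
    span_ms = (crows.max() - crows.min()) * period
    if extent_um < config.min_extent_um or span_ms < config.min_span_ms:
        return []

    prof = earliest.astype(float)
    if prof.size >= 5:
        prof = median_filter(prof, size=5, mode="nearest")
    prominence = config.split_prominence_ms / period
    distance = max(1, int(round(config.split_min_sep_um / pitch)))
    minima, _ = find_peaks(-prof, prominence=prominence, distance=distance)
    if minima.size == 0:
        minima = np.array([int(np.argmin(prof))])

    # partition profile columns at the latest-onset column between minima
    cuts = [0]
    for a, b in zip(minima[:-1], minima[1:]):
        cuts.append(a + int(np.argmax(prof[a:b])))
    cuts.append(prof.size)

    peak = float(
        r_smooth[
            ucols.min(): ucols.max() + 1,
            crows.min(): min(r_smooth.shape[1], crows.max() + 1),
        ].max()
    )

    events: list[tuple[float, float, float, float, float]] = []  # x0,t0,v,extent,span
    for m, lo, hi in zip(minima, cuts[:-1], cuts[1:]):
        part = ucols[lo:hi]
        x0 = (ucols[m] + 0.5) * pitch
        t0 = earliest[m] * period
        x_um = (part + 0.5) * pitch
        t_ms = earliest[lo:hi] * period
        v = _fit_velocity(x_um, t_ms, x0, t0)
        events.append((x0, t0, v, part.size * pitch, float(np.ptp(t_ms))))

    # cone check: which onset points are explained by some fitted origin?
    x_all = (ccols + 0.5) * pitch
    t_all = crows * period
    explained = np.zeros(idx.size, dtype=bool)
    for x0, t0, v, _, _ in events:
        v_eff = v if np.isfinite(v) and v > 0 else 1e9
        pred = t0 + np.abs(x_all - x0) / v_eff
        explained |= np.abs(t_all - pred) <= config.explain_tol_ms
    leftover = np.flatnonzero(~explained)
    if leftover.size:
        for sub in _cluster_points(
            ccols[leftover], crows[leftover], period, config
        ):
            scols, srows = ccols[leftover][sub], crows[leftover][sub]
            sucols, searliest = _earliest_profile(scols, srows)
            if (sucols.max() - sucols.min() + 1) * pitch < config.secondary_min_extent_um:
                continue
            apex = int(np.argmin(searliest))
            x0 = (sucols[apex] + 0.5) * pitch
            t0 = searliest[apex] * period
            v = _fit_velocity((sucols + 0.5) * pitch, searliest * period, x0, t0)
            events.append(
                (x0, t0, v, sucols.size * pitch, float(np.ptp(searliest) * period))
            )

    return [
        WaveEvent(
            origin_um=x0,
            origin_ms=t0,
            extent_um=ext,
            span_ms=spn,
            velocity_mm_s=v,
            peak_dff0=peak,
            synchrony_offset_ms=np.nan,  # filled in by classify_events
        )
        for x0, t0, v, ext, spn in events
    ]


def extract_wave_events(
    norm: NormalizedScan, config: WaveDetectionConfig | None = None
) -> list[WaveEvent]:
    """All propagating release events in the synchrony-removed residual."""
    config = config or WaveDetectionConfig()
    period = norm.line_period_ms
    pitch = norm.pixel_pitch_um
    residual = _residual(norm.dff0)
    cols, rows, r_smooth, _ = _onset_points(residual, config, period)
    events: list[WaveEvent] = []
    for idx in _cluster_points(cols, rows, period, config):
        events.extend(
            _cluster_events(idx, cols, rows, r_smooth, pitch, period, config)
        )
    events.sort(key=lambda e: e.origin_ms)
    return events


# ---------------------------------------------------------------------------
# classification and frequency


def classify_events(
    candidates: list[CandidateRegion],
    stimulus_times_ms: np.ndarray | None = None,
    config: WaveDetectionConfig | None = None,
) -> tuple[list[WaveEvent], list[CandidateRegion]]:
    """Separate wave events from paced/sinus transients.

    Paced transients are candidates that span (nearly) the full line
    width, start within the asynchrony tolerance of a stimulus, and whose
    front traverses the line faster than ``v_min_paced``.  Wave events are
    extracted from the synchrony-removed residual (see
    :func:`extract_wave_events`), so a wave riding on the decay of a beat
    is still found; an event is kept as a WAVE iff it is asynchronous with
    every stimulus (criterion a) OR slower than ``v_max_wave``
    (criterion b).

    With an empty stimulus list on a paced recording the synchrony
    criterion is unavailable and classification degrades, with a warning,
    to the velocity criterion alone.
    """
    config = config or WaveDetectionConfig()
    if not candidates:
        return [], []
    norm = candidates[0].scan
    stim = (
        np.asarray(stimulus_times_ms, dtype=float)
        if stimulus_times_ms is not None
        else norm.stimulus_times_ms
    )
    if stim.size == 0 and norm.provenance.protocol_tag == "paced":
        warnings.warn(
            "paced recording without stimulus times: classification degrades "
            "to the velocity criterion only",
            stacklevel=2,
        )

    paced: list[CandidateRegion] = []
    for cand in candidates:
        synchronous = (
            stim.size > 0
            and np.min(np.abs(cand.onset_ms - stim)) <= config.async_tol_ms
        )
        if (
            cand.width_fraction >= config.paced_width_frac
            and synchronous
            and _front_speed_mm_s(cand) >= config.v_min_paced_mm_s
        ):
            paced.append(cand)

    waves: list[WaveEvent] = []
    for ev in extract_wave_events(norm, config):
        offset = float(np.min(np.abs(ev.origin_ms - stim))) if stim.size else np.inf
        ev.synchrony_offset_ms = offset
        asynchronous = offset > config.async_tol_ms
        slow = ev.velocity_mm_s < config.v_max_wave_mm_s
        if asynchronous or slow:
            waves.append(ev)
    return waves, paced


def default_analysis_window(
    scan: LineScanImage, config: WaveDetectionConfig | None = None
) -> tuple[float, float]:
    """Counting window: first stimulus to 2 s after the last, clipped."""
    config = config or WaveDetectionConfig()
    stim = scan.stimulus_times_ms
    if stim.size == 0:
        return (0.0, scan.duration_ms)
    return (
        float(stim[0]),
        min(scan.duration_ms, float(stim[-1]) + config.post_pacing_window_ms),
    )


def wave_frequency(
    waves: list[WaveEvent],
    scan: LineScanImage,
    analysis_window: tuple[float, float] | None = None,
) -> WaveFrequencyResult:
    """Count wave onsets in the window and normalize to waves/(mm x s).

    An event counts iff its onset lies inside the half-open window
    ``[t0, t1)``; events straddling the edge follow their onset.
    """
    if analysis_window is None:
        analysis_window = default_analysis_window(scan)
    t0, t1 = analysis_window
    if not (0.0 <= t0 < t1 <= scan.duration_ms + 1e-9):
        raise ValidationError(f"invalid analysis window {analysis_window}")
    n = sum(1 for w in waves if t0 <= w.origin_ms < t1)
    duration_s = (t1 - t0) / 1000.0
    stim = scan.stimulus_times_ms
    pacing_hz = float(1000.0 / np.median(np.diff(stim))) if stim.size >= 2 else 0.0
    return WaveFrequencyResult(
        n_waves=n,
        scan_length_mm=scan.scan_length_mm,
        duration_s=duration_s,
        frequency=n / (scan.scan_length_mm * duration_s),
        pacing_hz=pacing_hz,
        window_ms=(t0, t1),
    )


def detect_waves(
    norm: NormalizedScan, config: WaveDetectionConfig | None = None
) -> tuple[list[WaveEvent], list[CandidateRegion]]:
    """Convenience pipeline: candidates -> classification -> wave list."""
    config = config or WaveDetectionConfig()
    candidates = detect_candidate_events(norm, config)
    return classify_events(candidates, norm.stimulus_times_ms, config)
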