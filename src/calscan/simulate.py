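"""Synthetic line-scan generator with ground-truth event logs.

The generator builds space x time fluorescence rasters that emulate confocal
line-scan recordings of beating atrial tissue: stimulus-locked Ca2+
transients that are spatially synchronous along the scanned line, diastolic
Ca2+ waves that propagate at a finite velocity (and therefore appear as
oblique bands in the x-t image), tetracaine-induced diastolic steps, and
caffeine-evoked store-release transients.  Every stochastic element is
drawn from a single seeded generator and recorded in a truth log so that
each analysis stage can be validated by parameter recovery.

The transient waveform is a saturating-exponential upstroke joined to a
strictly mono-exponential decay, so the decay constant of a noiseless
transient is ``tau_decay_ms`` exactly: one tau after the peak the signal
has fallen by 63.2% of its peak-above-baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .errors import ValidationError
from .io import LineScanImage, RecordingSet

# upstroke is rendered for 5 rise-time constants, i.e. to 99.3% saturation,
# then handed over to the pure exponential decay
_RISE_SPAN = 5.0
#: fixed upstroke time constant of the local wave release (ms)
WAVE_RISE_MS = 2.0
#: no two wave origins may fall within this box (mimics local SR refractoriness)
WAVE_EXCLUSION_UM = 40.0
WAVE_EXCLUSION_MS = 60.0


# ---------------------------------------------------------------------------
# parameter models


@dataclass(frozen=True)
class TransientKinetics:
    """Shape parameters of the stimulus-locked Ca2+ transient."""

    amplitude_dff0: float = 0.8
    rise_ms: float = 3.0
    tau_decay_ms: float = 30.03
    f0_counts: float = 500.0
    diastolic_dff0: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_dff0 <= 0:
            raise ValidationError("amplitude_dff0 must be > 0")
        if self.rise_ms <= 0 or self.tau_decay_ms <= 0 or self.f0_counts <= 0:
            raise ValidationError("rise_ms, tau_decay_ms, f0_counts must be > 0")
        if self.diastolic_dff0 < 0:
            raise ValidationError("diastolic_dff0 must be >= 0")

    @property
    def time_to_peak_ms(self) -> float:
        return _RISE_SPAN * self.rise_ms


@dataclass(frozen=True)
class WaveModel:
    """Statistics and geometry of propagating diastolic Ca2+ waves."""

    rate_per_mm_s: float = 0.0
    velocity_mm_s: float = 2.0
    amplitude_dff0: float = 0.6
    extent_um: float = 150.0
    duration_ms: float = 60.0

    def __post_init__(self) -> None:
        if self.rate_per_mm_s < 0:
            raise ValidationError("rate_per_mm_s must be >= 0")
        if self.velocity_mm_s <= 0:
            raise ValidationError("velocity_mm_s must be > 0")
        if self.amplitude_dff0 <= 0 or self.extent_um <= 0 or self.duration_ms <= 0:
            raise ValidationError("wave amplitude, extent and duration must be > 0")


@dataclass(frozen=True)
class NoiseModel:
    """Photon shot noise plus slow baseline drift / bleaching.

    ``shot_scale`` is the variance-to-mean factor of the Gaussian
    approximation to photon noise (1.0 = ideal Poisson); ``drift_per_s`` is
    a linear fractional baseline drift; ``bleach_tau_s`` a mono-exponential
    bleaching constant (``inf`` = no bleaching).  With ``shot_scale == 0``,
    ``drift_per_s == 0`` and ``bleach_tau_s == inf`` the generator is fully
    deterministic given the kinetics.
    """

    shot_scale: float = 1.0
    drift_per_s: float = 0.0
    bleach_tau_s: float = math.inf

    def __post_init__(self) -> None:
        if self.shot_scale < 0:
            raise ValidationError("shot_scale must be >= 0")
        if self.bleach_tau_s <= 0:
            raise ValidationError("bleach_tau_s must be > 0 (inf = none)")

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(shot_scale=0.0, drift_per_s=0.0, bleach_tau_s=math.inf)


@dataclass(frozen=True)
class ScanGeometry:
    """Raster geometry: 500 px at 2 um pitch = a 1 mm scanned line."""

    n_space: int = 500
    pixel_pitch_um: float = 2.0
    line_period_ms: float = 2.0

    def __post_init__(self) -> None:
        if self.n_space < 2:
            raise ValidationError("n_space must be >= 2")
        if self.pixel_pitch_um <= 0 or self.line_period_ms <= 0:
            raise ValidationError("pixel_pitch_um and line_period_ms must be > 0")

    @property
    def scan_length_mm(self) -> float:
        return self.n_space * self.pixel_pitch_um / 1000.0


@dataclass(frozen=True)
class WaveTruth:
    """Ground-truth record of one injected wave."""

    origin_um: float
    origin_ms: float
    extent_um: float
    duration_ms: float
    velocity_mm_s: float
    amplitude_dff0: float


@dataclass
class TruthLog:
    """Everything the generator injected into one scan."""

    stimulus_times_ms: np.ndarray
    waves: list[WaveTruth] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    @property
    def n_waves(self) -> int:
        return len(self.waves)


@dataclass(frozen=True)
class GroupPreset:
    """Named bundle of ground-truth parameters emulating one cohort."""

    name: str
    kinetics: TransientKinetics
    waves: dict[float, WaveModel]
    noise: NoiseModel
    leak_dff0: float
    load_dff0: float

    def wave_model(self, pacing_hz: float) -> WaveModel:
        key = float(pacing_hz)
        if key not in self.waves:
            raise ValidationError(
                f"preset {self.name!r} has no wave rate for pacing {pacing_hz} Hz"
            )
        return self.waves[key]


def list_presets() -> list[str]:
    root = resources.files("calscan").joinpath("presets")
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def get_preset(name: str) -> GroupPreset:
    """Load a shipped group preset (``wt_sham``, ``wt_alc``, ``jnk2dn_alc``)."""
    path = resources.files("calscan").joinpath("presets", f"{name}.yaml")
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise ValidationError(
            f"unknown preset {name!r}; available: {list_presets()}"
        ) from None
    return preset_from_dict(raw)


def preset_from_dict(raw: dict) -> GroupPreset:
    """Build a preset from a parsed YAML mapping (user-overridable files)."""
    wv = dict(raw["waves"])
    rates = wv.pop("rate_per_mm_s")
    waves = {float(hz): WaveModel(rate_per_mm_s=float(r), **wv) for hz, r in rates.items()}
    return GroupPreset(
        name=str(raw["name"]),
        kinetics=TransientKinetics(**raw["kinetics"]),
        waves=waves,
        noise=NoiseModel(**raw.get("noise", {})),
        leak_dff0=float(raw["leak_dff0"]),
        load_dff0=float(raw["load_dff0"]),
    )


# ---------------------------------------------------------------------------
# waveform primitives


def pulse(dt_ms: np.ndarray, amplitude: float, rise_ms: float, decay_ms: float) -> np.ndarray:
    """Upstroke-then-exponential-decay pulse, peak == ``amplitude``.

    The upstroke is ``1 - exp(-t/rise)`` rescaled so the pulse reaches
    ``amplitude`` exactly at ``t = 5 * rise``; from there the decay is a pure
    exponential with constant ``decay_ms``.
    """
    dt = np.asarray(dt_ms, dtype=float)
    tp = _RISE_SPAN * rise_ms
    a_rise = amplitude / (1.0 - math.exp(-_RISE_SPAN))
    out = np.zeros_like(dt)
    rising = (dt >= 0) & (dt < tp)
    out[rising] = a_rise * (1.0 - np.exp(-dt[rising] / rise_ms))
    decaying = dt >= tp
    out[decaying] = amplitude * np.exp(-(dt[decaying] - tp) / decay_ms)
    return out


def smooth_pulse(dt_ms: np.ndarray, amplitude: float, rise_ms: float, decay_ms: float) -> np.ndarray:
    """C1-smooth pulse ``(1-exp(-t/r)) * exp(-t/d)``, peak == ``amplitude``.

    Used for the caffeine store-release transient, whose rounded peak is
    what the load measurement reads out.
    """
    dt = np.asarray(dt_ms, dtype=float)
    t_peak = rise_ms * math.log1p(decay_ms / rise_ms)
    norm = (1.0 - math.exp(-t_peak / rise_ms)) * math.exp(-t_peak / decay_ms)
    out = np.zeros_like(dt)
    on = dt >= 0
    out[on] = (amplitude / norm) * (1.0 - np.exp(-dt[on] / rise_ms)) * np.exp(
        -dt[on] / decay_ms
    )
    return out


def _baseline_track(times_ms: np.ndarray, f0_counts: float, noise: NoiseModel) -> np.ndarray:
    t_s = times_ms / 1000.0
    track = np.full(times_ms.shape, float(f0_counts))
    if noise.drift_per_s:
        track = track * (1.0 + noise.drift_per_s * t_s)
    if math.isfinite(noise.bleach_tau_s):
        track = track * np.exp(-t_s / noise.bleach_tau_s)
    return track


def _apply_shot_noise(counts: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    if noise.shot_scale > 0:
        counts = counts + rng.standard_normal(counts.shape) * np.sqrt(
            noise.shot_scale * np.clip(counts, 0.0, None)
        )
    return np.clip(counts, 0.0, None).astype(np.float32)


# ---------------------------------------------------------------------------
# wave origin sampling


def _diastolic_intervals(
    duration_ms: float,
    stimulus_times_ms: np.ndarray,
    refractory_ms: float,
    tail_margin_ms: float,
) -> list[tuple[float, float]]:
    """Time intervals in which a wave may originate.

    Waves are diastolic events: origins are excluded for ``refractory_ms``
    after every stimulus (capped at half the pacing cycle, so fast pacing
    still leaves a late-diastolic window) and near the end of the scan so
    no event is truncated by the recording edge.
    """
    stim = np.asarray(stimulus_times_ms, dtype=float)
    refr = refractory_ms
    if stim.size >= 2:
        refr = min(refr, 0.5 * float(np.min(np.diff(stim))))
    t_max = duration_ms - tail_margin_ms
    if t_max <= 0:
        return []
    edges = [0.0]
    for s in stim:
        if s >= t_max:
            break
        edges.extend([max(s, 0.0), min(s + refr, t_max)])
    edges.append(t_max)
    intervals = []
    # edges alternate allowed/forbidden; walk them pairwise
    for lo, hi in zip(edges[::2], edges[1::2]):
        if hi - lo > 1e-9:
            intervals.append((lo, hi))
    return intervals


def _sample_wave_truths(
    rng: np.random.Generator,
    waves: WaveModel,
    scan_length_mm: float,
    duration_ms: float,
    stimulus_times_ms: np.ndarray,
    refractory_ms: float = 60.0,
) -> list[WaveTruth]:
    """Draw a Poisson number of wave origins, uniform over diastole.

    The count is Poisson with mean ``rate * scan_length_mm * duration_s``
    (the spatial/temporal placement never alters the count).  Origins are
    rejection-sampled so that no two fall within a 40 um x 60 ms exclusion
    box, emulating local refractoriness of the SR after a release.
    """
    if waves.rate_per_mm_s == 0:
        return []
    mean = waves.rate_per_mm_s * scan_length_mm * duration_ms / 1000.0
    n = int(rng.poisson(mean))
    if n == 0:
        return []
    intervals = _diastolic_intervals(
        duration_ms, stimulus_times_ms, refractory_ms, waves.duration_ms + 40.0
    )
    if not intervals:
        raise ValidationError(
            "no diastolic window available for wave placement; scan too short"
        )
    lengths = np.array([hi - lo for lo, hi in intervals])
    probs = lengths / lengths.sum()
    length_um = scan_length_mm * 1000.0
    placed: list[tuple[float, float]] = []
    out: list[WaveTruth] = []
    for _ in range(n):
        for _attempt in range(200):
            k = rng.choice(len(intervals), p=probs)
            t0 = intervals[k][0] + rng.uniform(0.0, lengths[k])
            x0 = rng.uniform(0.0, length_um)
            ok = all(
                not (
                    abs(x0 - xp) < WAVE_EXCLUSION_UM
                    and abs(t0 - tp) < WAVE_EXCLUSION_MS
                )
                for xp, tp in placed
            )
            if ok:
                break
        placed.append((x0, t0))
        out.append(
            WaveTruth(
                origin_um=x0,
                origin_ms=t0,
                extent_um=waves.extent_um,
                duration_ms=waves.duration_ms,
                velocity_mm_s=waves.velocity_mm_s,
                amplitude_dff0=waves.amplitude_dff0,
            )
        )
    out.sort(key=lambda w: w.origin_ms)
    return out


def _render_waves(
    dff0: np.ndarray,
    truths: list[WaveTruth],
    geometry: ScanGeometry,
) -> None:
    """Add every wave's oblique band into the dF/F0 field (in place)."""
    if not truths:
        return
    x = geometry.positions_um() if hasattr(geometry, "positions_um") else (
        (np.arange(dff0.shape[0]) + 0.5) * geometry.pixel_pitch_um
    )
    period = geometry.line_period_ms
    n_lines = dff0.shape[1]
    for w in truths:
        cols = np.flatnonzero(np.abs(x - w.origin_um) <= w.extent_um / 2.0)
        if cols.size == 0:
            continue
        # velocity in mm/s is numerically um/ms
        arrival = w.origin_ms + np.abs(x[cols] - w.origin_um) / w.velocity_mm_s
        horizon = _RISE_SPAN * WAVE_RISE_MS + 2.5 * w.duration_ms
        r0 = max(0, int(np.floor(arrival.min() / period)))
        r1 = min(n_lines, int(np.ceil((arrival.max() + horizon) / period)) + 1)
        if r1 <= r0:
            continue
        t_grid = np.arange(r0, r1) * period
        dt = t_grid[None, :] - arrival[:, None]
        dff0[np.ix_(cols, np.arange(r0, r1))] += pulse(
            dt, w.amplitude_dff0, WAVE_RISE_MS, w.duration_ms / 3.0
        )


# ---------------------------------------------------------------------------
# scan simulators


def simulate_paced_scan(
    kinetics: TransientKinetics,
    waves: WaveModel | None = None,
    noise: NoiseModel | None = None,
    pacing_hz: float = 0.0,
    duration_s: float = 10.0,
    geometry: ScanGeometry | None = None,
    seed: int = 0,
    *,
    sinus_hz: float = 5.0,
    refractory_ms: float = 60.0,
    group_tag: str = "",
) -> tuple[LineScanImage, TruthLog]:
    """Simulate one paced (or sinus) line-scan recording.

    ``pacing_hz == 0`` produces a sinus-rhythm surrogate with intrinsic
    beats at ``sinus_hz``.  Stimulus-locked transients are spatially
    synchronous across the whole line; waves propagate at the finite
    velocity of ``waves`` and are injected at a Poisson rate, uniformly
    over diastole.  Identical parameters + seed give byte-identical output.
    """
    if pacing_hz < 0:
        raise ValidationError("pacing_hz must be >= 0")
    if duration_s <= 0:
        raise ValidationError("duration_s must be > 0")
    waves = waves if waves is not None else WaveModel(rate_per_mm_s=0.0)
    noise = noise if noise is not None else NoiseModel.none()
    geometry = geometry or ScanGeometry()
    rng = np.random.default_rng(seed)

    duration_ms = duration_s * 1000.0
    n_lines = int(round(duration_ms / geometry.line_period_ms))
    times = np.arange(n_lines) * geometry.line_period_ms

    beat_hz = pacing_hz if pacing_hz > 0 else sinus_hz
    if beat_hz > 0:
        cycle = 1000.0 / beat_hz
        stim = np.arange(0.0, n_lines * geometry.line_period_ms - 1e-9, cycle)
    else:
        stim = np.empty(0)

    # stimulus-locked transients, identical along the line (synchronous)
    trace = np.full(n_lines, kinetics.diastolic_dff0)
    horizon = kinetics.time_to_peak_ms + 8.0 * kinetics.tau_decay_ms
    for s in stim:
        i0 = int(np.floor(s / geometry.line_period_ms))
        i1 = min(n_lines, int(np.ceil((s + horizon) / geometry.line_period_ms)) + 1)
        trace[i0:i1] += pulse(
            times[i0:i1] - s,
            kinetics.amplitude_dff0,
            kinetics.rise_ms,
            kinetics.tau_decay_ms,
        )

    dff0 = np.broadcast_to(trace, (geometry.n_space, n_lines)).copy()

    truths = _sample_wave_truths(
        rng, waves, geometry.scan_length_mm, duration_ms, stim, refractory_ms
    )

    class _Geo:  # tiny adapter so _render_waves can ask for positions
        pixel_pitch_um = geometry.pixel_pitch_um
        line_period_ms = geometry.line_period_ms

        @staticmethod
        def positions_um():
            return (np.arange(geometry.n_space) + 0.5) * geometry.pixel_pitch_um

    _render_waves(dff0, truths, _Geo)

    counts = _baseline_track(times, kinetics.f0_counts, noise)[None, :] * (1.0 + dff0)
    pixels = _apply_shot_noise(counts, noise, rng)

    image = LineScanImage(
        pixels=pixels,
        pixel_pitch_um=geometry.pixel_pitch_um,
        line_period_ms=geometry.line_period_ms,
        stimulus_times_ms=stim,
        protocol_tag="paced" if pacing_hz > 0 else "sinus",
        group_tag=group_tag,
    )
    log = TruthLog(
        stimulus_times_ms=stim,
        waves=truths,
        params={
            "pacing_hz": pacing_hz,
            "duration_s": duration_s,
            "seed": seed,
            "tau_decay_ms": kinetics.tau_decay_ms,
            "wave_rate_per_mm_s": waves.rate_per_mm_s,
        },
    )
    return image, log


def simulate_leak_pair(
    f0_counts: float = 500.0,
    leak_dff0: float = 0.1,
    noise: NoiseModel | None = None,
    duration_s: float = 6.0,
    seed: int = 0,
    geometry: ScanGeometry | None = None,
    settle_ms: float = 300.0,
    group_tag: str = "",
) -> RecordingSet:
    """Simulate a quiescent pre/post tetracaine pair.

    The pre recording sits at the diastolic level ``f0_counts``; in the post
    recording the diastolic fluorescence declines with time constant
    ``settle_ms`` to ``f0 * (1 - leak_dff0)``, so the steady-state drop over
    F0 equals ``leak_dff0``.
    """
    if leak_dff0 < 0:
        raise ValidationError("leak_dff0 must be >= 0")
    if f0_counts <= 0:
        raise ValidationError("f0_counts must be > 0")
    noise = noise if noise is not None else NoiseModel.none()
    geometry = geometry or ScanGeometry()
    rng = np.random.default_rng(seed)
    n_lines = int(round(duration_s * 1000.0 / geometry.line_period_ms))
    times = np.arange(n_lines) * geometry.line_period_ms
    base = _baseline_track(times, f0_counts, noise)

    pre_counts = np.broadcast_to(base, (geometry.n_space, n_lines)).copy()
    if settle_ms > 0:
        decline = 1.0 - leak_dff0 * (1.0 - np.exp(-times / settle_ms))
    else:
        decline = np.full(n_lines, 1.0 - leak_dff0)
    post_counts = np.broadcast_to(base * decline, (geometry.n_space, n_lines)).copy()

    images = []
    for tag, counts in (("pre_tetracaine", pre_counts), ("post_tetracaine", post_counts)):
        images.append(
            LineScanImage(
                pixels=_apply_shot_noise(counts, noise, rng),
                pixel_pitch_um=geometry.pixel_pitch_um,
                line_period_ms=geometry.line_period_ms,
                protocol_tag=tag,
                group_tag=group_tag,
            )
        )
    return RecordingSet.from_images(images)


def simulate_load_pair(
    kinetics: TransientKinetics | None = None,
    load_dff0: float = 1.5,
    noise: NoiseModel | None = None,
    seed: int = 0,
    geometry: ScanGeometry | None = None,
    baseline_s: float = 4.0,
    caffeine_s: float = 8.0,
    onset_ms: float = 1000.0,
    caffeine_rise_ms: float = 100.0,
    caffeine_decay_ms: float = 800.0,
    group_tag: str = "",
) -> RecordingSet:
    """Simulate a baseline/caffeine pair for SR load measurement.

    The caffeine recording contains a single large, slow store-release
    transient whose noiseless peak dF/F0 equals ``load_dff0`` exactly.
    """
    if load_dff0 <= 0:
        raise ValidationError("load_dff0 must be > 0")
    kinetics = kinetics or TransientKinetics()
    noise = noise if noise is not None else NoiseModel.none()
    geometry = geometry or ScanGeometry()
    rng = np.random.default_rng(seed)

    def _make(tag: str, duration_s: float, with_transient: bool) -> LineScanImage:
        n_lines = int(round(duration_s * 1000.0 / geometry.line_period_ms))
        times = np.arange(n_lines) * geometry.line_period_ms
        dff0 = np.zeros(n_lines)
        if with_transient:
            dff0 += smooth_pulse(
                times - onset_ms, load_dff0, caffeine_rise_ms, caffeine_decay_ms
            )
        counts = _baseline_track(times, kinetics.f0_counts, noise)[None, :] * (
            1.0 + dff0
        )
        counts = np.broadcast_to(counts, (geometry.n_space, n_lines)).copy()
        return LineScanImage(
            pixels=_apply_shot_noise(counts, noise, rng),
            pixel_pitch_um=geometry.pixel_pitch_um,
            line_period_ms=geometry.line_period_ms,
            protocol_tag=tag,
            group_tag=group_tag,
        )

    return RecordingSet.from_images(
        [_make("baseline", baseline_s, False), _make("caffeine", caffeine_s, True)]
    )
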