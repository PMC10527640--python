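"""Line-scan image I/O and the on-disk contract.

A recording is stored as a single-page grayscale TIFF (8/16-bit integer or
32-bit float) whose rows are spatial pixels and whose columns are scan lines
(time), plus a sidecar YAML file carrying the physical calibration and
protocol annotations.  Everything downstream consumes the in-memory
:class:`LineScanImage`, never the files directly.

Conventions
-----------
* axis 0 = space, axis 1 = time, regardless of the on-disk ``layout`` flag;
* line index 0 is t = 0 ms and timestamps refer to the line start;
* pixel indexing is 0-based with pixel centers at ``(i + 0.5) * pitch``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
import yaml

from .errors import InputError, PairingError, SchemaError, ValidationError

#: protocol tags understood by the analysis layers
PROTOCOL_TAGS = (
    "sinus",
    "paced",
    "pre_tetracaine",
    "post_tetracaine",
    "baseline",
    "caffeine",
)

#: the paired protocols required by the SR-flux measurements
LEAK_PAIR = ("pre_tetracaine", "post_tetracaine")
LOAD_PAIR = ("baseline", "caffeine")

_META_REQUIRED = ("pixel_pitch_um", "line_period_ms", "protocol")


@dataclass
class LineScanImage:
    """A space x time fluorescence raster with physical calibration.

    Parameters
    ----------
    pixels
        Nonnegative intensity matrix, shape ``(n_space, n_time)``, arbitrary
        fluorescence units.
    pixel_pitch_um
        Micrometers per spatial pixel (> 0).
    line_period_ms
        Milliseconds per scan line (> 0).
    stimulus_times_ms
        Sorted external pacing (or sinus beat) times; may be empty.  The
        stimulus schedule is metadata recorded by the rig, never inferred
        from the image.
    protocol_tag
        One of :data:`PROTOCOL_TAGS`.
    group_tag
        Free-form experimental group label (e.g. ``wt_sham``).
    """

    pixels: np.ndarray
    pixel_pitch_um: float
    line_period_ms: float
    stimulus_times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    protocol_tag: str = "sinus"
    group_tag: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("pixels must be a non-empty 2-D [space x time] matrix")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("pixel intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValidationError("pixel intensities must be nonnegative")
        if not (self.pixel_pitch_um > 0 and math.isfinite(self.pixel_pitch_um)):
            raise ValidationError("pixel_pitch_um must be positive")
        if not (self.line_period_ms > 0 and math.isfinite(self.line_period_ms)):
            raise ValidationError("line_period_ms must be positive")
        if self.protocol_tag not in PROTOCOL_TAGS:
            raise ValidationError(
                f"protocol_tag {self.protocol_tag!r} not one of {PROTOCOL_TAGS}"
            )
        stim = np.asarray(self.stimulus_times_ms, dtype=float).ravel()
        if stim.size:
            if np.any(np.diff(stim) <= 0):
                raise ValidationError("stimulus_times_ms must be strictly increasing")
            if stim[0] < 0 or stim[-1] >= self.duration_ms:
                raise ValidationError(
                    "stimulus_times_ms must lie within [0, n_lines * line_period_ms)"
                )
        self.stimulus_times_ms = stim

    # -- derived geometry ---------------------------------------------------

    @property
    def n_space(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_lines(self) -> int:
        return self.pixels.shape[1]

    @property
    def scan_length_mm(self) -> float:
        """Physical length of the scanned line in millimeters."""
        return self.n_space * self.pixel_pitch_um / 1000.0

    @property
    def duration_ms(self) -> float:
        return self.n_lines * self.line_period_ms

    @property
    def duration_s(self) -> float:
        return self.duration_ms / 1000.0

    def times_ms(self) -> np.ndarray:
        """Start time of every scan line."""
        return np.arange(self.n_lines) * self.line_period_ms

    def positions_um(self) -> np.ndarray:
        """Center position of every spatial pixel."""
        return (np.arange(self.n_space) + 0.5) * self.pixel_pitch_um

    def scaled(self, c: float) -> "LineScanImage":
        """Copy with raw intensities multiplied by ``c > 0`` (gain change)."""
        if c <= 0:
            raise ValidationError("intensity scale must be positive")
        return replace(self, pixels=self.pixels * c)


@dataclass
class RecordingSet:
    """A group of recordings from one preparation, indexed by protocol."""

    recordings: list[LineScanImage]
    pairing: dict[str, int]

    @classmethod
    def from_images(cls, images: list[LineScanImage]) -> "RecordingSet":
        pairing: dict[str, int] = {}
        for i, img in enumerate(images):
            if img.protocol_tag in pairing:
                raise ValidationError(
                    f"duplicate protocol_tag {img.protocol_tag!r} within a recording set"
                )
            pairing[img.protocol_tag] = i
        rset = cls(recordings=list(images), pairing=pairing)
        for pair in (LEAK_PAIR, LOAD_PAIR):
            if all(tag in pairing for tag in pair):
                rset._check_pair_calibration(pair)
        return rset

    def _check_pair_calibration(self, pair: tuple[str, str]) -> None:
        a = self.recordings[self.pairing[pair[0]]]
        b = self.recordings[self.pairing[pair[1]]]
        if a.pixel_pitch_um != b.pixel_pitch_um or a.line_period_ms != b.line_period_ms:
            raise ValidationError(
                f"paired recordings {pair} must share pixel_pitch_um and line_period_ms"
            )

    def get(self, protocol_tag: str) -> LineScanImage:
        try:
            return self.recordings[self.pairing[protocol_tag]]
        except KeyError:
            raise PairingError(f"recording set has no {protocol_tag!r} recording")

    def pair(self, kind: str) -> tuple[LineScanImage, LineScanImage]:
        """Return the (pre, post) pair for ``kind`` in {'leak', 'load'}."""
        tags = {"leak": LEAK_PAIR, "load": LOAD_PAIR}[kind]
        missing = [t for t in tags if t not in self.pairing]
        if missing:
            raise PairingError(
                f"{kind} measurement requires {tags}; missing {missing}"
            )
        return self.get(tags[0]), self.get(tags[1])


# ---------------------------------------------------------------------------
# file I/O


def read_linescan(image_path, meta_path) -> LineScanImage:
    """Read a TIFF + sidecar-YAML pair into a validated :class:`LineScanImage`.

    The sidecar must declare ``pixel_pitch_um``, ``line_period_ms`` and
    ``protocol``.  A ``layout`` of ``time_space`` marks a transposed raster,
    which is normalized on read; a missing stimulus list defaults to empty.
    """
    try:
        pixels = tifffile.imread(image_path)
    except FileNotFoundError as exc:
        raise InputError(f"image file not found: {image_path}") from exc
    except Exception as exc:  # corrupt / non-TIFF
        raise InputError(f"could not read TIFF {image_path}: {exc}") from exc
    if pixels.ndim != 2:
        raise InputError(f"{image_path} is not a single-channel 2-D image")

    try:
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh)
    except FileNotFoundError as exc:
        raise InputError(f"metadata file not found: {meta_path}") from exc
    if not isinstance(meta, dict):
        raise SchemaError(f"metadata {meta_path} is not a mapping")
    for key in _META_REQUIRED:
        if key not in meta:
            raise SchemaError(f"metadata {meta_path} lacks required key {key!r}")

    layout = meta.get("layout", "space_time")
    if layout not in ("space_time", "time_space"):
        raise SchemaError(f"unknown layout flag {layout!r}")
    if layout == "time_space":
        pixels = pixels.T

    return LineScanImage(
        pixels=pixels,
        pixel_pitch_um=float(meta["pixel_pitch_um"]),
        line_period_ms=float(meta["line_period_ms"]),
        stimulus_times_ms=np.asarray(meta.get("stimulus_times_ms") or [], dtype=float),
        protocol_tag=str(meta["protocol"]),
        group_tag=str(meta.get("group", "")),
    )


def write_linescan(image: LineScanImage, image_path, meta_path) -> None:
    """Write ``image`` as single-page TIFF + YAML sidecar.

    ``read_linescan(write_linescan(img))`` is the identity on pixels (bit
    exact) and metadata (full float precision).
    """
    pixels = image.pixels
    if pixels.dtype.kind == "f" and pixels.dtype != np.float32:
        pixels = pixels.astype(np.float32)
    try:
        tifffile.imwrite(image_path, pixels, photometric="minisblack")
    except OSError as exc:
        raise InputError(f"cannot write TIFF {image_path}: {exc}") from exc
    meta = {
        "pixel_pitch_um": float(image.pixel_pitch_um),
        "line_period_ms": float(image.line_period_ms),
        "protocol": image.protocol_tag,
        "group": image.group_tag,
        "stimulus_times_ms": [float(t) for t in image.stimulus_times_ms],
        "layout": "space_time",
    }
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def assemble_recording_set(entries) -> RecordingSet:
    """Read ``[(image_path, meta_path), ...]`` and group by protocol tag."""
    if not entries:
        raise ValidationError("assemble_recording_set needs at least one entry")
    images = [read_linescan(img, meta) for img, meta in entries]
    return RecordingSet.from_images(images)
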