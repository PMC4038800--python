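"""Per-frame detector-artefact correction and pixel flagging.

The correction chain runs, in order: saturation flagging on raw values, dark
subtraction, per-module common-mode subtraction, gain multiplication, bad-pixel
masking.  Every step can be switched off individually.  Flags live in a
per-pixel bitfield so one pixel can carry several conditions at once.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import h5py
import numpy as np

from .geometry import DetectorLayout

log = logging.getLogger(__name__)

__all__ = [
    "FLAG_BAD",
    "FLAG_SATURATED",
    "FLAG_HOT",
    "FLAG_PEAK_MASKED",
    "FLAG_SHADOWED",
    "Frame",
    "CalibrationSet",
    "CorrectionOptions",
    "build_dark",
    "build_gain",
    "common_mode",
    "flag_saturation",
    "correct_frame",
]

# Flag bits.  BAD excludes a pixel from every downstream statistic; the other
# bits each affect only specific stages (peak search, shadow reference, ...).
FLAG_BAD = np.uint8(1)
FLAG_SATURATED = np.uint8(2)
FLAG_HOT = np.uint8(4)
FLAG_PEAK_MASKED = np.uint8(8)
FLAG_SHADOWED = np.uint8(16)

# Bits that disqualify a pixel from analysis statistics.
ANALYSIS_EXCLUDE = FLAG_BAD | FLAG_HOT | FLAG_SATURATED


@dataclass
class Frame:
    """One detector exposure in raw layout plus its per-pixel flag bitfield."""

    data: np.ndarray
    flags: np.ndarray = None
    event_id: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(self.data.shape, dtype=np.uint8)
        else:
            self.flags = np.asarray(self.flags, dtype=np.uint8)
        if self.flags.shape != self.data.shape:
            raise ValueError("flags shape must match data shape")

    def copy(self) -> "Frame":
        return Frame(self.data.copy(), self.flags.copy(), self.event_id, dict(self.metadata))

    def good_mask(self, exclude: int = ANALYSIS_EXCLUDE) -> np.ndarray:
        """Pixels usable by analysis (none of the excluding bits set)."""
        return (self.flags & np.uint8(exclude)) == 0


def _check_congruent(name: str, arr: np.ndarray | None, shape: tuple[int, int]) -> None:
    if arr is not None and arr.shape != shape:
        raise ValueError(f"{name} shape {arr.shape} does not match frame shape {shape}")


@dataclass
class CalibrationSet:
    """Static per-run calibration inputs (all optional)."""

    dark: np.ndarray | None = None
    gain: np.ndarray | None = None
    badpixel_mask: np.ndarray | None = None
    peak_mask: np.ndarray | None = None
    shadow_mask: np.ndarray | None = None
    unresponsive_mask: np.ndarray | None = None
    saturation_level: float | None = None

    def validate(self, shape: tuple[int, int]) -> None:
        for name in ("dark", "gain", "badpixel_mask", "peak_mask", "shadow_mask",
                     "unresponsive_mask"):
            _check_congruent(name, getattr(self, name), shape)
        for name in ("badpixel_mask", "peak_mask", "shadow_mask", "unresponsive_mask"):
            m = getattr(self, name)
            if m is not None and m.dtype != np.bool_:
                raise ValueError(f"{name} must be boolean")
        if self.gain is not None:
            bad = self.badpixel_mask if self.badpixel_mask is not None else np.zeros(shape, bool)
            if np.any((self.gain <= 0) & ~bad):
                raise ValueError("gain must be > 0 wherever the pixel is not masked bad")

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in ("dark", "gain", "badpixel_mask", "peak_mask", "shadow_mask",
                         "unresponsive_mask"):
                a = getattr(self, name)
                if a is not None:
                    f.create_dataset(name, data=a)
            if self.saturation_level is not None:
                f.attrs["saturation_level"] = self.saturation_level

    @classmethod
    def load(cls, path) -> "CalibrationSet":
        kw = {}
        with h5py.File(path, "r") as f:
            for name in ("dark", "gain"):
                if name in f:
                    kw[name] = np.asarray(f[name], dtype=float)
            for name in ("badpixel_mask", "peak_mask", "shadow_mask", "unresponsive_mask"):
                if name in f:
                    kw[name] = np.asarray(f[name]).astype(bool)
            if "saturation_level" in f.attrs:
                kw["saturation_level"] = float(f.attrs["saturation_level"])
        return cls(**kw)


@dataclass
class CorrectionOptions:
    """Per-step on/off switches for :func:`correct_frame`."""

    saturation: bool = True
    dark: bool = True
    common_mode: bool = True
    gain: bool = True
    mask: bool = True
    # Per-pixel transfer-function hook for detector nonlinearity; identity by
    # default. Receives and returns the data array.
    nonlinearity: Callable[[np.ndarray], np.ndarray] | None = None


def _frame_data(f) -> np.ndarray:
    return f.data if isinstance(f, Frame) else np.asarray(f, dtype=float)


def build_dark(frames: Sequence) -> np.ndarray:
    """Per-pixel mean over X-ray-free frames."""
    stack = [_frame_data(f) for f in frames]
    if not stack:
        raise ValueError("build_dark requires at least one frame")
    return np.mean(np.stack(stack), axis=0)


def build_gain(
    frames: Sequence,
    reference: float,
    badpixel_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gain map from uniformly illuminated frames: gain = reference / mean.

    Masked-bad pixels get gain 1.  Pixels whose mean is zero without being
    masked are flagged unresponsive (returned mask) and also get gain 1.
    """
    mean = build_dark(frames)  # same arithmetic: per-pixel mean
    bad = badpixel_mask if badpixel_mask is not None else np.zeros(mean.shape, bool)
    unresponsive = (mean == 0) & ~bad
    safe = np.where((mean == 0) | bad, 1.0, mean)
    gain = np.where(bad | unresponsive, 1.0, reference / safe)
    return gain, unresponsive


def common_mode(
    module_pixels: np.ndarray,
    reference_mask: np.ndarray | None = None,
    good: np.ndarray | None = None,
) -> float:
    """Per-module additive offset: median of the reference pixels.

    The reference set is the shadowed pixels when a shadow mask is supplied,
    otherwise all unmasked pixels of the module.  An empty reference set gives
    offset 0 with a warning.
    """
    vals = np.asarray(module_pixels, dtype=float)
    sel = np.ones(vals.shape, bool) if good is None else np.asarray(good, bool)
    if reference_mask is not None:
        ref = sel & np.asarray(reference_mask, bool)
        if np.any(ref):
            sel = ref
    if not np.any(sel):
        warnings.warn("common_mode: all pixels masked; offset 0", stacklevel=2)
        return 0.0
    return float(np.median(vals[sel]))


def flag_saturation(f: Frame, level: float) -> Frame:
    """Set SATURATED where raw data >= level; data values untouched."""
    if level <= 0:
        raise ValueError("saturation level must be positive")
    f.flags[f.data >= level] |= FLAG_SATURATED
    return f


def correct_frame(
    f: Frame,
    cal: CalibrationSet,
    layout: DetectorLayout | None = None,
    opts: CorrectionOptions | None = None,
) -> Frame:
    """Run the correction chain on a copy of ``f``.

    Order: (1) saturation flagging on raw values, (2) dark subtraction,
    (3) per-module common mode, (4) gain, (5) bad-pixel flags.  Disabled steps
    are no-ops; steps lacking their calibration input are skipped.
    """
    opts = opts or CorrectionOptions()
    cal.validate(f.data.shape)
    out = f.copy()

    if opts.saturation and cal.saturation_level is not None:
        flag_saturation(out, cal.saturation_level)

    if opts.dark and cal.dark is not None:
        out.data -= cal.dark

    if opts.common_mode:
        if layout is None:
            modules: Iterable = [(0, (slice(None), slice(None)))]
        else:
            modules = layout.iter_modules()
        good = out.good_mask(FLAG_BAD)
        if opts.mask and cal.badpixel_mask is not None:
            good &= ~cal.badpixel_mask
        for _m, sl in modules:
            shadow = cal.shadow_mask[sl] if cal.shadow_mask is not None else None
            offset = common_mode(out.data[sl], reference_mask=shadow, good=good[sl])
            out.data[sl] -= offset

    if opts.nonlinearity is not None:
        out.data = opts.nonlinearity(out.data)

    if opts.gain and cal.gain is not None:
        out.data *= cal.gain

    if opts.mask:
        if cal.badpixel_mask is not None:
            out.flags[cal.badpixel_mask] |= FLAG_BAD
        if cal.unresponsive_mask is not None:
            out.flags[cal.unresponsive_mask] |= FLAG_BAD
        if cal.peak_mask is not None:
            out.flags[cal.peak_mask] |= FLAG_PEAK_MASKED
        if cal.shadow_mask is not None:
            out.flags[cal.shadow_mask] |= FLAG_SHADOWED
    return out
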