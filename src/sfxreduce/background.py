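"""Photon-background estimation.

Two complementary schemes:

* **Running background** — a ring buffer of the most recent non-hit frames;
  the pixel-wise median through the buffer estimates the current background,
  the pixel-wise spread gives a per-pixel noise level, and pixels bright in
  more than 80% of buffered frames are flagged hot.  Static detector offsets
  ride along in the median, so a separate dark calibration becomes optional.

* **Local background** — a per-pixel truncated windowed median of side
  ``2r + 1``, evaluated strictly within each detector module (windows are
  truncated at module edges, never wrapped or mirrored).  Used for peak
  finding on liquid-jet data where the solvent scattering jitters shot to
  shot.

All medians here use the lower-middle order statistic for even counts: the
result is always a value that occurred in the data, and is bit-reproducible
with no averaging of ADU counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .corrections import FLAG_HOT, Frame
from .geometry import DetectorLayout

__all__ = [
    "BackgroundBuffer",
    "LocalBackgroundParams",
    "push_nonhit",
    "running_background",
    "background_sigma",
    "detect_hot",
    "subtract_running",
    "local_background",
    "check_box_validity",
]


def _lower_median(sorted_stack: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Lower-middle order statistic along axis 0 of a NaN-padded sorted stack."""
    idx = np.clip((counts - 1) // 2, 0, sorted_stack.shape[0] - 1)
    med = np.take_along_axis(sorted_stack, idx[None, ...], axis=0)[0]
    return np.where(counts > 0, med, 0.0)


class BackgroundBuffer:
    """Ring buffer of the last ``depth`` non-hit frames.

    The median and sigma images are cached and refreshed every
    ``recompute_period`` pushes (default ``max(1, depth // 2)``) — "periodic"
    recomputation trades a bounded staleness for speed on long streams.
    """

    def __init__(self, depth: int, frame_shape: tuple[int, int],
                 recompute_period: int | None = None):
        if depth < 1:
            raise ValueError("buffer depth must be >= 1")
        self.depth = int(depth)
        self.frame_shape = tuple(frame_shape)
        self.recompute_period = int(recompute_period) if recompute_period else max(1, depth // 2)
        self._slots = np.zeros((self.depth, *self.frame_shape), dtype=float)
        self._cursor = 0
        self._filled = 0
        self._median: np.ndarray | None = None
        self._sigma: np.ndarray | None = None
        self._pushes_since_refresh = 0

    @property
    def n_filled(self) -> int:
        return self._filled

    def push(self, frame) -> "BackgroundBuffer":
        data = frame.data if isinstance(frame, Frame) else np.asarray(frame, dtype=float)
        if data.shape != self.frame_shape:
            raise ValueError(f"frame shape {data.shape} != buffer shape {self.frame_shape}")
        self._slots[self._cursor] = data
        self._cursor = (self._cursor + 1) % self.depth
        self._filled = min(self._filled + 1, self.depth)
        self._pushes_since_refresh += 1
        if self._pushes_since_refresh >= self.recompute_period:
            self._refresh()
        return self

    def _stack(self) -> np.ndarray:
        return self._slots[: self._filled]

    def _refresh(self) -> None:
        if self._filled == 0:
            return
        stack = np.sort(self._stack(), axis=0)
        counts = np.full(self.frame_shape, self._filled)
        self._median = _lower_median(stack, counts)
        self._sigma = np.std(self._stack(), axis=0) if self._filled >= 2 else None
        self._pushes_since_refresh = 0

    def median(self) -> np.ndarray:
        """Per-pixel lower-middle median over the buffered frames."""
        if self._filled == 0:
            raise ValueError("background buffer is empty")
        if self._median is None or self._pushes_since_refresh >= self.recompute_period:
            self._refresh()
        return self._median

    def sigma(self) -> np.ndarray:
        """Per-pixel population standard deviation over the buffered frames."""
        if self._filled < 2:
            raise ValueError("background sigma requires at least 2 buffered frames")
        if self._sigma is None or self._pushes_since_refresh >= self.recompute_period:
            self._refresh()
        return self._sigma

    def hot_mask(self, signal_level: float, fraction: float = 0.8) -> np.ndarray:
        """Pixels above ``signal_level`` in strictly more than ``fraction``
        of the buffered frames."""
        if self._filled == 0:
            raise ValueError("background buffer is empty")
        above = np.count_nonzero(self._stack() > signal_level, axis=0)
        return above > fraction * self._filled


# --- thin module-level wrappers with the operation names of the pipeline ----

def push_nonhit(buf: BackgroundBuffer, f) -> BackgroundBuffer:
    """Insert a frame already classified as a non-hit."""
    return buf.push(f)


def running_background(buf: BackgroundBuffer) -> np.ndarray:
    return buf.median()


def background_sigma(buf: BackgroundBuffer) -> np.ndarray:
    return buf.sigma()


def detect_hot(buf: BackgroundBuffer, signal_level: float, fraction: float = 0.8) -> np.ndarray:
    return buf.hot_mask(signal_level, fraction)


def subtract_running(f: Frame, buf: BackgroundBuffer, flag_hot_level: float | None = None) -> Frame:
    """Frame minus the buffered median; empty buffer passes through with a warning."""
    out = f.copy()
    if buf.n_filled == 0:
        warnings.warn("background buffer empty; frame passed through unsubtracted",
                      stacklevel=2)
        return out
    out.data = out.data - buf.median()
    if flag_hot_level is not None:
        out.flags[buf.hot_mask(flag_hot_level)] |= FLAG_HOT
    return out


@dataclass
class LocalBackgroundParams:
    """Box half-width ``radius`` (window side 2r+1) and the minimum ratio of
    background pixels to peak pixels that keeps the blind median honest."""

    radius: int = 3
    factor: float = 3.0

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.factor < 1:
            raise ValueError("factor must be >= 1")


def _windowed_median_module(values: np.ndarray, valid: np.ndarray, r: int) -> np.ndarray:
    """Truncated (2r+1)^2 windowed lower-median over one module.

    Masked pixels are excluded from every window; windows are clipped at the
    module edge.  A window with zero valid pixels yields 0.
    """
    padded = np.full((values.shape[0] + 2 * r, values.shape[1] + 2 * r), np.nan)
    padded[r:-r, r:-r] = np.where(valid, values, np.nan)
    win = np.lib.stride_tricks.sliding_window_view(padded, (2 * r + 1, 2 * r + 1))
    flat = win.reshape(*values.shape, -1)
    counts = np.count_nonzero(~np.isnan(flat), axis=-1)
    srt = np.sort(flat, axis=-1)  # NaNs sort to the end
    idx = np.clip((counts - 1) // 2, 0, flat.shape[-1] - 1)
    med = np.take_along_axis(srt, idx[..., None], axis=-1)[..., 0]
    return np.where(counts > 0, med, 0.0), counts


def local_background(
    f: Frame,
    params: LocalBackgroundParams,
    layout: DetectorLayout | None = None,
) -> tuple[np.ndarray, Frame]:
    """Per-pixel box-median background and the background-subtracted frame.

    The window is the (2r+1) x (2r+1) box centred on each pixel, intersected
    with the pixel's own module and with the unmasked pixels.
    """
    good = f.good_mask()
    bg = np.zeros_like(f.data)
    any_empty = False
    if layout is None:
        modules = [(0, (slice(0, f.data.shape[0]), slice(0, f.data.shape[1])))]
    else:
        modules = list(layout.iter_modules())
    for _m, sl in modules:
        med, counts = _windowed_median_module(f.data[sl], good[sl], params.radius)
        bg[sl] = med
        any_empty |= bool(np.any(counts == 0))
    if any_empty:
        warnings.warn("local_background: some windows contained no valid pixels; "
                      "background 0 used there", stacklevel=2)
    out = f.copy()
    out.data = out.data - bg
    return bg, out


def check_box_validity(params: LocalBackgroundParams, expected_peak_npix: int) -> bool:
    """True when the background region is large enough relative to the peak.

    Warns (and returns False) when the box holds fewer than
    ``factor * expected_peak_npix`` background pixels.
    """
    if expected_peak_npix < 0:
        raise ValueError("expected_peak_npix must be >= 0")
    side = 2 * params.radius + 1
    n_background = side * side - expected_peak_npix
    if n_background < params.factor * expected_peak_npix:
        warnings.warn(
            f"local background box ({side}x{side}) leaves only {n_background} background "
            f"pixels for a {expected_peak_npix}-pixel peak "
            f"(need >= {params.factor} x peak pixels)",
            stacklevel=2,
        )
        return False
    return True
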