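"""Run-level reduced data products.

Accumulated across a stream: virtual powder patterns (digital sums of many
single-crystal snapshots, split by hit class and by raw-corrected vs
background-subtracted variant), radial stacks (one azimuthally integrated
profile per frame, sortable by keys such as pump-probe delay), per-pixel ADU
histograms (photon-peak calibration, anomalous-pixel screening, and the prior
for the log-likelihood hit metric), and hit-rate / resolution statistics.
"""

from __future__ import annotations

import numpy as np

from .corrections import Frame

__all__ = [
    "PowderAccumulator",
    "RadialStack",
    "PixelHistograms",
    "RunStatistics",
    "powder_add",
    "radial_average",
    "stack_append",
    "stack_normalize_reject",
    "histograms_add",
    "update_stats",
    "success_rate",
    "frames_per_window",
]


def _data_of(f) -> np.ndarray:
    return f.data if isinstance(f, Frame) else np.asarray(f, dtype=float)


class PowderAccumulator:
    """Per-class running sums (exact, no averaging) plus frame counts.

    Classes are (is_hit, variant) with variant ``"corrected"`` or
    ``"subtracted"``.  Summing only background-subtracted hit frames yields a
    virtual powder pattern carrying Bragg signal with almost no background.
    """

    VARIANTS = ("corrected", "subtracted")

    def __init__(self, shape: tuple[int, int]):
        self.shape = tuple(shape)
        self.sums: dict[tuple[bool, str], np.ndarray] = {
            (h, v): np.zeros(self.shape) for h in (False, True) for v in self.VARIANTS
        }
        self.counts: dict[tuple[bool, str], int] = {k: 0 for k in self.sums}

    def add(self, frame, is_hit: bool, variant: str = "corrected") -> "PowderAccumulator":
        if variant not in self.VARIANTS:
            raise ValueError(f"unknown powder variant {variant!r}")
        data = _data_of(frame)
        if data.shape != self.shape:
            raise ValueError("frame shape does not match accumulator")
        self.sums[(bool(is_hit), variant)] += data
        self.counts[(bool(is_hit), variant)] += 1
        return self

    def sum(self, is_hit: bool, variant: str = "corrected") -> np.ndarray:
        return self.sums[(bool(is_hit), variant)]

    def mean(self, is_hit: bool, variant: str = "corrected") -> np.ndarray:
        n = self.counts[(bool(is_hit), variant)]
        return self.sums[(bool(is_hit), variant)] / max(n, 1)


def powder_add(acc: PowderAccumulator, f, is_hit: bool,
               variant: str = "corrected") -> PowderAccumulator:
    return acc.add(f, is_hit, variant)


def radial_average(f, bin_index: np.ndarray, n_bins: int,
                   good: np.ndarray | None = None) -> np.ndarray:
    """Azimuthal integration: per-annulus mean over unmasked pixels.

    Empty annuli are NaN-marked.
    """
    data = _data_of(f)
    if good is None:
        good = f.good_mask() if isinstance(f, Frame) else np.ones(data.shape, bool)
    idx = bin_index[good]
    cnt = np.bincount(idx, minlength=n_bins).astype(float)
    s = np.bincount(idx, weights=data[good], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnt > 0, s / cnt, np.nan)


class RadialStack:
    """One azimuthally integrated profile per processed frame."""

    def __init__(self, n_bins: int):
        self.n_bins = int(n_bins)
        self._rows: list[np.ndarray] = []
        self.keys: list = []
        self.flags: list[bool] = []   # True = outlier, excluded from averages
        self.scales: list[float] = []

    def __len__(self) -> int:
        return len(self._rows)

    def append(self, profile: np.ndarray, key=None) -> "RadialStack":
        profile = np.asarray(profile, dtype=float)
        if profile.shape != (self.n_bins,):
            raise ValueError(f"profile length {profile.shape} != {self.n_bins} bins")
        self._rows.append(profile)
        self.keys.append(key)
        self.flags.append(False)
        self.scales.append(1.0)
        return self

    def as_array(self) -> np.ndarray:
        if not self._rows:
            return np.empty((0, self.n_bins))
        return np.stack(self._rows)

    def sorted_order(self) -> np.ndarray:
        """Stable sort by key (None keys keep insertion order at the end)."""
        keyed = [(k is None, k if k is not None else 0, i)
                 for i, k in enumerate(self.keys)]
        return np.array([i for _, _, i in sorted(keyed, key=lambda t: (t[0], t[1]))],
                        dtype=np.int64)

    def sorted_view(self) -> np.ndarray:
        return self.as_array()[self.sorted_order()]

    def partition(self, key) -> np.ndarray:
        """Rows whose sort key equals ``key`` (e.g. laser-on vs laser-off)."""
        sel = [i for i, k in enumerate(self.keys) if k == key]
        return self.as_array()[sel]

    def normalize_reject(self, norm_range: tuple[int, int] | None = None,
                         reject_z: float = 5.0) -> np.ndarray:
        """Scale each row to unit mean over ``norm_range`` bins (default: the
        low-q first quarter) and flag rows whose pre-normalization scale is a
        robust outlier (|z| > reject_z against median/MAD of the scales).

        Flagged rows are retained in the stack but excluded from
        :meth:`averaged_view`.  All-zero rows are flagged and left unscaled.
        Returns the normalized array.
        """
        arr = self.as_array()
        if arr.shape[0] < 3:
            raise ValueError("normalization needs at least 3 rows")
        lo, hi = norm_range if norm_range is not None else (0, max(1, self.n_bins // 4))
        with np.errstate(invalid="ignore"):
            scales = np.nanmean(arr[:, lo:hi], axis=1)
        scales = np.where(np.isfinite(scales), scales, 0.0)
        zero = scales == 0
        med = float(np.median(scales[~zero])) if np.any(~zero) else 0.0
        mad = float(np.median(np.abs(scales[~zero] - med))) if np.any(~zero) else 0.0
        spread = max(1.4826 * mad, 1e-12 * max(abs(med), 1.0))
        out = np.where(zero[:, None], arr, arr / np.where(zero, 1.0, scales)[:, None])
        flags = zero | (np.abs(scales - med) > reject_z * spread)
        self.flags = list(map(bool, flags))
        self.scales = list(map(float, scales))
        self._normalized = out
        return out

    def averaged_view(self) -> np.ndarray:
        """Mean normalized profile over non-flagged rows."""
        if not hasattr(self, "_normalized"):
            raise ValueError("call normalize_reject first")
        keep = ~np.asarray(self.flags, bool)
        if not keep.any():
            raise ValueError("all rows flagged")
        return np.nanmean(self._normalized[keep], axis=0)


def stack_append(st: RadialStack, profile: np.ndarray, key=None) -> RadialStack:
    return st.append(profile, key)


def stack_normalize_reject(st: RadialStack, norm_range=None, reject_z: float = 5.0):
    return st.normalize_reject(norm_range, reject_z)


class PixelHistograms:
    """Per-pixel histogram of measured ADU over a shared set of bins.

    Out-of-range values are clipped into the end bins (and counted), so the
    per-pixel mass always equals the number of frames contributed.
    """

    def __init__(self, shape: tuple[int, int], bin_edges: np.ndarray):
        self.shape = tuple(shape)
        self.bin_edges = np.asarray(bin_edges, dtype=float)
        if self.bin_edges.ndim != 1 or self.bin_edges.size < 2:
            raise ValueError("bin_edges must be a 1-D array of >= 2 edges")
        self.n_bins = self.bin_edges.size - 1
        self.counts = np.zeros((*self.shape, self.n_bins), dtype=np.int64)
        self.n_frames = 0
        self.n_clipped_low = 0
        self.n_clipped_high = 0

    @classmethod
    def for_adu_range(cls, shape, lo: float, hi: float, bin_width: float) -> "PixelHistograms":
        edges = np.arange(lo, hi + bin_width, bin_width)
        return cls(shape, edges)

    def bin_index(self, data: np.ndarray) -> np.ndarray:
        return np.clip(np.digitize(data, self.bin_edges) - 1, 0, self.n_bins - 1)

    def add(self, frame) -> "PixelHistograms":
        data = _data_of(frame)
        if data.shape != self.shape:
            raise ValueError("frame shape does not match histograms")
        self.n_clipped_low += int(np.count_nonzero(data < self.bin_edges[0]))
        self.n_clipped_high += int(np.count_nonzero(data >= self.bin_edges[-1]))
        idx = self.bin_index(data)
        flat = idx.ravel() + self.n_bins * np.arange(idx.size)
        self.counts.reshape(-1)[flat] += 1
        self.n_frames += 1
        return self

    def probability(self, pseudo: float = 1.0) -> np.ndarray:
        """Pseudo-count-smoothed empirical pmf per pixel."""
        return (self.counts + pseudo) / (self.n_frames + pseudo * self.n_bins)


def histograms_add(h: PixelHistograms, f) -> PixelHistograms:
    return h.add(f)


class RunStatistics:
    """Hit-rate bookkeeping plus peak-count and resolution histograms.

    The instantaneous hit rate is the percentage of hits within consecutive
    fixed windows of ``frame_rate * window_seconds`` frames (600 at 120 Hz
    with the default 5 s window).
    """

    def __init__(self, frame_rate_hz: float = 120.0, window_seconds: float = 5.0):
        self.frame_rate_hz = float(frame_rate_hz)
        self.window_seconds = float(window_seconds)
        self.window_frames = frames_per_window(frame_rate_hz, window_seconds)
        self.frames = 0
        self.hits = 0
        self._window_hits: list[int] = []
        self._window_sizes: list[int] = []
        self._cur_hits = 0
        self._cur_frames = 0
        self.peak_counts: list[int] = []
        self.resolutions: list[float] = []
        self.skipped = 0

    def update(self, hit) -> "RunStatistics":
        """Record one classified event (a HitResult)."""
        self.frames += 1
        self._cur_frames += 1
        if hit.is_hit:
            self.hits += 1
            self._cur_hits += 1
            self.peak_counts.append(int(hit.n_peaks))
            if np.isfinite(hit.resolution_radius):
                self.resolutions.append(float(hit.resolution_radius))
        if self._cur_frames == self.window_frames:
            self._window_hits.append(self._cur_hits)
            self._window_sizes.append(self._cur_frames)
            self._cur_hits = 0
            self._cur_frames = 0
        return self

    @property
    def overall_hit_rate(self) -> float:
        """Percentage of hits over all frames."""
        return 100.0 * self.hits / self.frames if self.frames else 0.0

    def window_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(percent hit rate, frame count) per window; includes the partial
        final window so every frame is covered."""
        hits = list(self._window_hits)
        sizes = list(self._window_sizes)
        if self._cur_frames:
            hits.append(self._cur_hits)
            sizes.append(self._cur_frames)
        sizes_a = np.asarray(sizes, dtype=float)
        hits_a = np.asarray(hits, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(sizes_a > 0, 100.0 * hits_a / sizes_a, np.nan)
        return rates, sizes_a.astype(np.int64)

    def peak_count_histogram(self, bins=20) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.peak_counts, bins=bins)

    def resolution_histogram(self, bins=20) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.resolutions, bins=bins)

    def to_text(self) -> str:
        """Deterministic machine-parsable key=value dump."""
        rates, sizes = self.window_rates()
        lines = [
            f"frames={self.frames}",
            f"hits={self.hits}",
            f"skipped={self.skipped}",
            f"overall_hit_rate_pct={self.overall_hit_rate:.6f}",
            f"window_frames={self.window_frames}",
            "window_rates_pct=" + ",".join(f"{r:.6f}" for r in rates),
            "window_sizes=" + ",".join(str(s) for s in sizes),
            "peak_counts=" + ",".join(str(c) for c in self.peak_counts),
            "resolutions=" + ",".join(f"{r:.6f}" for r in self.resolutions),
        ]
        return "\n".join(lines) + "\n"


def update_stats(rs: RunStatistics, hit) -> RunStatistics:
    return rs.update(hit)


def success_rate(successes: int, trials: int) -> float:
    """Percentage of successes over trials (e.g. indexed frames over exported
    hits, the practical proxy for a hit-finder's false-positive rate)."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    return 100.0 * successes / trials


def frames_per_window(frame_rate_hz: float, window_seconds: float) -> int:
    """Number of frames in a time window at a fixed repetition rate."""
    if frame_rate_hz <= 0 or window_seconds <= 0:
        raise ValueError("rate and window must be positive")
    return int(round(frame_rate_hz * window_seconds))
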