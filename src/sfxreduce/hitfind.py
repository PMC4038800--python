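"""Event classification: is this frame a hit worth keeping?

Crystals: count Bragg peaks; a frame is a hit when strictly more than
``n_peaks_min`` peaks were found (downstream auto-indexing needs a minimum
number of reflections), optionally gated on the 80%-circle resolution.

Single particles: no Bragg peaks exist, so count pixels elevated above the
per-pixel background noise (value > k * sigma(x, y)); counting pixels is more
robust than summed intensity because a single randomly high pixel cannot fire
the classifier.  For photon-counting detectors a threshold just below one
photon-ADU converts frames to photon counts.  For extremely weak scatterers a
log-likelihood score against the per-pixel background histograms separates
statistical outliers from background frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .corrections import Frame

__all__ = [
    "HitParams",
    "HitResult",
    "classify_crystal",
    "classify_particle",
    "resolution_radius_80",
    "radius_to_d",
    "photon_count",
    "loglik_metric",
    "loglik_is_outlier",
]


@dataclass
class HitParams:
    """Classification thresholds.

    ``n_peaks_min`` defaults to 20 (strict ``>``); ``particle_sigma_k`` to 3
    (pixels above 3 sigma of the per-pixel background noise count as
    elevated); ``photon_threshold_fraction`` sits just below one photon.
    """

    n_peaks_min: int = 20
    resolution_cutoff: float | None = None  # minimum 80%-circle radius, pixels
    particle_sigma_k: float = 3.0
    particle_npix_min: int = 100
    adu_per_photon: float = 30.0
    photon_threshold_fraction: float = 0.9
    loglik_cutoff: float = 5.0

    def __post_init__(self) -> None:
        if self.n_peaks_min < 1:
            raise ValueError("n_peaks_min must be >= 1")
        if self.particle_sigma_k <= 0:
            raise ValueError("particle_sigma_k must be > 0")
        if not 0 < self.photon_threshold_fraction < 1:
            raise ValueError("photon_threshold_fraction must be in (0, 1)")


@dataclass
class HitResult:
    is_hit: bool
    classifier: str
    n_peaks: int = 0
    resolution_radius: float = np.nan   # pixels
    resolution_d: float = np.nan        # Angstroms, when geometry known
    n_pixels_above: int = 0
    total_counts: float = np.nan
    loglik: float = np.nan


def resolution_radius_80(radii) -> float:
    """Smallest radius containing at least 80% of the items.

    The ceil(0.8 n)-th order statistic of the sorted radii — deliberately not
    the maximum, so a single outlier peak cannot inflate the resolution
    estimate.  Empty input returns NaN.
    """
    r = np.sort(np.asarray([x for x in np.ravel(radii) if np.isfinite(x)], dtype=float))
    if r.size == 0:
        return float("nan")
    k = math.ceil(0.8 * r.size)
    return float(r[k - 1])


def radius_to_d(radius_px: float, wavelength: float, detector_distance: float,
                pixel_pitch: float) -> float:
    """Bragg d-spacing for a detector radius: d = lambda / (2 sin(theta)),
    theta = atan(r * pitch / D) / 2.  Zero radius maps to infinity."""
    if wavelength <= 0 or detector_distance <= 0 or pixel_pitch <= 0:
        raise ValueError("wavelength, distance and pitch must be positive")
    if radius_px == 0:
        return float("inf")
    theta = 0.5 * math.atan2(radius_px * pixel_pitch, detector_distance)
    return wavelength / (2.0 * math.sin(theta))


def classify_crystal(peaks, p: HitParams) -> HitResult:
    """Hit iff strictly more than ``n_peaks_min`` peaks (and, when a
    resolution cutoff is set, the 80%-circle radius reaches it)."""
    n = len(peaks)
    radii = [pk.radius for pk in peaks]
    r80 = resolution_radius_80(radii)
    is_hit = n > p.n_peaks_min
    if p.resolution_cutoff is not None:
        is_hit = is_hit and np.isfinite(r80) and r80 >= p.resolution_cutoff
    return HitResult(is_hit=bool(is_hit), classifier="crystal_npeaks",
                     n_peaks=n, resolution_radius=r80)


def classify_particle(
    f: Frame,
    sigma_map: np.ndarray,
    p: HitParams,
    radius_px: np.ndarray | None = None,
) -> HitResult:
    """Count unmasked pixels with value > k * sigma(x, y) on a
    background-subtracted frame; hit iff the count reaches
    ``particle_npix_min``.  The discriminator is the pixel count, never the
    summed intensity."""
    if sigma_map is None:
        raise ValueError("classify_particle requires a per-pixel sigma map")
    if sigma_map.shape != f.data.shape:
        raise ValueError("sigma map shape must match frame shape")
    good = f.good_mask()
    above = good & (f.data > p.particle_sigma_k * sigma_map)
    n_above = int(np.count_nonzero(above))
    r80 = float("nan")
    if radius_px is not None and n_above:
        r80 = resolution_radius_80(radius_px[above])
    return HitResult(
        is_hit=n_above >= p.particle_npix_min,
        classifier="particle_npix",
        n_pixels_above=n_above,
        resolution_radius=r80,
        total_counts=float(np.sum(f.data[good])),
    )


def photon_count(f: Frame, adu_per_photon: float,
                 fraction: float = 0.9) -> tuple[np.ndarray, int]:
    """Per-pixel photon integers and their total.

    Pixels below ``fraction * adu_per_photon`` count zero photons; others
    round ``data / adu_per_photon`` to the nearest integer (minimum one, the
    threshold having established the pixel contains a photon).
    """
    if adu_per_photon <= 0:
        raise ValueError("adu_per_photon must be positive")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    data = f.data if isinstance(f, Frame) else np.asarray(f, dtype=float)
    counts = np.rint(data / adu_per_photon).astype(np.int64)
    counts = np.where(data >= fraction * adu_per_photon, np.maximum(counts, 1), 0)
    if isinstance(f, Frame):
        counts = np.where(f.good_mask(), counts, 0)
    return counts, int(counts.sum())


def loglik_metric(f: Frame, hist, pseudo: float = 1.0) -> float:
    """Average negative log empirical probability of the frame under the
    per-pixel background histograms.

    score = -(1/N) * sum_pixels log p_hat(value), with
    p_hat = (count + pseudo) / (n_frames + pseudo * n_bins) per pixel per bin.
    Higher means less background-like.
    """
    if hist.n_frames == 0:
        raise ValueError("pixel histograms are unpopulated")
    data = f.data if isinstance(f, Frame) else np.asarray(f, dtype=float)
    idx = hist.bin_index(data)
    counts = np.take_along_axis(hist.counts, idx[..., None], axis=-1)[..., 0]
    p = (counts + pseudo) / (hist.n_frames + pseudo * hist.n_bins)
    if isinstance(f, Frame):
        good = f.good_mask()
        logs = np.log(p)[good]
    else:
        logs = np.log(p)
    return float(-np.mean(logs))


def loglik_is_outlier(score: float, background_scores, cutoff: float) -> bool:
    """Flag a frame whose score sits more than ``cutoff`` robust spreads above
    the median score of background frames (spread = 1.4826 * MAD, floored)."""
    bg = np.asarray(background_scores, dtype=float)
    med = float(np.median(bg))
    spread = max(1.4826 * float(np.median(np.abs(bg - med))), 1e-12)
    return score - med > cutoff * spread
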