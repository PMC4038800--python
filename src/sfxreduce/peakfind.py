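"""Bragg-peak search on raw-layout frames.

Three procedures, all operating strictly module-by-module so that clusters
never cross a module boundary:

* :func:`find_peaks_static` — connected clusters of pixels above a fixed ADU
  threshold, with ``n_min < npix < n_max`` (strict bounds: the lower bound
  rejects single-pixel outliers, the upper bound overly diffuse blobs) and a
  retention test against the surrounding noise.

* :func:`find_peaks_pf8` — the radially adaptive variant ("peakfinder 8"):
  the per-pixel threshold is ``max(floor, <I(r)> + SNR * sigma(I(r)))`` from
  the frame's own radial statistics, exploiting the largely radial symmetry
  of solvent scattering.  The ADU floor guards almost-empty frames where the
  radial sigma collapses.

* :func:`find_peaks_local_snr` — local-maximum candidates (8-neighbour),
  background and noise measured in a concentric annulus around each
  candidate, acceptance on both the background-corrected intensity and the
  SNR, with nearby-peak deduplication keeping the highest-SNR peak.

Connectivity conventions: cluster growth is 4-connected (conservative);
local-maximum detection compares the eight nearest neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .corrections import FLAG_PEAK_MASKED, Frame
from .geometry import DetectorLayout

__all__ = [
    "Peak",
    "PeakList",
    "PeakFindParams",
    "RadialProfile",
    "connected_cluster",
    "radial_stats",
    "find_peaks_static",
    "find_peaks_pf8",
    "find_peaks_local_snr",
    "prescreen_region",
]

# 4-connectivity structure for cluster labelling.
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)

# Floor applied wherever an SNR divides by sigma, so noiseless synthetic
# frames do not produce infinities.
SIGMA_FLOOR = 1e-6


@dataclass
class Peak:
    """One detected Bragg spot in raw-layout coordinates."""

    centroid_row: float
    centroid_col: float
    module_id: int
    npix: int
    intensity: float          # background-corrected integrated ADU
    snr: float
    radius: float = np.nan    # pixels from the beam centre (NaN if no map)
    intensity_raw: float = np.nan  # integrated ADU before background removal

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.centroid_row, self.centroid_col)


class PeakList(list):
    """List of :class:`Peak` with tab-separated export."""

    COLUMNS = ("event_id", "module", "row", "col", "npix", "intensity",
               "intensity_raw", "snr", "radius")

    def to_array(self) -> np.ndarray:
        """(n, 8) float array: module, row, col, npix, I, I_raw, snr, radius."""
        if not self:
            return np.empty((0, 8))
        return np.array([
            [p.module_id, p.centroid_row, p.centroid_col, p.npix,
             p.intensity, p.intensity_raw, p.snr, p.radius]
            for p in self
        ])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "PeakList":
        out = cls()
        for row in np.atleast_2d(arr):
            if row.size == 0:
                continue
            out.append(Peak(
                module_id=int(row[0]), centroid_row=float(row[1]),
                centroid_col=float(row[2]), npix=int(row[3]),
                intensity=float(row[4]), intensity_raw=float(row[5]),
                snr=float(row[6]), radius=float(row[7]),
            ))
        return out

    def to_tsv(self, event_id: int = 0) -> str:
        lines = ["\t".join(self.COLUMNS)]
        for p in self:
            lines.append("\t".join(str(v) for v in (
                event_id, p.module_id, f"{p.centroid_row:.4f}", f"{p.centroid_col:.4f}",
                p.npix, f"{p.intensity:.4f}", f"{p.intensity_raw:.4f}",
                f"{p.snr:.4f}", f"{p.radius:.4f}")))
        return "\n".join(lines) + "\n"


@dataclass
class PeakFindParams:
    """Tunables shared by the three finders.

    ``adc_threshold`` is the static threshold / peakfinder8 floor in ADU
    (default 30); ``snr_threshold`` is dimensionless (robust defaults lie
    between 6 and 8).  Cluster sizes are accepted strictly between ``n_min``
    and ``n_max``.
    """

    algorithm: str = "peakfinder8"
    adc_threshold: float = 30.0
    snr_threshold: float = 7.0
    n_min: int = 1
    n_max: int = 40
    local_bg_radius: int = 3
    min_peak_separation: float = 5.0
    n_radial_bins: int | None = None   # None -> 1-pixel annuli

    def __post_init__(self) -> None:
        if not 1 <= self.n_min < self.n_max:
            raise ValueError("require 1 <= n_min < n_max")
        if self.adc_threshold <= 0 or self.snr_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class RadialProfile:
    """Per-annulus mean and standard deviation of unmasked intensity."""

    mean: np.ndarray
    sigma: np.ndarray
    counts: np.ndarray
    bin_edges: np.ndarray
    bin_index: np.ndarray = field(repr=False, default=None)

    def threshold_map(self, snr: float, floor: float) -> np.ndarray:
        """peakfinder8 per-pixel threshold: max(floor, mean + snr * sigma)."""
        t = self.mean + snr * self.sigma
        t = np.where(np.isfinite(t), t, -np.inf)
        return np.maximum(floor, t[self.bin_index])


def _radial_bin_index(radius_px: np.ndarray, n_bins: int | None) -> tuple[np.ndarray, np.ndarray]:
    rmax = float(np.max(radius_px))
    if n_bins is None:  # 1-pixel-wide annuli
        edges = np.arange(0.0, np.floor(rmax) + 2.0)
    else:
        edges = np.linspace(0.0, rmax + 1e-9, n_bins + 1)
    idx = np.clip(np.digitize(radius_px, edges) - 1, 0, len(edges) - 2)
    return idx.astype(np.int64), edges


def radial_stats(
    frame,
    radius_px: np.ndarray,
    n_bins: int | None = None,
    good: np.ndarray | None = None,
    clip_sigma: float = 2.5,
    max_iter: int = 10,
) -> RadialProfile:
    """Mean and sigma of intensity per radial annulus, with iterative
    exclusion of obvious peaks (pixels more than ``clip_sigma`` sigma above
    their annulus mean are removed and the statistics recomputed, up to
    ``max_iter`` passes or until stable).

    Empty bins carry count 0 and NaN mean/sigma.
    """
    data = frame.data if isinstance(frame, Frame) else np.asarray(frame, dtype=float)
    if radius_px.shape != data.shape:
        raise ValueError("radius map shape must match frame shape")
    if good is None:
        good = frame.good_mask() if isinstance(frame, Frame) else np.ones(data.shape, bool)
    bin_idx, edges = _radial_bin_index(radius_px, n_bins)
    nb = len(edges) - 1

    include = good.copy()
    mean = sigma = None
    for _ in range(max_iter):
        flat_idx = bin_idx[include]
        vals = data[include]
        cnt = np.bincount(flat_idx, minlength=nb).astype(float)
        s1 = np.bincount(flat_idx, weights=vals, minlength=nb)
        s2 = np.bincount(flat_idx, weights=vals * vals, minlength=nb)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(cnt > 0, s1 / cnt, np.nan)
            var = np.where(cnt > 0, s2 / cnt - (s1 / np.maximum(cnt, 1)) ** 2, np.nan)
        sigma = np.sqrt(np.clip(var, 0.0, None))
        cut = mean[bin_idx] + clip_sigma * sigma[bin_idx]
        new_include = good & ~(data > cut)
        if np.array_equal(new_include, include):
            break
        include = new_include

    cnt_final = np.bincount(bin_idx[include], minlength=nb).astype(np.int64)
    return RadialProfile(mean=mean, sigma=sigma, counts=cnt_final,
                         bin_edges=edges, bin_index=bin_idx)


def connected_cluster(
    data: np.ndarray,
    seed: tuple[int, int],
    threshold: float,
    layout: DetectorLayout | None = None,
) -> set[tuple[int, int]]:
    """Maximal 4-connected set of above-threshold pixels containing ``seed``,
    confined to the seed's module."""
    data = np.asarray(data, dtype=float)
    if data[seed] <= threshold:
        raise ValueError("seed pixel is not above threshold")
    if layout is None:
        sl = (slice(0, data.shape[0]), slice(0, data.shape[1]))
    else:
        mid = layout.module_id_map()[seed]
        sl = layout.module_slice(int(mid))
    sub = data[sl] > threshold
    labels, _ = ndimage.label(sub, structure=_STRUCT4)
    lab = labels[seed[0] - sl[0].start, seed[1] - sl[1].start]
    rr, cc = np.nonzero(labels == lab)
    return {(int(r + sl[0].start), int(c + sl[1].start)) for r, c in zip(rr, cc)}


def _local_sigma(data: np.ndarray, good: np.ndarray, member_mask: np.ndarray,
                 bbox: tuple[int, int, int, int], margin: int) -> float:
    """Noise level around a cluster: sigma of good, non-member pixels in the
    bounding box dilated by ``margin`` (clipped to the module array)."""
    r0, r1, c0, c1 = bbox
    r0 = max(0, r0 - margin); c0 = max(0, c0 - margin)
    r1 = min(data.shape[0], r1 + margin); c1 = min(data.shape[1], c1 + margin)
    sel = good[r0:r1, c0:c1] & ~member_mask[r0:r1, c0:c1]
    if np.count_nonzero(sel) < 2:
        return SIGMA_FLOOR
    return max(float(np.std(data[r0:r1, c0:c1][sel])), SIGMA_FLOOR)


def _clusters_to_peaks(
    data: np.ndarray,
    background: np.ndarray | None,
    candidate: np.ndarray,
    good: np.ndarray,
    params: PeakFindParams,
    layout: DetectorLayout | None,
    radius_px: np.ndarray | None,
    sigma_of_pixel: np.ndarray | None,
) -> PeakList:
    """Shared cluster -> Peak stage: label candidates per module, apply the
    strict size bounds, intensity-weighted centroid, noise-retention test."""
    peaks = PeakList()
    modules = ([(0, (slice(0, data.shape[0]), slice(0, data.shape[1])))]
               if layout is None else list(layout.iter_modules()))
    bgsub = data - background if background is not None else data
    for m, sl in modules:
        cand = candidate[sl]
        if not cand.any():
            continue
        labels, nlab = ndimage.label(cand, structure=_STRUCT4)
        if nlab == 0:
            continue
        member_mask = np.zeros(cand.shape, bool)
        objects = ndimage.find_objects(labels)
        sub_data = data[sl]
        sub_bgsub = bgsub[sl]
        sub_good = good[sl]
        for lab, obj in enumerate(objects, start=1):
            rows, cols = np.nonzero(labels[obj] == lab)
            npix = rows.size
            if not (params.n_min < npix < params.n_max):
                continue
            rows = rows + obj[0].start
            cols = cols + obj[1].start
            w = sub_bgsub[rows, cols]
            wsum = float(np.sum(w))
            if wsum <= 0:
                continue
            cr = float(np.sum(w * rows) / wsum)
            cc = float(np.sum(w * cols) / wsum)
            # retention: integrated intensity sufficiently above surrounding noise
            if sigma_of_pixel is not None:
                sig = max(float(np.median(sigma_of_pixel[sl][rows, cols])), SIGMA_FLOOR)
            else:
                member_mask[:] = False
                member_mask[rows, cols] = True
                bbox = (rows.min(), rows.max() + 1, cols.min(), cols.max() + 1)
                sig = _local_sigma(sub_bgsub, sub_good, member_mask, bbox,
                                   params.local_bg_radius)
            snr = wsum / (np.sqrt(npix) * sig)
            if snr <= params.snr_threshold:
                continue
            gr, gc = cr + sl[0].start, cc + sl[1].start
            rad = np.nan
            if radius_px is not None:
                rad = float(radius_px[int(round(gr)), int(round(gc))])
            peaks.append(Peak(
                centroid_row=gr, centroid_col=gc, module_id=m, npix=int(npix),
                intensity=wsum, snr=float(snr), radius=rad,
                intensity_raw=float(np.sum(sub_data[rows, cols])),
            ))
    return peaks


def _good_for_peaks(f: Frame) -> np.ndarray:
    return f.good_mask() & ((f.flags & FLAG_PEAK_MASKED) == 0)


def find_peaks_static(
    f: Frame,
    params: PeakFindParams,
    layout: DetectorLayout | None = None,
    radius_px: np.ndarray | None = None,
) -> PeakList:
    """Connected clusters above a fixed ADU threshold."""
    good = _good_for_peaks(f)
    candidate = (f.data > params.adc_threshold) & good
    return _clusters_to_peaks(f.data, None, candidate, good, params, layout,
                              radius_px, None)


def find_peaks_pf8(
    f: Frame,
    params: PeakFindParams,
    radius_px: np.ndarray,
    layout: DetectorLayout | None = None,
    profile: RadialProfile | None = None,
) -> PeakList:
    """Radially adaptive threshold search ("peakfinder 8").

    The per-pixel threshold is ``max(adc_threshold, <I(r)> + SNR * sigma(r))``
    from the frame's own radial statistics (computed here unless supplied).
    Peak intensity is integrated above the radial mean.
    """
    good = _good_for_peaks(f)
    if profile is None:
        profile = radial_stats(f, radius_px, n_bins=params.n_radial_bins, good=good)
    tmap = profile.threshold_map(params.snr_threshold, params.adc_threshold)
    candidate = (f.data > tmap) & good
    bg = np.where(np.isfinite(profile.mean[profile.bin_index]),
                  profile.mean[profile.bin_index], 0.0)
    sig = np.where(np.isfinite(profile.sigma[profile.bin_index]),
                   profile.sigma[profile.bin_index], 0.0)
    return _clusters_to_peaks(f.data, bg, candidate, good, params, layout,
                              radius_px, sigma_of_pixel=sig)


def _annulus_stats(data: np.ndarray, good: np.ndarray, row: int, col: int,
                   r_in: float, r_out: float) -> tuple[float, float, int]:
    r0 = max(0, int(np.floor(row - r_out))); r1 = min(data.shape[0], int(np.ceil(row + r_out)) + 1)
    c0 = max(0, int(np.floor(col - r_out))); c1 = min(data.shape[1], int(np.ceil(col + r_out)) + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(rr - row, cc - col)
    sel = (d >= r_in) & (d <= r_out) & good[r0:r1, c0:c1]
    n = int(np.count_nonzero(sel))
    if n == 0:
        return np.nan, np.nan, 0
    vals = data[r0:r1, c0:c1][sel]
    return float(np.mean(vals)), max(float(np.std(vals)), SIGMA_FLOOR), n


def find_peaks_local_snr(
    f: Frame,
    params: PeakFindParams,
    layout: DetectorLayout | None = None,
    radius_px: np.ndarray | None = None,
    annulus_inner: float | None = None,
    annulus_width: float = 2.0,
) -> PeakList:
    """Local-SNR finder for frames with non-isotropic noise (e.g. coherent
    speckle in the water ring).

    Per module: strict 8-neighbour local maxima above the ADU threshold are
    candidates; background mean and sigma come from a concentric annulus;
    a candidate is accepted when both ``I - <I>`` and ``(I - <I>)/sigma``
    exceed their thresholds; connected qualifying pixels are counted against
    the strict (n_min, n_max) bounds; peaks closer than
    ``min_peak_separation`` are deduplicated keeping the highest SNR.
    """
    good = _good_for_peaks(f)
    r_in = annulus_inner if annulus_inner is not None else params.local_bg_radius + 1.0
    r_out = r_in + annulus_width
    peaks = PeakList()
    modules = ([(0, (slice(0, data.shape[0]), slice(0, data.shape[1])))]
               if layout is None else list(layout.iter_modules()))
    for m, sl in modules:
        data = f.data[sl]
        g = good[sl]
        above = (data > params.adc_threshold) & g
        if not above.any():
            continue
        # strict local maxima: no 8-neighbour strictly greater
        neigh_max = ndimage.maximum_filter(np.where(g, data, -np.inf), size=3,
                                           mode="constant", cval=-np.inf)
        is_max = above & (data >= neigh_max)
        claimed = np.zeros(data.shape, bool)
        cand_order = np.argsort(data[is_max])[::-1]
        rows, cols = np.nonzero(is_max)
        module_peaks: list[Peak] = []
        for k in cand_order:
            r, c = int(rows[k]), int(cols[k])
            if claimed[r, c]:
                continue
            mean, sig, n = _annulus_stats(data, g, r, c, r_in, r_out)
            if n == 0:
                continue  # annulus entirely masked
            excess = data[r, c] - mean
            snr = excess / sig
            if excess < params.adc_threshold or snr < params.snr_threshold:
                continue
            qual = (data - mean >= params.snr_threshold * sig) & \
                   (data > params.adc_threshold) & g
            labels, _ = ndimage.label(qual, structure=_STRUCT4)
            lab = labels[r, c]
            if lab == 0:
                continue
            mrows, mcols = np.nonzero(labels == lab)
            claimed[mrows, mcols] = True
            npix = mrows.size
            if not (params.n_min < npix < params.n_max):
                continue
            w = np.clip(data[mrows, mcols] - mean, 0.0, None)
            wsum = float(np.sum(w))
            if wsum <= 0:
                continue
            cr = float(np.sum(w * mrows) / wsum) + sl[0].start
            cc = float(np.sum(w * mcols) / wsum) + sl[1].start
            rad = np.nan
            if radius_px is not None:
                rad = float(radius_px[int(round(cr)), int(round(cc))])
            module_peaks.append(Peak(
                centroid_row=cr, centroid_col=cc, module_id=m, npix=int(npix),
                intensity=wsum, snr=float(snr), radius=rad,
                intensity_raw=float(np.sum(data[mrows, mcols])),
            ))
        # nearby-peak dedup within the module: keep the highest SNR
        kept: list[Peak] = []
        for p in sorted(module_peaks, key=lambda q: -q.snr):
            if all(np.hypot(p.centroid_row - q.centroid_row,
                            p.centroid_col - q.centroid_col) >= params.min_peak_separation
                   for q in kept):
                kept.append(p)
        peaks.extend(kept)
    return peaks


def prescreen_region(
    f: Frame,
    region_mask: np.ndarray,
    params: PeakFindParams,
    min_region_peaks: int,
    layout: DetectorLayout | None = None,
    radius_px: np.ndarray | None = None,
    finder=None,
) -> tuple[str, PeakList]:
    """Run the finder on a detector sub-region first; the full-frame search is
    worthwhile only when the region already yields ``min_region_peaks`` peaks.

    Returns ``("continue", region_peaks)`` or ``("skip", region_peaks)``.
    Blank frames are eliminated after examining only the region — the speedup
    the prescreen exists for; peaks lying entirely outside the region are its
    documented false-negative mode.
    """
    if region_mask.shape != f.data.shape:
        raise ValueError("region mask shape must match frame shape")
    masked = f.copy()
    masked.flags[~region_mask] |= FLAG_PEAK_MASKED
    if finder is None:
        finder = lambda fr: find_peaks_pf8(fr, params, radius_px, layout=layout) \
            if params.algorithm == "peakfinder8" else find_peaks_static(fr, params, layout,
                                                                        radius_px)
    region_peaks = finder(masked)
    decision = "continue" if len(region_peaks) >= min_region_peaks else "skip"
    return decision, region_peaks
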