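"""Deterministic synthetic frame streams with known ground truth.

The generator emulates the statistical structure the reduction algorithms
assume: a tiled module layout with per-pixel dark offsets and gain spread, a
few hot pixels, Gaussian read noise plus Poisson photon noise, an isotropic
solvent ring whose amplitude jitters (and whose radius breathes) shot to
shot, crystal hits as randomly placed 2-D Gaussian Bragg spots with contrast
drawn relative to the local noise level, and particle hits as a small number
of photons scattered under a low-q speckle envelope.

It does *not* simulate physical diffraction (no lattices, no molecular
transforms, no polarization, no detector point-spread): spots are placed at
random, which is exactly what makes planted-truth recovery metrics
unambiguous.  Every stream is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np

from .corrections import CalibrationSet, Frame
from .geometry import DetectorLayout, PixelMap, radius_map

__all__ = ["SynthSpec", "PlantedSpot", "TruthTable", "generate_stream",
           "worked_example_frames"]


@dataclass(frozen=True)
class PlantedSpot:
    module_id: int
    row: float
    col: float
    amplitude: float  # peak ADU above background


@dataclass
class TruthRecord:
    event_id: int
    label: str                  # "hit" | "blank" | "particle"
    ring_scale: float
    spots: list[PlantedSpot] = field(default_factory=list)


class TruthTable(list):
    """Per-frame ground truth, exportable as tab-separated text."""

    def to_tsv(self) -> str:
        lines = ["event_id\tlabel\tring_scale\tmodule\trow\tcol\tamplitude"]
        for rec in self:
            if rec.spots:
                for s in rec.spots:
                    lines.append(f"{rec.event_id}\t{rec.label}\t{rec.ring_scale:.6f}\t"
                                 f"{s.module_id}\t{s.row:.4f}\t{s.col:.4f}\t{s.amplitude:.4f}")
            else:
                lines.append(f"{rec.event_id}\t{rec.label}\t{rec.ring_scale:.6f}\t\t\t\t")
        return "\n".join(lines) + "\n"

    def n_planted(self) -> int:
        return sum(len(rec.spots) for rec in self)


@dataclass
class SynthSpec:
    """Study conditions for one synthetic stream.

    Defaults describe a desk-scale run: a 2x2 tiling of 64x64-pixel modules
    (128x128 raw array), 200 frames at a 10% crystal hit rate, a solvent ring
    of ~100 ADU with 10% shot-to-shot amplitude jitter and sub-pixel radial
    breathing, 30 ADU per photon with Poisson noise, 10 ADU read noise,
    per-module common-mode jitter of 5 ADU referenced by a shadowed corner
    block, and Bragg spots of width 1.3 px whose peak contrast is drawn
    uniformly between 10 and 30 local noise sigma.
    """

    layout: DetectorLayout = field(default_factory=lambda: DetectorLayout((64, 64), (2, 2)))
    pixel_pitch: float = 110e-6
    # detector artefacts
    dark_mean: float = 50.0
    dark_spread: float = 5.0
    gain_spread: float = 0.02
    n_hot: int = 3
    hot_value: float = 5000.0
    cm_sigma: float = 5.0         # ADU, per-module per-shot common-mode jitter
    shadow_size: int = 4          # px, shadowed corner block per module
    # noise model: read noise of order a third of a photon, as for
    # CSPAD-class integrating detectors where single photons sit only a few
    # sigma above electronic noise
    sigma_read: float = 10.0
    adu_per_photon: float = 30.0
    poisson: bool = True
    # solvent ring background
    ring_radius: float = 40.0     # px
    ring_width: float = 8.0       # px (Gaussian sigma of the ring profile)
    ring_amplitude: float = 100.0  # ADU at the ring crest
    ring_jitter: float = 0.10     # fractional shot-to-shot amplitude scale
    ring_breathing: float = 0.5   # px sigma of shot-to-shot radius shift
    # crystal-hit model
    peaks_per_hit: tuple[int, int] = (25, 45)   # uniform integer range
    spot_sigma: float = 1.3       # px
    spot_contrast: tuple[float, float] = (10.0, 30.0)  # x local noise sigma
    min_peak_separation: float = 6.0
    edge_margin: int = 6
    # particle-hit model
    particle_photons_mean: float = 100.0
    speckle_scale: float = 12.0   # px envelope decay
    # stream
    n_frames: int = 200
    hit_rate: float = 0.10
    mode: str = "crystal"         # "crystal" | "particle" | "blank"
    seed: int = 0


def _make_pixelmap(spec: SynthSpec) -> PixelMap:
    rows, cols = spec.layout.raw_shape
    center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    return PixelMap.from_layout(spec.layout, pixel_pitch=spec.pixel_pitch, center=center)


def _ring_profile(radius_px: np.ndarray, spec: SynthSpec, shift: float) -> np.ndarray:
    return spec.ring_amplitude * np.exp(
        -0.5 * ((radius_px - (spec.ring_radius + shift)) / spec.ring_width) ** 2)


def _noise_sigma_at(ring_adu: np.ndarray, spec: SynthSpec) -> np.ndarray:
    """Local noise level in ADU: read noise plus Poisson at adu_per_photon.

    Floored at 1 ADU so that spot contrast stays meaningful in noiseless
    configurations (contrast is then simply ADU).
    """
    poiss_var = ring_adu * spec.adu_per_photon if spec.poisson else 0.0
    return np.maximum(np.sqrt(spec.sigma_read**2 + poiss_var), 1.0)


def _place_spots(rng: np.random.Generator, spec: SynthSpec, n_spots: int):
    """Rejection-sample spot centres inside module interiors, no two closer
    than min_peak_separation.  Returns (positions, n_rejected)."""
    rows, cols = spec.layout.raw_shape
    mid = spec.layout.module_id_map()
    placed: list[tuple[float, float]] = []
    rejected = 0
    attempts = 0
    while len(placed) < n_spots and attempts < 200 * n_spots:
        attempts += 1
        r = rng.uniform(0, rows)
        c = rng.uniform(0, cols)
        m = int(mid[int(r), int(c)])
        sl = spec.layout.module_slice(m)
        if not (sl[0].start + spec.edge_margin <= r < sl[0].stop - spec.edge_margin
                and sl[1].start + spec.edge_margin <= c < sl[1].stop - spec.edge_margin):
            rejected += 1
            continue
        if any(np.hypot(r - pr, c - pc) < spec.min_peak_separation for pr, pc in placed):
            rejected += 1
            continue
        placed.append((r, c))
    return placed, rejected


def _render_spot(signal: np.ndarray, row: float, col: float, amp: float,
                 sigma: float, module_slice) -> None:
    """Add a 2-D Gaussian spot, truncated at 3 sigma and at module edges."""
    ext = int(np.ceil(3 * sigma))
    r0 = max(module_slice[0].start, int(np.floor(row)) - ext)
    r1 = min(module_slice[0].stop, int(np.ceil(row)) + ext + 1)
    c0 = max(module_slice[1].start, int(np.floor(col)) - ext)
    c1 = min(module_slice[1].stop, int(np.ceil(col)) + ext + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    signal[r0:r1, c0:c1] += amp * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma**2))


def generate_stream(spec: SynthSpec):
    """Generate (frames, truth, calibration, pixelmap).

    Frames carry artefacts in physical order: signal -> Poisson photon noise
    -> inverse gain -> dark offset -> read noise -> hot pixels.  The exact
    planted hit count is round(n_frames * hit_rate); per-frame labels, spot
    positions/amplitudes and ring scales are recorded in the truth table.
    """
    rng = np.random.default_rng(spec.seed)
    layout = spec.layout
    shape = layout.raw_shape
    pm = _make_pixelmap(spec)
    rpx = radius_map(pm)  # pixel units, beam at detector centre

    dark = spec.dark_mean + spec.dark_spread * rng.standard_normal(shape)
    gain_factor = 1.0 + spec.gain_spread * rng.standard_normal(shape)  # pixel response
    gain_factor = np.clip(gain_factor, 0.5, 2.0)
    hot_mask = np.zeros(shape, bool)
    if spec.n_hot:
        flat = rng.choice(shape[0] * shape[1], size=spec.n_hot, replace=False)
        hot_mask.ravel()[flat] = True
    # physically shadowed corner block per module: sees dark + common mode
    # only, and serves as the common-mode reference region
    shadow_mask = np.zeros(shape, bool)
    if spec.shadow_size:
        for _m, sl in layout.iter_modules():
            shadow_mask[sl[0].start:sl[0].start + spec.shadow_size,
                        sl[1].start:sl[1].start + spec.shadow_size] = True
    cal = CalibrationSet(dark=dark, gain=gain_factor, badpixel_mask=hot_mask,
                         shadow_mask=shadow_mask if spec.shadow_size else None,
                         saturation_level=spec.hot_value)

    n_hits = int(round(spec.n_frames * spec.hit_rate)) if spec.mode != "blank" else 0
    hit_ids = set(rng.choice(spec.n_frames, size=n_hits, replace=False).tolist())

    mid_map = layout.module_id_map()
    envelope = np.exp(-rpx / spec.speckle_scale)
    env_p = (envelope / envelope.sum()).ravel()

    frames: list[Frame] = []
    truth = TruthTable()
    for i in range(spec.n_frames):
        ring_scale = max(0.0, 1.0 + spec.ring_jitter * rng.standard_normal())
        shift = spec.ring_breathing * rng.standard_normal()
        signal = ring_scale * _ring_profile(rpx, spec, shift)

        label = "blank"
        spots: list[PlantedSpot] = []
        if i in hit_ids and spec.mode == "crystal":
            label = "hit"
            n_spots = int(rng.integers(spec.peaks_per_hit[0], spec.peaks_per_hit[1] + 1))
            placed, _ = _place_spots(rng, spec, n_spots)
            for r, c in placed:
                m = int(mid_map[int(r), int(c)])
                local_sigma = float(_noise_sigma_at(signal[int(r), int(c)], spec))
                amp = rng.uniform(*spec.spot_contrast) * local_sigma
                _render_spot(signal, r, c, amp, spec.spot_sigma, layout.module_slice(m))
                spots.append(PlantedSpot(m, r, c, amp))
        elif i in hit_ids and spec.mode == "particle":
            label = "particle"
            n_photons = int(rng.poisson(spec.particle_photons_mean))
            pix = rng.choice(env_p.size, size=n_photons, p=env_p)
            np.add.at(signal.ravel(), pix, spec.adu_per_photon)

        if spec.shadow_size:
            signal[shadow_mask] = 0.0
        if spec.poisson:
            photons = rng.poisson(np.clip(signal, 0, None) / spec.adu_per_photon)
            signal_noisy = photons * spec.adu_per_photon
        else:
            signal_noisy = signal
        data = signal_noisy / gain_factor + dark + \
            spec.sigma_read * rng.standard_normal(shape)
        if spec.cm_sigma:
            for _m, sl in layout.iter_modules():
                data[sl] += spec.cm_sigma * rng.standard_normal()
        data[hot_mask] = spec.hot_value

        frames.append(Frame(data=data, event_id=i))
        truth.append(TruthRecord(event_id=i, label=label, ring_scale=ring_scale,
                                 spots=spots))
    return frames, truth, cal, pm


def worked_example_frames() -> SimpleNamespace:
    """Hand-sized fixtures with enumerable pixels for oracle tests.

    * ``layout`` / ``blank``: two 8x8 modules side by side (raw 8x16).
    * ``boundary_blob``: a 6-pixel blob straddling the module boundary at
      column 8 — cluster growth must return only the seed-side half.
    * ``median_fixture``: flat field of 10 with one pixel at 1000 — a width-7
      (r=3) local median must report background 10 under the outlier.
    * ``radii_1_to_10``: peak radii 1..10, whose 80%-circle radius is the 8th
      order statistic.
    """
    layout = DetectorLayout((8, 8), (1, 2))
    blank = np.zeros(layout.raw_shape)

    boundary_blob = blank.copy()
    for r, c in [(3, 6), (3, 7), (4, 7), (3, 8), (3, 9), (2, 8)]:
        boundary_blob[r, c] = 50.0

    median_fixture = np.full(layout.raw_shape, 10.0)
    median_fixture[4, 4] = 1000.0

    return SimpleNamespace(
        layout=layout,
        blank=blank,
        boundary_blob=boundary_blob,
        median_fixture=median_fixture,
        radii_1_to_10=list(range(1, 11)),
    )
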