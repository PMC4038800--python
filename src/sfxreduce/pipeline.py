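"""Run orchestration: the per-frame reduction loop.

For every frame: detector correction -> optional region prescreen ->
background handling per policy -> peak search -> hit classification ->
export of hits -> update of the non-hit background buffer -> accumulation of
reduced products.  Hits are never pushed into the background buffer; non-hits
always are — that feedback loop is what keeps the running background current.

Sequential mode is the reference behaviour and is bit-reproducible for a
fixed configuration and stream.  "Parallel" processing is specified here as a
contract rather than a mechanism: once the background buffer is frozen (after
an optional warmup prefix), per-frame results no longer depend on processing
order, so any scheduler yields the same hit set and accumulator sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import background as bg
from . import peakfind as pf
from .config import RunConfig, serialize_config
from .corrections import (CalibrationSet, CorrectionOptions, FLAG_HOT, Frame,
                          correct_frame)
from .events import EventRecord, append_hitlist, iter_frames, write_event
from .geometry import DetectorLayout, ModuleTable, PixelMap, radius_map
from .hitfind import HitParams, HitResult, classify_crystal, classify_particle
from .reduce import (PixelHistograms, PowderAccumulator, RadialStack,
                     RunStatistics, radial_average)

log = logging.getLogger(__name__)

__all__ = ["RunResult", "process_run"]


@dataclass
class RunResult:
    stats: RunStatistics
    powder: PowderAccumulator
    stack: RadialStack
    histograms: PixelHistograms
    hit_event_ids: list[int] = field(default_factory=list)
    hitlist_path: Path | None = None
    events_written: int = 0


def _layout_from_pixelmap(pm: PixelMap):
    """Declared layout if present, else module boundaries recovered from the
    per-pixel module_id map."""
    return pm.layout if pm.layout is not None else ModuleTable(pm.module_id)


def _peak_params(cfg: RunConfig) -> pf.PeakFindParams:
    return pf.PeakFindParams(
        algorithm=cfg.algorithm,
        adc_threshold=cfg.adc_threshold,
        snr_threshold=cfg.snr_threshold,
        n_min=cfg.n_min,
        n_max=cfg.n_max,
        local_bg_radius=cfg.local_bg_radius,
        min_peak_separation=cfg.min_peak_separation,
        n_radial_bins=cfg.n_radial_bins or None,
    )


def _hit_params(cfg: RunConfig) -> HitParams:
    return HitParams(
        n_peaks_min=cfg.n_peaks_min,
        resolution_cutoff=cfg.resolution_cutoff,
        particle_sigma_k=cfg.particle_sigma_k,
        particle_npix_min=cfg.particle_npix_min,
        adu_per_photon=cfg.adu_per_photon,
        photon_threshold_fraction=cfg.photon_threshold_fraction,
        loglik_cutoff=cfg.loglik_cutoff,
    )


def _find_peaks(frame: Frame, cfg: RunConfig, params, layout, radius_px,
                beam_rc) -> pf.PeakList:
    if cfg.prescreen:
        r_cut = cfg.prescreen_radius or 0.25 * float(np.max(radius_px))
        region = radius_px <= r_cut
        decision, region_peaks = pf.prescreen_region(
            frame, region, params, cfg.prescreen_min_peaks, layout=layout,
            radius_px=radius_px)
        if decision == "skip":
            return region_peaks
    if cfg.algorithm == "peakfinder8":
        return pf.find_peaks_pf8(frame, params, radius_px, layout=layout)
    if cfg.algorithm == "static":
        return pf.find_peaks_static(frame, params, layout=layout, radius_px=radius_px)
    if cfg.algorithm == "localsnr":
        return pf.find_peaks_local_snr(frame, params, layout=layout, radius_px=radius_px)
    raise ValueError(f"unknown algorithm {cfg.algorithm!r}")


def process_run(
    source,
    cfg: RunConfig,
    pixelmap: PixelMap,
    calibration: CalibrationSet | None = None,
    layout: DetectorLayout | None = None,
    freeze_background: bool = False,
    write_outputs: bool | None = None,
) -> RunResult:
    """Process a frame stream and return the accumulated run products.

    ``source`` is a path (stacked HDF5 or directory of per-frame files) or an
    iterable of frames.  ``freeze_background`` stops buffer updates entirely
    (calibration-replay mode); ``cfg.freeze_after > 0`` freezes the buffer
    after that many frames.  Per-frame processing errors skip the frame
    (counted and logged) — long streams must survive bad frames.
    """
    layout = layout or _layout_from_pixelmap(pixelmap)
    cal = calibration or CalibrationSet(saturation_level=cfg.saturation_level)
    if cfg.saturation_level is not None:
        cal.saturation_level = cfg.saturation_level
    opts = CorrectionOptions(saturation=cfg.do_saturation, dark=cfg.do_dark,
                             common_mode=cfg.do_common_mode, gain=cfg.do_gain,
                             mask=cfg.do_mask)
    params = _peak_params(cfg)
    hp = _hit_params(cfg)

    beam = (cfg.beam_center_x, cfg.beam_center_y)
    radius_px = radius_map(pixelmap, beam_center=beam)
    n_rbins = cfg.n_radial_bins or int(np.floor(radius_px.max())) + 1
    bin_idx, _edges = pf._radial_bin_index(radius_px,
                                           cfg.n_radial_bins or None)

    shape = pixelmap.raw_shape
    buf = bg.BackgroundBuffer(cfg.buffer_depth, shape,
                              recompute_period=cfg.recompute_period or None)
    stats = RunStatistics(cfg.frame_rate_hz, cfg.window_seconds)
    powder = PowderAccumulator(shape)
    stack = RadialStack(n_rbins)
    hist = PixelHistograms.for_adu_range(
        shape, lo=-4 * cfg.adu_per_photon, hi=16 * cfg.adu_per_photon,
        bin_width=cfg.adu_per_photon / 4.0)

    if write_outputs is None:
        write_outputs = cfg.write_events
    outdir = Path(cfg.output_dir)
    hitlist_path = None
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
        hitlist_path = outdir / "hits.lst"
        if hitlist_path.exists():
            if not cfg.overwrite:
                raise FileExistsError(f"{hitlist_path} exists; set overwrite")
            hitlist_path.unlink()
        (outdir / "run_config.log").write_text(serialize_config(cfg))

    result = RunResult(stats=stats, powder=powder, stack=stack, histograms=hist,
                       hitlist_path=hitlist_path)

    lbp = bg.LocalBackgroundParams(radius=cfg.local_bg_radius)
    n_seen = 0
    for frame in iter_frames(source):
        if cfg.limit and n_seen >= cfg.limit:
            break
        n_seen += 1
        try:
            _process_one(frame, cfg, cal, opts, params, hp, layout, radius_px,
                         bin_idx, n_rbins, buf, lbp, stats, powder, stack, hist,
                         result, beam, freeze_background, write_outputs, outdir)
        except Exception:  # noqa: BLE001 — skip bad frames, keep the stream alive
            stats.skipped += 1
            log.exception("event=%s skipped", frame.event_id)
    return result


def _process_one(frame, cfg, cal, opts, params, hp, layout, radius_px, bin_idx,
                 n_rbins, buf, lbp, stats, powder, stack, hist, result, beam,
                 freeze_background, write_outputs, outdir) -> None:
    if frame.data.shape != radius_px.shape:
        raise ValueError(
            f"frame shape {frame.data.shape} does not match geometry {radius_px.shape}")

    corrected = correct_frame(frame, cal, layout=layout, opts=opts)

    # flag hot pixels known from the running buffer
    if cfg.hot_level is not None and buf.n_filled >= 2:
        corrected.flags[buf.hot_mask(cfg.hot_level, cfg.hot_fraction)] |= FLAG_HOT

    hist.add(corrected)

    # background handling for peak search
    if cfg.background_mode == "running" and buf.n_filled > 0:
        search_frame = bg.subtract_running(corrected, buf)
    elif cfg.background_mode == "local":
        _bgimg, search_frame = bg.local_background(corrected, lbp, layout)
    else:
        search_frame = corrected

    if cfg.mode == "crystal":
        peaks = _find_peaks(search_frame, cfg, params, layout, radius_px, beam)
        hit = classify_crystal(peaks, hp)
    else:
        peaks = pf.PeakList()
        if buf.n_filled >= 2:
            hit = classify_particle(bg.subtract_running(corrected, buf),
                                    buf.sigma(), hp, radius_px=radius_px)
        else:
            hit = HitResult(is_hit=False, classifier="particle_npix")

    if hit.is_hit:
        result.hit_event_ids.append(frame.event_id)
        if write_outputs:
            saved = search_frame if cfg.save_policy == "subtracted" else corrected
            rec = EventRecord(event_id=frame.event_id, frame=saved, peaks=peaks,
                              hit=hit)
            write_event(rec, outdir / f"event_{frame.event_id:06d}.h5",
                        overwrite=cfg.overwrite)
            append_hitlist(result.hitlist_path, frame.event_id)
            result.events_written += 1
    elif not freeze_background and not (cfg.freeze_after and
                                        stats.frames >= cfg.freeze_after):
        buf.push(corrected)

    powder.add(corrected, hit.is_hit, "corrected")
    powder.add(search_frame, hit.is_hit, "subtracted")
    stack.append(radial_average(corrected, bin_idx, n_rbins,
                                good=corrected.good_mask()),
                 key=corrected.metadata.get("delay"))
    stats.update(hit)
    log.info("event=%s hit=%s n_peaks=%s", frame.event_id, hit.is_hit, hit.n_peaks)
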