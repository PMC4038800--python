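"""Run configuration: an ini-style file covering every pipeline tunable.

Unknown keys are rejected with their location; values are type- and
range-checked before any frame is processed; the fully resolved configuration
is echoed to the run log for provenance, and re-parsing the echo reproduces
the configuration exactly.
"""

from __future__ import annotations

import configparser
import io
from dataclasses import dataclass, fields


class ConfigError(ValueError):
    pass


def _opt_float(s: str):
    return None if s.strip() == "" else float(s)


def _opt_str(s: str):
    return None if s.strip() == "" else s.strip()


def _bool(s: str) -> bool:
    t = s.strip().lower()
    if t in ("1", "true", "yes", "on"):
        return True
    if t in ("0", "false", "no", "off"):
        return False
    raise ValueError(f"not a boolean: {s!r}")


@dataclass
class RunConfig:
    """All tunables of the reduction pipeline with their documented defaults."""

    # [geometry]
    geometry_path: str | None = None
    beam_center_x: float = 0.0        # physical metres
    beam_center_y: float = 0.0
    # [corrections]
    calibration_path: str | None = None
    do_saturation: bool = True
    do_dark: bool = True
    do_common_mode: bool = True
    do_gain: bool = True
    do_mask: bool = True
    saturation_level: float | None = None
    # [background]
    background_mode: str = "running"  # running | local | none
    buffer_depth: int = 50
    recompute_period: int = 0         # 0 -> depth // 2
    hot_level: float | None = None
    hot_fraction: float = 0.8
    local_bg_radius: int = 3
    # [peakfind]
    algorithm: str = "peakfinder8"    # peakfinder8 | static | localsnr
    adc_threshold: float = 30.0
    snr_threshold: float = 7.0
    n_min: int = 1
    n_max: int = 40
    min_peak_separation: float = 5.0
    n_radial_bins: int = 0            # 0 -> 1-pixel annuli
    prescreen: bool = False
    prescreen_min_peaks: int = 10
    prescreen_radius: float = 0.0     # px; 0 -> inner quarter of r_max
    # [hitfind]
    mode: str = "crystal"             # crystal | particle
    n_peaks_min: int = 20
    resolution_cutoff: float | None = None
    particle_sigma_k: float = 3.0
    particle_npix_min: int = 100
    adu_per_photon: float = 30.0
    photon_threshold_fraction: float = 0.9
    loglik_cutoff: float = 5.0
    # [output]
    output_dir: str = "."
    overwrite: bool = False
    save_policy: str = "corrected"    # corrected | subtracted
    write_events: bool = True
    # [run]
    frame_rate_hz: float = 120.0
    window_seconds: float = 5.0
    seed: int = 0
    limit: int = 0                    # 0 -> no limit
    sequential: bool = True
    freeze_after: int = 0             # frames of warmup before buffer freeze (parallel)


# attribute -> (section, parser)
_PARSERS = {
    "geometry_path": ("geometry", _opt_str),
    "beam_center_x": ("geometry", float),
    "beam_center_y": ("geometry", float),
    "calibration_path": ("corrections", _opt_str),
    "do_saturation": ("corrections", _bool),
    "do_dark": ("corrections", _bool),
    "do_common_mode": ("corrections", _bool),
    "do_gain": ("corrections", _bool),
    "do_mask": ("corrections", _bool),
    "saturation_level": ("corrections", _opt_float),
    "background_mode": ("background", str),
    "buffer_depth": ("background", int),
    "recompute_period": ("background", int),
    "hot_level": ("background", _opt_float),
    "hot_fraction": ("background", float),
    "local_bg_radius": ("background", int),
    "algorithm": ("peakfind", str),
    "adc_threshold": ("peakfind", float),
    "snr_threshold": ("peakfind", float),
    "n_min": ("peakfind", int),
    "n_max": ("peakfind", int),
    "min_peak_separation": ("peakfind", float),
    "n_radial_bins": ("peakfind", int),
    "prescreen": ("peakfind", _bool),
    "prescreen_min_peaks": ("peakfind", int),
    "prescreen_radius": ("peakfind", float),
    "mode": ("hitfind", str),
    "n_peaks_min": ("hitfind", int),
    "resolution_cutoff": ("hitfind", _opt_float),
    "particle_sigma_k": ("hitfind", float),
    "particle_npix_min": ("hitfind", int),
    "adu_per_photon": ("hitfind", float),
    "photon_threshold_fraction": ("hitfind", float),
    "loglik_cutoff": ("hitfind", float),
    "output_dir": ("output", str),
    "overwrite": ("output", _bool),
    "save_policy": ("output", str),
    "write_events": ("output", _bool),
    "frame_rate_hz": ("run", float),
    "window_seconds": ("run", float),
    "seed": ("run", int),
    "limit": ("run", int),
    "sequential": ("run", _bool),
    "freeze_after": ("run", int),
}

_BY_LOCATION = {(sec, attr): attr for attr, (sec, _p) in _PARSERS.items()}


def validate_config(cfg: RunConfig) -> RunConfig:
    """Range checks; raises :class:`ConfigError` naming the offending key."""
    def req(cond: bool, key: str, msg: str) -> None:
        if not cond:
            raise ConfigError(f"config key '{key}': {msg}")

    req(cfg.background_mode in ("running", "local", "none"), "background_mode",
        "must be running|local|none")
    req(cfg.buffer_depth >= 1, "buffer_depth", "must be >= 1")
    req(0 < cfg.hot_fraction < 1, "hot_fraction", "must be in (0, 1)")
    req(cfg.local_bg_radius >= 1, "local_bg_radius", "must be >= 1")
    req(cfg.algorithm in ("peakfinder8", "static", "localsnr"), "algorithm",
        "must be peakfinder8|static|localsnr")
    req(cfg.adc_threshold > 0, "adc_threshold", "must be > 0")
    req(cfg.snr_threshold > 0, "snr_threshold", "must be > 0")
    req(1 <= cfg.n_min < cfg.n_max, "n_min", "require 1 <= n_min < n_max")
    req(cfg.mode in ("crystal", "particle"), "mode", "must be crystal|particle")
    req(cfg.n_peaks_min >= 1, "n_peaks_min", "must be >= 1")
    req(cfg.particle_sigma_k > 0, "particle_sigma_k", "must be > 0")
    req(0 < cfg.photon_threshold_fraction < 1, "photon_threshold_fraction",
        "must be in (0, 1)")
    req(cfg.adu_per_photon > 0, "adu_per_photon", "must be > 0")
    req(cfg.save_policy in ("corrected", "subtracted"), "save_policy",
        "must be corrected|subtracted")
    req(cfg.frame_rate_hz > 0, "frame_rate_hz", "must be > 0")
    req(cfg.window_seconds > 0, "window_seconds", "must be > 0")
    req(cfg.limit >= 0, "limit", "must be >= 0")
    req(cfg.freeze_after >= 0, "freeze_after", "must be >= 0")
    if cfg.saturation_level is not None:
        req(cfg.saturation_level > 0, "saturation_level", "must be > 0")
    return cfg


def parse_config(path_or_text) -> RunConfig:
    """Parse an ini file (path or text); empty file means all defaults."""
    cp = configparser.ConfigParser()
    try:
        if hasattr(path_or_text, "read"):
            cp.read_file(path_or_text)
        elif "\n" in str(path_or_text) or "=" in str(path_or_text):
            cp.read_string(str(path_or_text))
        else:
            with open(path_or_text) as fh:
                cp.read_file(fh)
    except (OSError, configparser.Error) as e:
        raise ConfigError(str(e)) from e
    cfg = RunConfig()
    for sec in cp.sections():
        for key, raw in cp.items(sec):
            attr = _BY_LOCATION.get((sec, key))
            if attr is None:
                raise ConfigError(f"unknown config key '{key}' in section [{sec}]")
            _section, parser = _PARSERS[attr]
            try:
                setattr(cfg, attr, parser(raw))
            except (TypeError, ValueError) as e:
                raise ConfigError(
                    f"bad value for '{key}' in section [{sec}]: {raw!r} ({e})") from e
    return validate_config(cfg)


def serialize_config(cfg: RunConfig) -> str:
    """Full resolved configuration as ini text (parse -> serialize -> parse
    is the identity)."""
    cp = configparser.ConfigParser()
    for f in fields(RunConfig):
        sec, _parser = _PARSERS[f.name]
        if not cp.has_section(sec):
            cp.add_section(sec)
        v = getattr(cfg, f.name)
        cp.set(sec, f.name, "" if v is None else repr(v) if isinstance(v, float) else str(v))
    buf = io.StringIO()
    cp.write(buf)
    return buf.getvalue()
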