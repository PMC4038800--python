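"""Facility-independent HDF5 event export and stream reading.

Hit events are written one file per event with a self-defined, CXI-inspired
layout:

* ``/data/data`` — the frame (policy-chosen variant: raw-corrected or
  background-subtracted) and ``/data/flags`` — the pixel flag bitfield;
* ``/processing/peaks`` — the peak table (module, row, col, npix, intensity,
  intensity_raw, snr, radius), background-corrected intensities regardless of
  the saving policy of the frame itself;
* ``/processing/hit`` — the classification metrics;
* ``/metadata`` — per-event scalars.

Input streams are either one stacked HDF5 file with the frame axis first or a
directory of per-frame files in the same dialect.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np

from .corrections import Frame
from .hitfind import HitResult
from .peakfind import PeakList

__all__ = ["EventRecord", "write_event", "read_event", "append_hitlist",
           "write_stream", "iter_frames"]


@dataclass
class EventRecord:
    event_id: int
    frame: Frame
    peaks: PeakList
    hit: HitResult
    metadata: dict = field(default_factory=dict)


_HIT_FIELDS = ("is_hit", "n_peaks", "resolution_radius", "resolution_d",
               "n_pixels_above", "total_counts", "loglik")


def write_event(rec: EventRecord, path, overwrite: bool = False) -> None:
    """Write one event; refuses to clobber an existing file unless asked."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists (pass overwrite=True to replace)")
    with h5py.File(path, "w") as f:
        f.create_dataset("data/data", data=rec.frame.data)
        f.create_dataset("data/flags", data=rec.frame.flags)
        f.create_dataset("processing/peaks", data=rec.peaks.to_array())
        f["processing/peaks"].attrs["columns"] = \
            "module,row,col,npix,intensity,intensity_raw,snr,radius"
        g = f.create_group("processing/hit")
        for name in _HIT_FIELDS:
            v = getattr(rec.hit, name)
            g.attrs[name] = v if v is not None else np.nan
        g.attrs["classifier"] = rec.hit.classifier
        m = f.create_group("metadata")
        m.attrs["event_id"] = rec.event_id
        for k, v in {**rec.frame.metadata, **rec.metadata}.items():
            try:
                m.attrs[str(k)] = v
            except TypeError:
                m.attrs[str(k)] = str(v)


def read_event(path) -> EventRecord:
    with h5py.File(path, "r") as f:
        data = np.asarray(f["data/data"])
        flags = np.asarray(f["data/flags"])
        peaks = PeakList.from_array(np.asarray(f["processing/peaks"]))
        ha = f["processing/hit"].attrs
        hit = HitResult(
            is_hit=bool(ha["is_hit"]),
            classifier=str(ha["classifier"]),
            n_peaks=int(ha["n_peaks"]),
            resolution_radius=float(ha["resolution_radius"]),
            resolution_d=float(ha["resolution_d"]),
            n_pixels_above=int(ha["n_pixels_above"]),
            total_counts=float(ha["total_counts"]),
            loglik=float(ha["loglik"]),
        )
        ma = dict(f["metadata"].attrs)
    event_id = int(ma.pop("event_id"))
    return EventRecord(event_id=event_id,
                       frame=Frame(data=data, flags=flags, event_id=event_id,
                                   metadata=ma),
                       peaks=peaks, hit=hit, metadata={})


def append_hitlist(path, event_id: int) -> None:
    """Append one event id per line, flushed immediately."""
    with open(path, "a") as fh:
        fh.write(f"{event_id}\n")
        fh.flush()
        os.fsync(fh.fileno())


def write_stream(frames, path) -> None:
    """Write a frame stream as one stacked HDF5 dataset (frame axis first)."""
    stack = np.stack([f.data for f in frames])
    ids = np.array([f.event_id for f in frames], dtype=np.int64)
    with h5py.File(path, "w") as f:
        f.create_dataset("data/data", data=stack)
        f.create_dataset("data/event_id", data=ids)


def iter_frames(source) -> Iterator[Frame]:
    """Yield frames in event order from a stacked HDF5 file, a directory of
    per-frame HDF5 files (sorted by name), or any iterable of Frames."""
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.is_dir():
            for i, fp in enumerate(sorted(p.glob("*.h5"))):
                with h5py.File(fp, "r") as f:
                    data = np.asarray(f["data/data"])
                    eid = int(f["data/event_id"][()]) if "data/event_id" in f else i
                yield Frame(data=data, event_id=eid)
        else:
            with h5py.File(p, "r") as f:
                stack = np.asarray(f["data/data"])
                ids = (np.asarray(f["data/event_id"])
                       if "data/event_id" in f else np.arange(stack.shape[0]))
            for eid, data in zip(ids, stack):
                yield Frame(data=data, event_id=int(eid))
    else:
        for fr in source:
            yield fr if isinstance(fr, Frame) else Frame(data=np.asarray(fr, float))
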