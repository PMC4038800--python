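"""Segmented-detector geometry.

Modular X-ray detectors store data in a "raw" in-memory layout that bears no
resemblance to the physical arrangement of modules.  A pixel map carrying the
physical (x, y, z) coordinates of every raw-layout pixel is the single link
between array indices and laboratory space.  All analysis in this package runs
on the raw layout, module by module; assembly into a physically correct image
exists only for viewing/FFT-style output.

Conventions (the upstream practice leaves these open, so they are fixed here):

* pixel indices are 0-based ``(row, col)``;
* physical coordinates are in metres, ``y`` increasing with the row index of
  module 0 in its nominal orientation; the beam centre is stored in physical
  units;
* momentum transfer uses ``|q| = (2 / lambda) * sin(theta)`` with ``2*theta``
  the scattering angle (no ``2*pi`` factor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "DetectorLayout",
    "ModuleTable",
    "PixelMap",
    "load_pixelmap",
    "assemble",
    "radius_map",
    "scattering_vectors",
    "resolution_annulus_mask",
]


@dataclass(frozen=True)
class DetectorLayout:
    """Tiling of detector modules into the raw data array.

    Parameters
    ----------
    module_shape : (rows, cols) of a single module in pixels.
    grid : (modules down, modules across); the raw array is the dense tiling
        of ``grid[0] * grid[1]`` modules, row-major module numbering.
    """

    module_shape: tuple[int, int]
    grid: tuple[int, int]

    def __post_init__(self) -> None:
        mr, mc = self.module_shape
        gr, gc = self.grid
        if mr < 1 or mc < 1 or gr < 1 or gc < 1:
            raise ValueError("module_shape and grid entries must be >= 1")

    @property
    def n_modules(self) -> int:
        return self.grid[0] * self.grid[1]

    @property
    def raw_shape(self) -> tuple[int, int]:
        return (self.grid[0] * self.module_shape[0], self.grid[1] * self.module_shape[1])

    def module_slice(self, module_id: int) -> tuple[slice, slice]:
        """Slice of the raw array occupied by ``module_id``."""
        if not 0 <= module_id < self.n_modules:
            raise ValueError(f"module_id {module_id} out of range 0..{self.n_modules - 1}")
        gr, gc = self.grid
        mr, mc = self.module_shape
        i, j = divmod(module_id, gc)
        return (slice(i * mr, (i + 1) * mr), slice(j * mc, (j + 1) * mc))

    def module_id_map(self) -> np.ndarray:
        """Per-pixel module label, raw-layout shape."""
        out = np.empty(self.raw_shape, dtype=np.int32)
        for m in range(self.n_modules):
            out[self.module_slice(m)] = m
        return out

    def iter_modules(self):
        for m in range(self.n_modules):
            yield m, self.module_slice(m)


class ModuleTable:
    """Module boundaries recovered from a per-pixel ``module_id`` map.

    Serves as a drop-in for :class:`DetectorLayout` when geometry comes from a
    file rather than a declared grid; each module must occupy an axis-aligned
    rectangular block of the raw array.
    """

    def __init__(self, module_id: np.ndarray):
        self._module_id = np.asarray(module_id)
        self.raw_shape = self._module_id.shape
        self.n_modules = int(self._module_id.max()) + 1 if self._module_id.size else 0
        self._slices = []
        for m in range(self.n_modules):
            rr, cc = np.nonzero(self._module_id == m)
            if rr.size == 0:
                raise ValueError(f"module {m} has no pixels")
            sl = (slice(int(rr.min()), int(rr.max()) + 1),
                  slice(int(cc.min()), int(cc.max()) + 1))
            if (rr.max() - rr.min() + 1) * (cc.max() - cc.min() + 1) != rr.size:
                raise ValueError(f"module {m} is not a rectangular block")
            self._slices.append(sl)

    def module_slice(self, module_id: int) -> tuple[slice, slice]:
        return self._slices[module_id]

    def module_id_map(self) -> np.ndarray:
        return self._module_id

    def iter_modules(self):
        for m, sl in enumerate(self._slices):
            yield m, sl


@dataclass
class PixelMap:
    """Per-pixel physical coordinates (metres) congruent with the raw layout."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    module_id: np.ndarray
    pixel_pitch: float
    wavelength: float | None = None
    detector_distance: float | None = None
    layout: DetectorLayout | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.x, self.y, self.z, self.module_id)}
        if len(shapes) != 1:
            raise ValueError(f"x/y/z/module_id shapes differ: {sorted(shapes)}")
        mids = np.unique(self.module_id)
        if mids.size and (mids[0] != 0 or not np.array_equal(mids, np.arange(mids.size))):
            raise ValueError("module_id values must be contiguous integers starting at 0")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def raw_shape(self) -> tuple[int, int]:
        return self.x.shape

    @classmethod
    def from_layout(
        cls,
        layout: DetectorLayout,
        pixel_pitch: float = 1.0,
        center: tuple[float, float] | None = None,
        module_offsets: dict[int, tuple[float, float]] | None = None,
        **kw,
    ) -> "PixelMap":
        """Identity-like map: physical position = raw index * pitch.

        ``center`` is a (row, col) raw index placed at physical (0, 0);
        ``module_offsets`` are per-module (row, col) shifts in pixel units
        (for deliberately misplaced-module fixtures).
        """
        rows, cols = np.indices(layout.raw_shape).astype(float)
        if module_offsets:
            mid = layout.module_id_map()
            for m, (dr, dc) in module_offsets.items():
                rows[mid == m] += dr
                cols[mid == m] += dc
        if center is not None:
            rows -= center[0]
            cols -= center[1]
        return cls(
            x=cols * pixel_pitch,
            y=rows * pixel_pitch,
            z=np.zeros(layout.raw_shape),
            module_id=layout.module_id_map(),
            pixel_pitch=pixel_pitch,
            layout=layout,
            **kw,
        )


def load_pixelmap(path) -> PixelMap:
    """Read a geometry file: HDF5 datasets ``x``, ``y``, ``z`` in metres, raw
    layout shape, plus optional ``module_id`` and scalar attributes
    ``pixel_pitch``, ``wavelength``, ``detector_distance``.

    Missing coordinate datasets raise ``KeyError``; shape mismatches raise
    ``ValueError`` (never silently broadcast).
    """
    with h5py.File(path, "r") as f:
        arrs = {}
        for name in ("x", "y", "z"):
            if name not in f:
                raise KeyError(f"geometry file {path!s} is missing dataset '{name}'")
            arrs[name] = np.asarray(f[name], dtype=float)
        if "module_id" in f:
            module_id = np.asarray(f["module_id"], dtype=np.int32)
        else:
            module_id = np.zeros(arrs["x"].shape, dtype=np.int32)
        attrs = dict(f.attrs)
    pitch = float(attrs.get("pixel_pitch", 0.0))
    if pitch <= 0:
        # fall back to the median nearest-neighbour spacing along a row
        dx = np.abs(np.diff(arrs["x"], axis=1))
        dy = np.abs(np.diff(arrs["y"], axis=1))
        step = np.hypot(dx, dy)
        pitch = float(np.median(step[step > 0])) if np.any(step > 0) else 1.0
    return PixelMap(
        x=arrs["x"],
        y=arrs["y"],
        z=arrs["z"],
        module_id=module_id,
        pixel_pitch=pitch,
        wavelength=attrs.get("wavelength"),
        detector_distance=attrs.get("detector_distance"),
    )


def save_pixelmap(pm: PixelMap, path) -> None:
    """Write the HDF5 geometry dialect read by :func:`load_pixelmap`."""
    with h5py.File(path, "w") as f:
        f.create_dataset("x", data=pm.x)
        f.create_dataset("y", data=pm.y)
        f.create_dataset("z", data=pm.z)
        f.create_dataset("module_id", data=pm.module_id)
        f.attrs["pixel_pitch"] = pm.pixel_pitch
        if pm.wavelength is not None:
            f.attrs["wavelength"] = pm.wavelength
        if pm.detector_distance is not None:
            f.attrs["detector_distance"] = pm.detector_distance


def assemble(frame_raw: np.ndarray, pm: PixelMap) -> tuple[np.ndarray, tuple[int, int]]:
    """Deposit raw pixels at their nearest physical grid position.

    Nearest-neighbour only — values are moved, never blended.  Unoccupied grid
    cells hold NaN (distinguishable from dark pixels at 0).  Returns the
    assembled image and the grid index of the physical origin (direct beam).
    """
    if frame_raw.shape != pm.raw_shape:
        raise ValueError(f"frame shape {frame_raw.shape} != pixel map shape {pm.raw_shape}")
    irow = np.rint(pm.y / pm.pixel_pitch).astype(np.int64)
    icol = np.rint(pm.x / pm.pixel_pitch).astype(np.int64)
    r0, c0 = irow.min(), icol.min()
    out = np.full((int(irow.max() - r0 + 1), int(icol.max() - c0 + 1)), np.nan, dtype=float)
    out[irow - r0, icol - c0] = frame_raw
    return out, (int(-r0), int(-c0))


def radius_map(
    pm: PixelMap, beam_center: tuple[float, float] = (0.0, 0.0), units: str = "pixels"
) -> np.ndarray:
    """Per-pixel in-plane distance from the beam centre.

    ``beam_center`` is physical (x, y) in metres; ``units`` is ``"pixels"``
    (radius / pixel_pitch, the scale radial binning uses) or ``"metres"``.
    """
    r = np.hypot(pm.x - beam_center[0], pm.y - beam_center[1])
    if units == "pixels":
        return r / pm.pixel_pitch
    if units == "metres":
        return r
    raise ValueError(f"units must be 'pixels' or 'metres', got {units!r}")


def scattering_vectors(
    pm: PixelMap, wavelength: float | None = None, detector_distance: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel momentum transfer (k_x, k_y, k_z) on the Ewald sphere.

    q = (s_hat - z_hat) / lambda with s_hat the unit vector from the sample to
    the pixel at (x, y, D + z).  |q| = (2/lambda) sin(theta); a pixel on the
    beam axis maps to the zero vector.
    """
    lam = wavelength if wavelength is not None else pm.wavelength
    dist = detector_distance if detector_distance is not None else pm.detector_distance
    if lam is None or lam <= 0:
        raise ValueError("wavelength must be positive")
    if dist is None or dist <= 0:
        raise ValueError("detector_distance must be positive")
    zz = dist + pm.z
    norm = np.sqrt(pm.x**2 + pm.y**2 + zz**2)
    kx = pm.x / (norm * lam)
    ky = pm.y / (norm * lam)
    kz = (zz / norm - 1.0) / lam
    return kx, ky, kz


def resolution_annulus_mask(
    pm: PixelMap,
    r_min: float,
    r_max: float,
    beam_center: tuple[float, float] = (0.0, 0.0),
    units: str = "pixels",
) -> np.ndarray:
    """Boolean mask, true exactly where ``r_min <= r < r_max``.

    Depends only on geometry, so callers cache it until the detector moves.
    """
    if not 0 <= r_min < r_max:
        raise ValueError(f"require 0 <= r_min < r_max, got {r_min}, {r_max}")
    r = radius_map(pm, beam_center=beam_center, units=units)
    return (r >= r_min) & (r < r_max)
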