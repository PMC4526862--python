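"""File I/O: TIFF stacks, contour JSON, surface JSON/OBJ, pixel binning.

Contours use a small JSON dialect::

    {"points": [[x, y], ...], "closed": true, "slice": z}

All image intensities are promoted to double precision on read so that the
downstream conditioning chain (means and differences) is never distorted by
integer truncation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError
from .pipeline import SurfaceModel
from .resampling import ClosedBoundary, ImageSlice

__all__ = [
    "read_stack",
    "write_stack",
    "bin_pixels",
    "read_contour",
    "write_contour",
    "write_surface",
    "read_surface",
    "write_obj",
]

_TIFF_SUFFIXES = (".tif", ".tiff")


def _to_slices(volume: np.ndarray) -> list[ImageSlice]:
    if volume.ndim == 2:
        volume = volume[None]
    if volume.ndim != 3:
        raise FormatError(f"expected a 2D/3D grayscale stack, got shape {volume.shape}")
    return [ImageSlice(np.asarray(plane, dtype=np.float64)) for plane in volume]


def read_stack(path) -> list[ImageSlice]:
    """Read a z-ordered stack from a multi-page TIFF or a directory of
    same-shape single-page TIFFs (lexicographic z-order)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES)
        if not files:
            raise FormatError(f"no TIFF files in directory {path}")
        slices: list[ImageSlice] = []
        shape = None
        for f in files:
            try:
                arr = tifffile.imread(f)
            except Exception as exc:  # noqa: BLE001 - name the offending file
                raise FormatError(f"unreadable TIFF file {f}: {exc}") from exc
            if arr.ndim != 2:
                raise FormatError(f"{f} is not a single-page 2D TIFF")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise FormatError(
                    f"mixed slice shapes: {f} has {arr.shape}, expected {shape}"
                )
            slices.append(ImageSlice(np.asarray(arr, dtype=np.float64)))
        return slices
    try:
        volume = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"unreadable TIFF file {path}: {exc}") from exc
    return _to_slices(np.asarray(volume))


def write_stack(slices: list[ImageSlice], path) -> None:
    """Write a stack as one multi-page TIFF (float64, lossless round trip)."""
    volume = np.stack([s.intensities for s in slices])
    tifffile.imwrite(Path(path), volume, photometric="minisblack")


def _block_mean(arr: np.ndarray, k: int, axis: int) -> np.ndarray:
    """Mean over blocks of size k along one axis; a trailing partial block
    is averaged over its actual extent."""
    if k == 1:
        return arr
    n = arr.shape[axis]
    starts = np.arange(0, n, k)
    sums = np.add.reduceat(arr, starts, axis=axis)
    counts = np.minimum(starts + k, n) - starts
    shape = [1] * arr.ndim
    shape[axis] = len(starts)
    return sums / counts.reshape(shape)


def bin_pixels(stack, kx: int, ky: int, kz: int):
    """Downsample by averaging kx x ky x kz voxel blocks.

    ``stack`` may be a list of :class:`ImageSlice` (returned as such) or a
    3D array (returned as an array, which also permits outputs smaller than
    the minimum slice size).
    """
    if kx < 1 or ky < 1 or kz < 1:
        raise FormatError("binning factors must be >= 1")
    as_slices = not isinstance(stack, np.ndarray)
    volume = np.stack([s.intensities for s in stack]) if as_slices else np.asarray(stack, dtype=np.float64)
    if volume.ndim != 3:
        raise FormatError("expected a 3D stack")
    volume = _block_mean(volume, kz, axis=0)
    volume = _block_mean(volume, ky, axis=1)
    volume = _block_mean(volume, kx, axis=2)
    if as_slices:
        return [ImageSlice(plane) for plane in volume]
    return volume


def read_contour(path) -> ClosedBoundary:
    """Read a closed contour from the JSON dialect above."""
    path = Path(path)
    try:
        with open(path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(
            f"malformed contour JSON {path}: line {exc.lineno}, col {exc.colno}: {exc.msg}"
        ) from exc
    if not isinstance(data, dict) or "points" not in data:
        raise FormatError(f"{path}: contour JSON must contain a 'points' list")
    if not data.get("closed", False):
        raise FormatError(f"{path}: only closed contours are supported")
    return ClosedBoundary(np.asarray(data["points"], dtype=np.float64))


def write_contour(boundary: ClosedBoundary, path, slice_index: int = 0) -> None:
    data = {
        "points": [[float(x), float(y)] for x, y in boundary.points],
        "closed": True,
        "slice": int(slice_index),
    }
    with open(Path(path), "w") as fh:
        json.dump(data, fh)


def write_surface(model: SurfaceModel, path) -> None:
    """Write a reconstructed surface as one JSON document."""
    z0 = model.z_range[0]
    data = {
        "voxel_size": list(model.voxel_size),
        "z_range": list(model.z_range),
        "slices": [
            {
                "slice": z0 + i,
                "points": [[float(x), float(y)] for x, y in b.points],
                "closed": True,
                "converged": st.converged,
                "failed": st.failed,
                "iterations": st.iterations,
            }
            for i, (b, st) in enumerate(zip(model.boundaries, model.per_slice_status))
        ],
    }
    with open(Path(path), "w") as fh:
        json.dump(data, fh)


def read_surface(path) -> list[ClosedBoundary]:
    """Read back the boundaries of a surface JSON (z-ordered)."""
    path = Path(path)
    try:
        with open(path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(
            f"malformed surface JSON {path}: line {exc.lineno}, col {exc.colno}: {exc.msg}"
        ) from exc
    return [
        ClosedBoundary(np.asarray(s["points"], dtype=np.float64)) for s in data["slices"]
    ]


def write_obj(model: SurfaceModel, path) -> None:
    """Export the surface as an OBJ triangle mesh.

    Ring i contributes N vertices at physical coordinates
    (x * vx, y * vy, z_i * vz); consecutive rings are joined by a band of
    quads split into two triangles each (matching vertex indices across
    rings), giving 2N triangles per band.
    """
    vx, vy, vz = model.voxel_size
    z0 = model.z_range[0]
    n = len(model.boundaries[0])
    lines = []
    for i, b in enumerate(model.boundaries):
        z = (z0 + i) * vz
        for x, y in b.points:
            lines.append(f"v {x * vx:.6f} {y * vy:.6f} {z:.6f}")
    for i in range(len(model.boundaries) - 1):
        a0 = i * n
        b0 = (i + 1) * n
        for j in range(n):
            k = (j + 1) % n
            # OBJ indices are 1-based
            lines.append(f"f {a0 + j + 1} {a0 + k + 1} {b0 + k + 1}")
            lines.append(f"f {a0 + j + 1} {b0 + k + 1} {b0 + j + 1}")
    Path(path).write_text("\n".join(lines) + "\n")
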