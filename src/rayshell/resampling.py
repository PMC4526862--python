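"""Boundary discretization, normal estimation and ray resampling.

A closed boundary on one image slice is represented as a cyclic, ordered
point list.  Along the exterior normal at each boundary element we sample
the image at integer offsets m in [-M, M] ("the ray"); negative offsets are
interior, positive exterior.  The raw ray profiles are conditioned in three
stages -- per-ray clamping between the interior and exterior mean levels,
repeated 3-point smoothing, and negated thresholded differencing -- to give
the valid gradient g(p), which is positive only where the intensity drops
in the outward direction, i.e. at candidate boundary crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from shapely.geometry import LinearRing

from .errors import BoundaryError, ParameterError, SamplingError

__all__ = [
    "ImageSlice",
    "ClosedBoundary",
    "RayField",
    "resample_closed_polyline",
    "exterior_normals",
    "sample_ray_signals",
    "clamp_profile",
    "smooth_profile",
    "valid_gradient",
    "build_ray_field",
]


@dataclass(frozen=True)
class ImageSlice:
    """One 2D slice of the stack: nonnegative scalar intensities.

    Pixel centers sit at integer coordinates, 0-based, with x = column and
    y = row.
    """

    intensities: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 2:
            raise ParameterError("image slice must be 2D")
        if arr.shape[0] < 8 or arr.shape[1] < 8:
            raise ParameterError("image slice must be at least 8x8 pixels")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ParameterError("intensities must be finite and nonnegative")
        object.__setattr__(self, "intensities", arr)

    @property
    def height(self) -> int:
        return self.intensities.shape[0]

    @property
    def width(self) -> int:
        return self.intensities.shape[1]


def _signed_area(points: np.ndarray) -> float:
    """Shoelace signed area; positive for counter-clockwise order."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _is_simple(points: np.ndarray) -> bool:
    return LinearRing(points).is_simple


@dataclass(frozen=True)
class ClosedBoundary:
    """Cyclic ordered list of planar points (continuous pixel units).

    Vertex order is canonicalized to counter-clockwise (positive shoelace
    area with x = column, y = row).  The polygon must be simple.
    """

    points: np.ndarray
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise BoundaryError("boundary points must be an (N, 2) array")
        if pts.shape[0] < 8:
            raise BoundaryError("a closed boundary needs at least 8 points")
        if not np.all(np.isfinite(pts)):
            raise BoundaryError("boundary points must be finite")
        area = _signed_area(pts)
        if area < 0:  # canonicalize to CCW
            pts = pts[::-1].copy()
        if self.validate:
            if area == 0:
                raise BoundaryError("boundary has zero signed area")
            if not _is_simple(pts):
                raise BoundaryError("boundary polygon is self-intersecting")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def is_simple(self) -> bool:
        return _is_simple(self.points)


def _resample_points(points: np.ndarray, n_points: int) -> np.ndarray:
    """Equal arc-length resampling of a closed polyline, no validation.

    Keeps the original first vertex as the first output point.  If the
    requested count equals the current count and the spacing is already
    uniform, the input is returned unchanged so the operation is an exact
    identity (and hence idempotent).
    """
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0:
        raise BoundaryError("boundary has zero perimeter")
    if n_points == len(points):
        rel = (seg.max() - seg.min()) / seg.mean()
        if rel <= 1e-6:
            return points.copy()
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(n_points) * (total / n_points)
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    return np.column_stack([x, y])


def resample_closed_polyline(boundary: ClosedBoundary, n_points: int) -> ClosedBoundary:
    """Resample a closed boundary to ``n_points`` equally spaced by arc length.

    The first output point coincides with the original first vertex and CCW
    order is preserved.
    """
    if n_points < 8:
        raise ParameterError("n_points must be at least 8")
    pts = _resample_points(boundary.points, n_points)
    return ClosedBoundary(pts)


def exterior_normals(boundary: ClosedBoundary) -> np.ndarray:
    """Unit exterior normals at each boundary element.

    The normal at point i is perpendicular to the chord from point i-1 to
    point i+1 (cyclic), oriented away from the polygon interior.  For a CCW
    polygon in image coordinates the outward perpendicular of a tangent
    (tx, ty) is (ty, -tx).
    """
    pts = boundary.points
    chord = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    norms = np.linalg.norm(chord, axis=1)
    if np.any(norms < 1e-12):
        bad = int(np.argmin(norms))
        raise BoundaryError(f"degenerate geometry: zero chord at element {bad}")
    normals = np.column_stack([chord[:, 1], -chord[:, 0]]) / norms[:, None]
    return normals


def _box_mean_image(image: np.ndarray, size: int = 5) -> np.ndarray:
    """Mean over the size x size window at every pixel, windows clipped at
    the image borders (mean over in-image pixels only)."""
    num = uniform_filter(image, size=size, mode="constant", cval=0.0)
    den = uniform_filter(np.ones_like(image), size=size, mode="constant", cval=0.0)
    return num / den


def _containing_pixel(coords: np.ndarray) -> np.ndarray:
    """Nearest-integer pixel for continuous coordinates, ties toward +inf."""
    return np.floor(coords + 0.5).astype(np.intp)


def sample_ray_signals(
    slice_: ImageSlice,
    boundary: ClosedBoundary,
    normals: np.ndarray,
    M: int,
) -> "RayField":
    """Sample the image along each element's normal ray.

    The signal at offset m of element i is the mean intensity over the 5x5
    pixel window centered on the pixel containing the position
    ``origin_i + m * normal_i`` (window clipped at image borders).  Negative
    m is interior to the boundary, positive m exterior.
    """
    if M < 2:
        raise ParameterError("M must be at least 2")
    origins = boundary.points
    offsets = np.arange(-M, M + 1)
    # positions: (N, 2M+1, 2)
    pos = origins[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    px = _containing_pixel(pos[..., 0])
    py = _containing_pixel(pos[..., 1])
    h, w = slice_.height, slice_.width
    bad = (px < 0) | (px >= w) | (py < 0) | (py >= h)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise SamplingError(
            f"ray sample out of image bounds at element {int(i)}, "
            f"offset m={int(offsets[j])}"
        )
    box = _box_mean_image(slice_.intensities)
    raw = box[py, px]
    return RayField(origins=origins, normals=normals, M=int(M), raw_signal=raw)


def clamp_profile(ray_signal: np.ndarray):
    """Clamp ray profiles between their interior and exterior mean levels.

    L1 is the mean of the exterior samples (m = 1..M) and L2 the mean of
    the interior samples (m = -M..-1); the m = 0 sample contributes to
    neither.  Every sample (including m = 0) is clipped to
    [min(L1, L2), max(L1, L2)].  Works on a single profile of length 2M+1
    or on a stack of profiles along the last axis.

    Returns ``(clamped, L1, L2)``.
    """
    v = np.asarray(ray_signal, dtype=np.float64)
    n = v.shape[-1]
    if n < 5 or n % 2 == 0:
        raise ParameterError("profile length must be odd and at least 5 (2M+1, M>=2)")
    M = n // 2
    L2 = v[..., :M].mean(axis=-1)  # interior, m = -M..-1
    L1 = v[..., M + 1 :].mean(axis=-1)  # exterior, m = 1..M
    lo = np.minimum(L1, L2)
    hi = np.maximum(L1, L2)
    clamped = np.clip(v, lo[..., None], hi[..., None])
    return clamped, L1, L2


def smooth_profile(signal: np.ndarray, passes: int) -> np.ndarray:
    """Repeated 3-point moving average along the last axis.

    Endpoints use edge replication (virtual samples equal to the ends), so
    constant profiles are invariant and the output length equals the input
    length.
    """
    if passes < 0:
        raise ParameterError("passes must be nonnegative")
    x = np.asarray(signal, dtype=np.float64)
    if x.shape[-1] < 3:
        raise ParameterError("profile too short to smooth")
    for _ in range(passes):
        xp = np.concatenate([x[..., :1], x, x[..., -1:]], axis=-1)
        x = (xp[..., :-2] + xp[..., 1:-1] + xp[..., 2:]) / 3.0
    return x


def valid_gradient(smoothed_signal: np.ndarray) -> np.ndarray:
    """Negated, thresholded outward difference of a conditioned ray profile.

    g_m = -(v_{m+1} - v_m) where the difference is negative (intensity drops
    outward), else 0.  Output has one fewer sample than the input along the
    last axis; sample m lives at the offset midpoint m + 1/2.
    """
    v = np.asarray(smoothed_signal, dtype=np.float64)
    d = np.diff(v, axis=-1)
    return np.where(d < 0, -d, 0.0)


@dataclass
class RayField:
    """Per-element rays: origins, unit exterior normals, sampled and
    conditioned signals over offsets m in [-M, M], and the valid gradient.

    ``grad`` has 2M samples per ray, located at offset midpoints m + 1/2
    for m = -M..M-1 (see :attr:`grad_offsets`).
    """

    origins: np.ndarray
    normals: np.ndarray
    M: int
    raw_signal: np.ndarray
    conditioned_signal: np.ndarray | None = None
    grad: np.ndarray | None = None
    L1: np.ndarray | None = None
    L2: np.ndarray | None = None

    def __post_init__(self):
        lens = np.linalg.norm(self.normals, axis=1)
        if np.any(np.abs(lens - 1.0) > 1e-9):
            raise ParameterError("normals must be unit vectors")
        if self.raw_signal.shape != (len(self.origins), 2 * self.M + 1):
            raise ParameterError("raw_signal must have shape (N, 2M+1)")

    @property
    def n_rays(self) -> int:
        return self.origins.shape[0]

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.M, self.M + 1)

    @property
    def grad_offsets(self) -> np.ndarray:
        """Offset midpoints of the gradient samples: m + 1/2, m = -M..M-1."""
        return np.arange(-self.M, self.M) + 0.5

    def condition(self, smoothing_passes: int = 10) -> "RayField":
        """Run the clamp -> smooth -> valid-gradient chain in place."""
        clamped, L1, L2 = clamp_profile(self.raw_signal)
        smoothed = smooth_profile(clamped, smoothing_passes)
        self.conditioned_signal = smoothed
        self.grad = valid_gradient(smoothed)
        self.L1 = L1
        self.L2 = L2
        return self


def build_ray_field(
    slice_: ImageSlice,
    boundary: ClosedBoundary,
    M: int,
    smoothing_passes: int = 10,
) -> RayField:
    """Sample and condition all rays for one slice in one call."""
    normals = exterior_normals(boundary)
    rays = sample_ray_signals(slice_, boundary, normals, M)
    return rays.condition(smoothing_passes)
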