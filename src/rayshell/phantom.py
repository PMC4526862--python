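"""Synthetic image stacks with known ground-truth boundaries.

The generator emulates the imaging regime the reconstruction targets: a
smooth, possibly non-convex closed shape drifting slowly across slices,
with interior intensity above exterior, strong low-frequency intensity
inhomogeneity along the boundary, optional bright interference blobs just
outside the boundary, and additive Gaussian noise.

Truth shapes are star-convex: the radius is a harmonic function of angle,
rho(theta) = R * (1 + sum_j a_j cos(j theta + phi_j)), scaled per slice by
a geometric drift factor.  Star-convexity with sum |a_j| < 1/2 guarantees a
simple polygon while still exercising concave boundary stretches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import SpecError
from .evaluate import rasterize_boundary
from .resampling import ClosedBoundary, ImageSlice

__all__ = ["BlobSpec", "PhantomSpec", "truth_boundary", "generate_phantom", "standard_phantom"]

#: phase advance (radians per slice) of the interior inhomogeneity field
_INHOM_AXIAL_RATE = 0.25
#: points used to render truth polygons onto the pixel grid
_RENDER_POINTS = 720


@dataclass(frozen=True)
class BlobSpec:
    """One exterior interference blob: a bright disc whose inner edge sits
    ``radial_offset`` pixels outside the truth boundary, centered at angle
    ``theta`` and sized to span ``arc_width`` radians of boundary arc."""

    theta: float
    arc_width: float
    radial_offset: float
    intensity: float
    z_range: tuple[int, int]  # inclusive


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom parameters; the defaults are the standard phantom used
    throughout the package's evaluation.

    harmonics : list of (order j, amplitude a_j, phase phi_j) defining the
        star-convex radius function.
    z_drift : per-slice multiplicative radial scale factor.
    inhomogeneity_amp : relative amplitude of the low-frequency
        multiplicative field modulating the interior intensity.
    """

    width: int = 220
    height: int = 220
    n_slices: int = 20
    base_radius: float = 60.0
    harmonics: tuple[tuple[int, float, float], ...] = ((3, 0.12, 0.0), (5, 0.05, 1.0))
    z_drift: float = 1.003
    intensity_in: float = 120.0
    intensity_out: float = 20.0
    inhomogeneity_amp: float = 0.3
    blob_specs: tuple[BlobSpec, ...] = (
        BlobSpec(
            theta=math.pi / 4,
            arc_width=math.radians(20.0),
            radial_offset=5.0,
            intensity=110.0,
            z_range=(8, 12),
        ),
    )
    noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if not (self.intensity_in > self.intensity_out >= 0):
            raise SpecError("require intensity_in > intensity_out >= 0")
        if sum(abs(a) for _, a, _ in self.harmonics) >= 0.5:
            raise SpecError("sum of harmonic amplitudes must stay below 0.5")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be nonnegative")
        if self.n_slices < 1 or self.width < 8 or self.height < 8:
            raise SpecError("invalid phantom dimensions")

    @property
    def center(self) -> tuple[float, float]:
        return ((self.width - 1) / 2.0, (self.height - 1) / 2.0)


def standard_phantom(seed: int = 0, blob: bool = True) -> PhantomSpec:
    """The standard 220x220x20 phantom, optionally without its blob."""
    if blob:
        return PhantomSpec(seed=seed)
    return PhantomSpec(seed=seed, blob_specs=())


def _radius(spec: PhantomSpec, theta: np.ndarray, z: int) -> np.ndarray:
    rho = np.ones_like(theta)
    for j, a, phi in spec.harmonics:
        rho = rho + a * np.cos(j * theta + phi)
    return spec.base_radius * rho * spec.z_drift**z


def truth_boundary(spec: PhantomSpec, z: int, n_points: int = _RENDER_POINTS) -> ClosedBoundary:
    """Ground-truth CCW polygon of slice ``z`` sampled at ``n_points`` angles."""
    if not (0 <= z < spec.n_slices):
        raise SpecError(f"slice index {z} outside [0, {spec.n_slices})")
    theta = 2.0 * np.pi * np.arange(n_points) / n_points
    rho = _radius(spec, theta, z)
    cx, cy = spec.center
    margin = min(cx, cy, spec.width - 1 - cx, spec.height - 1 - cy) - 1.0
    if rho.max() > margin:
        raise SpecError("truth shape exceeds the image margins")
    pts = np.column_stack([cx + rho * np.cos(theta), cy + rho * np.sin(theta)])
    return ClosedBoundary(pts)


def _render_slice(spec: PhantomSpec, z: int, rng: np.random.Generator) -> np.ndarray:
    cx, cy = spec.center
    ys, xs = np.mgrid[0 : spec.height, 0 : spec.width]
    theta = np.arctan2(ys - cy, xs - cx)
    rad = np.hypot(xs - cx, ys - cy)

    mask = rasterize_boundary(truth_boundary(spec, z), spec.height, spec.width)
    field = 1.0 + spec.inhomogeneity_amp * np.sin(theta + _INHOM_AXIAL_RATE * z)
    img = np.where(mask, spec.intensity_in * field, spec.intensity_out)

    for blob in spec.blob_specs:
        z0, z1 = blob.z_range
        if not (z0 <= z <= z1):
            continue
        rho_b = float(_radius(spec, np.asarray([blob.theta]), z)[0])
        r_disc = rho_b * blob.arc_width / 2.0
        r_center = rho_b + blob.radial_offset + r_disc
        bx = cx + r_center * math.cos(blob.theta)
        by = cy + r_center * math.sin(blob.theta)
        in_disc = (xs - bx) ** 2 + (ys - by) ** 2 <= r_disc**2
        img = np.where(in_disc & ~mask, blob.intensity, img)

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def generate_phantom(spec: PhantomSpec) -> tuple[list[ImageSlice], list[ClosedBoundary]]:
    """Render the full stack and its truth boundaries.

    All randomness comes from one generator seeded with ``spec.seed``, so
    the same spec always produces a bit-identical stack.
    """
    rng = np.random.default_rng(spec.seed)
    slices = [ImageSlice(_render_slice(spec, z, rng)) for z in range(spec.n_slices)]
    truths = [truth_boundary(spec, z) for z in range(spec.n_slices)]
    return slices, truths
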